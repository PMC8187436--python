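"""Headline gain-control indices: GSS and GEI.

GSS (Gamma Suppression Slope): per subject, the weighted GR power of each
moving condition is normalized to the 'slow' (lowest-velocity moving)
condition, shifted so the slow condition maps to zero, and regressed on drift
velocity through the origin:

    y_v = GR_v / GR_slow - 1,     gss = sum(v * y_v) / sum(v**2)

More negative GSS means stronger velocity-related attenuation.  The static
condition is excluded from GSS and handled by GEI:

    GEI = (GR_slow - GR_static) / GR_slow

which is <= 1 for positive powers and 0 iff static and slow powers are equal.
Subject results are averaged over visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateDataError
from .response import GammaResponse

__all__ = ["SubjectIndices", "compute_gss", "compute_gei", "visit_indices", "average_visits"]


@dataclass
class SubjectIndices:
    """Per-subject summary: indices plus per-condition weighted GR metrics."""

    subject_id: str
    visit: int | str  # visit number or "mean"
    gss: float
    gei: float
    gr_power: dict[str, float] = field(default_factory=dict)
    gr_freq: dict[str, float] = field(default_factory=dict)
    included: bool = True


def compute_gss(gr_power_by_velocity: Mapping[float, float]) -> float:
    """Zero-intercept least-squares slope of slow-normalized GR power vs
    velocity, over the moving conditions.

    The slow condition is the smallest velocity in the map; its power must be
    positive.  Invariant under common multiplicative gain.
    """
    if len(gr_power_by_velocity) < 2:
        raise ValueError("need at least two moving-condition powers")
    v = np.array(sorted(gr_power_by_velocity), dtype=float)
    if np.any(v <= 0):
        raise ValueError("GSS is defined on moving conditions (velocity > 0)")
    p = np.array([gr_power_by_velocity[vi] for vi in v], dtype=float)
    p_slow = p[0]
    if p_slow <= 0:
        raise DegenerateDataError("non-positive GR power in the slow condition")
    y = p / p_slow - 1.0
    return float((v * y).sum() / (v**2).sum())


def compute_gei(gr_static: float, gr_slow: float) -> float:
    """Gamma Enhancement Index: (GR_slow - GR_static) / GR_slow."""
    if gr_slow <= 0:
        raise DegenerateDataError("non-positive GR power in the slow condition")
    return float((gr_slow - gr_static) / gr_slow)


def visit_indices(
    subject_id: str,
    responses: Mapping[str, GammaResponse],
    visit: int = 0,
) -> SubjectIndices:
    """Indices for one visit from that visit's per-condition responses."""
    by_velocity = {r.velocity: r for r in responses.values()}
    velocities = sorted(by_velocity)
    if velocities[0] != 0.0 or len(velocities) < 3:
        raise ValueError("need a static condition and at least two moving conditions")
    moving = {v: by_velocity[v].weighted_power for v in velocities if v > 0}
    gss = compute_gss(moving)
    gei = compute_gei(by_velocity[velocities[0]].weighted_power, by_velocity[velocities[1]].weighted_power)
    return SubjectIndices(
        subject_id=subject_id,
        visit=visit,
        gss=gss,
        gei=gei,
        gr_power={r.condition: r.weighted_power for r in responses.values()},
        gr_freq={r.condition: r.weighted_freq for r in responses.values()},
    )


def average_visits(visit_indices_list: Sequence[SubjectIndices], included: bool | None = None) -> SubjectIndices:
    """Arithmetic mean of gss, gei and per-condition metrics across visits.

    ``included`` overrides the gate flag (normally the subject_gate result);
    by default it is the conjunction of the per-visit flags.  Indices are
    reported regardless of inclusion.
    """
    if not visit_indices_list:
        raise ValueError("no visits to average")
    ids = {si.subject_id for si in visit_indices_list}
    if len(ids) != 1:
        raise ValueError(f"mismatched subject ids: {sorted(ids)}")
    conditions = list(visit_indices_list[0].gr_power)
    return SubjectIndices(
        subject_id=visit_indices_list[0].subject_id,
        visit="mean",
        gss=float(np.mean([si.gss for si in visit_indices_list])),
        gei=float(np.mean([si.gei for si in visit_indices_list])),
        gr_power={c: float(np.mean([si.gr_power[c] for si in visit_indices_list])) for c in conditions},
        gr_freq={c: float(np.mean([si.gr_freq[c] for si in visit_indices_list])) for c in conditions},
        included=all(si.included for si in visit_indices_list) if included is None else included,
    )
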