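"""Cohort-level statistics: Spearman rank correlations of the gamma indices
(GSS, GEI) with sensitivity scores, age and behavioral covariates.

Per-scale p-values are reported without multiplicity correction; the report
carries nominal p and the row count so users can apply their own correction.
"""

from __future__ import annotations

from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

__all__ = ["spearman", "build_report"]

#: largest n for which the exact permutation null is enumerated (n! <= 362880)
EXACT_N_MAX = 9


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).  The
    p-value is exact (full enumeration of the n! rank permutations) for
    n <= 9 and the classical t approximation with n - 2 degrees of freedom
    above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input vector: rank correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)

    if n <= EXACT_N_MAX:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        ryc = perms - ry.mean()
        null = (rxc * ryc).sum(axis=1) / np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def build_report(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One Spearman correlation row per (x, y) variable pair.

    Columns: x, y, rho, p, n, significant (nominal ``alpha``, uncorrected).
    Rows with missing values in either column are dropped pairwise.
    """
    rows = []
    for xcol, ycol in pairs:
        for col in (xcol, ycol):
            if col not in table.columns:
                raise ValueError(f"unknown column {col!r}")
        sub = table[[xcol, ycol]].dropna()
        rho, p = spearman(sub[xcol].to_numpy(), sub[ycol].to_numpy())
        rows.append({"x": xcol, "y": ycol, "rho": rho, "p": p, "n": len(sub), "significant": p < alpha})
    return pd.DataFrame(rows, columns=["x", "y", "rho", "p", "n", "significant"])


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of a correlation report."""
    if report.empty:
        return "no correlations requested\n"
    lines = ["Spearman rank correlations", "-" * 54]
    for _, r in report.iterrows():
        star = " *" if r["significant"] else ""
        lines.append(f"{r['x']:<12} vs {r['y']:<22} R({r['n']}) = {r['rho']:+.2f}, p = {r['p']:.3f}{star}")
    lines.append("-" * 54)
    lines.append("* p < 0.05 (uncorrected)")
    return "\n".join(lines) + "\n"
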