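"""Three-stage pipeline: simulate -> analyze -> report.

The stages exchange data through the documented on-disk layout (HDF5 epochs +
TSV tables) and are also available as in-memory functions for programmatic use
(`analyze_epochs`, `analyze_cohort`), which large simulation studies should
prefer to avoid disk traffic.

Every run writes a provenance record (config, seed, package/library versions,
config hash) so outputs are reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, synth
from .cohort import build_report, format_report
from .errors import ConfigError
from .indices import SubjectIndices, average_visits, visit_indices
from .response import GammaResponse, analyze_condition, subject_gate
from .spectral import multitaper_window_power
from .synth import CohortConfig, EpochSet

__all__ = [
    "AnalysisParams",
    "PipelineConfig",
    "analyze_epochs",
    "analyze_cohort",
    "simulate",
    "analyze",
    "report",
    "run_pipeline",
    "make_fixture",
    "DEFAULT_PAIRS",
]

logger = logging.getLogger("gammares")

DEFAULT_PAIRS = (("gss", "sens_score"), ("gei", "sens_score"), ("gss", "age"), ("gei", "age"))


@dataclass
class AnalysisParams:
    """Analysis-stage constants.

    Defaults are the protocol's printed values: baseline (-0.9, 0) s and
    stimulation (0.3, 1.2) s windows, 10 Hz multitaper bandwidth, top-26
    vertex selection on 40-80 Hz, 30-115 Hz averaging range, 3-bin smoothing,
    35-90 Hz peak band, reliability alpha 1e-4.
    """

    baseline: tuple[float, float] = (-0.9, 0.0)
    stimulation: tuple[float, float] = (0.3, 1.2)
    bandwidth: float = 10.0
    vertex_band: tuple[float, float] = (40.0, 80.0)
    n_select: int = 26
    gamma_range: tuple[float, float] = (30.0, 115.0)
    peak_band: tuple[float, float] = (35.0, 90.0)
    smooth_window: int = 3
    reliability_alpha: float = 1e-4

    def validate(self) -> None:
        for name in ("baseline", "stimulation", "vertex_band", "gamma_range", "peak_band"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ConfigError(f"{name} bounds must be increasing")
        if self.smooth_window % 2 == 0 or self.smooth_window < 1:
            raise ConfigError("smooth_window must be odd and positive")
        if not 0 < self.reliability_alpha < 1:
            raise ConfigError("reliability_alpha must lie in (0, 1)")


@dataclass
class PipelineConfig:
    """Full run configuration: cohort generation + analysis parameters."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS

    def validate(self) -> None:
        self.cohort.validate()
        self.analysis.validate()

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        cohort_d = dict(d.get("cohort", {}))
        for key, val in list(cohort_d.items()):
            if isinstance(val, Mapping) and "mean" in val:
                cohort_d[key] = synth.ParamDist(**val)
            elif key == "velocities":
                cohort_d[key] = tuple(val)
        analysis_d = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in dict(d.get("analysis", {})).items()
        }
        pairs = tuple(tuple(p) for p in d.get("pairs", DEFAULT_PAIRS))
        try:
            return cls(cohort=CohortConfig(**cohort_d), analysis=AnalysisParams(**analysis_d), pairs=pairs)
        except TypeError as exc:
            raise ConfigError(f"bad configuration key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        cfg = cls.from_dict(data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig, stage: str) -> dict:
    import scipy

    return {
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.cohort.seed,
        "versions": {"gammares": __version__, "numpy": np.__version__, "scipy": scipy.__version__},
    }


def _write_provenance(out_dir: Path, config: PipelineConfig, stage: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"provenance_{stage}.json", "w") as f:
        json.dump(_provenance(config, stage), f, indent=2, sort_keys=True)
        f.write("\n")


# --------------------------------------------------------------------------
# in-memory analysis


def analyze_epochs(
    epochs_by_condition: Mapping[str, EpochSet],
    params: AnalysisParams | None = None,
) -> dict[str, GammaResponse]:
    """Window power -> normalized spectra -> GammaResponse, per condition."""
    from .errors import NoResponseError

    params = params or AnalysisParams()
    out: dict[str, GammaResponse] = {}
    for condition, es in epochs_by_condition.items():
        base = multitaper_window_power(es, params.baseline, params.bandwidth, window="baseline")
        stim = multitaper_window_power(es, params.stimulation, params.bandwidth, window="stimulation")
        try:
            out[condition] = analyze_condition(
                base,
                stim,
                condition=condition,
                velocity=es.velocity,
                visit=es.visit,
                vertex_band=params.vertex_band,
                n_select=params.n_select,
                gamma_range=params.gamma_range,
                peak_band=params.peak_band,
                smooth_window=params.smooth_window,
                alpha=params.reliability_alpha,
            )
        except NoResponseError:
            out[condition] = GammaResponse.no_response(condition, es.velocity, es.visit)
    return out


def analyze_cohort(config: PipelineConfig) -> tuple[list[synth.SubjectParams], pd.DataFrame, pd.DataFrame]:
    """Simulate and analyze a whole cohort in memory.

    Returns (subject params, per-visit+mean indices frame, per-condition
    response frame).  Epochs are generated per subject-visit and discarded,
    so memory stays bounded by one subject's data.
    """
    config.validate()
    cohort = synth.sample_cohort(config.cohort)
    index_records: list[SubjectIndices] = []
    response_rows = []
    for i, sp in enumerate(cohort):
        per_visit: dict[int, dict[str, GammaResponse]] = {}
        for visit in range(config.cohort.n_visits):
            epochs = synth.generate_subject_epochs(sp, config.cohort, i, visit)
            per_visit[visit] = analyze_epochs(epochs, config.analysis)
            del epochs
        included = subject_gate(per_visit)
        visit_records = []
        for visit, responses in per_visit.items():
            for r in responses.values():
                response_rows.append(
                    {
                        "subject_id": sp.subject_id,
                        "visit": visit,
                        "condition": r.condition,
                        "velocity": r.velocity,
                        "weighted_power": r.weighted_power,
                        "weighted_freq": r.weighted_freq,
                        "peak_freq": r.peak_freq,
                        "peak_power": r.peak_power,
                        "reliability_p": r.reliability_p,
                        "reliable": r.reliable,
                    }
                )
            visit_records.append(visit_indices(sp.subject_id, responses, visit=visit))
        index_records.extend(visit_records)
        index_records.append(average_visits(visit_records, included=included))
    return cohort, io.indices_to_frame(index_records), pd.DataFrame(response_rows)


# --------------------------------------------------------------------------
# disk stages


def simulate(config: PipelineConfig, out_dir: Path | str) -> Path:
    """Write one HDF5 file per subject x visit plus cohort.tsv."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = synth.sample_cohort(config.cohort)
    for i, sp in enumerate(cohort):
        for visit in range(config.cohort.n_visits):
            epochs = synth.generate_subject_epochs(sp, config.cohort, i, visit)
            io.write_subject_epochs(io.epochs_path(out_dir, sp.subject_id, visit), epochs)
            logger.info("simulated %s visit %d", sp.subject_id, visit)
    io.write_cohort_table(out_dir / "cohort.tsv", cohort, config.cohort.n_visits)
    _write_provenance(out_dir, config, "simulate")
    return out_dir


def analyze(config: PipelineConfig, in_dir: Path | str, out_dir: Path | str) -> Path:
    """Analyze every subject x visit HDF5 in ``in_dir``; write responses.tsv
    and indices.tsv (per-visit rows plus one 'mean' row per subject)."""
    config.validate()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    cohort_tsv = in_dir / "cohort.tsv"
    if not cohort_tsv.exists():
        raise FileNotFoundError(f"missing {cohort_tsv}")
    table = io.read_cohort_table(cohort_tsv)
    out_dir.mkdir(parents=True, exist_ok=True)

    index_records: list[SubjectIndices] = []
    response_rows = []
    for subject_id, sub in table.groupby("subject_id", sort=True):
        per_visit: dict[int, dict[str, GammaResponse]] = {}
        for visit in sorted(sub["visit"].unique()):
            path = io.epochs_path(in_dir, str(subject_id), int(visit))
            per_visit[int(visit)] = analyze_epochs(io.read_subject_epochs(path), config.analysis)
        included = subject_gate(per_visit)
        visit_records = []
        for visit, responses in sorted(per_visit.items()):
            for r in responses.values():
                response_rows.append(
                    {
                        "subject_id": subject_id,
                        "visit": visit,
                        "condition": r.condition,
                        "velocity": r.velocity,
                        "weighted_power": r.weighted_power,
                        "weighted_freq": r.weighted_freq,
                        "peak_freq": r.peak_freq,
                        "peak_power": r.peak_power,
                        "reliability_p": r.reliability_p,
                        "reliable": r.reliable,
                    }
                )
            visit_records.append(visit_indices(str(subject_id), responses, visit=visit))
        index_records.extend(visit_records)
        index_records.append(average_visits(visit_records, included=included))
        logger.info("analyzed %s (included=%s)", subject_id, included)

    pd.DataFrame(response_rows).to_csv(out_dir / "responses.tsv", sep="\t", index=False)
    io.indices_to_frame(index_records).to_csv(out_dir / "indices.tsv", sep="\t", index=False)
    _write_provenance(out_dir, config, "analyze")
    return out_dir


def report(
    config: PipelineConfig,
    indices_tsv: Path | str,
    cohort_tsv: Path | str,
    out_dir: Path | str,
) -> pd.DataFrame:
    """Merge subject-mean indices with the cohort table and write
    correlations.tsv plus a human-readable summary."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    indices = pd.read_csv(indices_tsv, sep="\t")
    cohort = io.read_cohort_table(cohort_tsv)

    means = indices[indices["visit"] == "mean"] if indices["visit"].dtype == object else indices
    means = means[means["included"]]
    subject_cols = cohort.drop(columns=["visit"]).groupby("subject_id", as_index=False).first()
    merged = means.merge(subject_cols, on="subject_id", how="inner")

    pairs = [p for p in config.pairs if p[0] in merged.columns and p[1] in merged.columns]
    rep = build_report(merged, pairs)
    rep.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    (out_dir / "correlations.txt").write_text(format_report(rep))
    _write_provenance(out_dir, config, "report")
    return rep


def run_pipeline(config: PipelineConfig, out_dir: Path | str) -> Path:
    """simulate + analyze + report into one run directory."""
    out_dir = Path(out_dir)
    data_dir = simulate(config, out_dir / "data")
    analyze(config, data_dir, out_dir)
    report(config, out_dir / "indices.tsv", data_dir / "cohort.tsv", out_dir)
    return out_dir


# --------------------------------------------------------------------------
# fixtures


def fixture_config(seed: int = 7, snr_mean: float = 2.5) -> PipelineConfig:
    """Miniature cohort for tests and docs: 3 subjects x 2 visits x 4
    conditions x 20 trials x 16 vertices, exaggerated snr so every subject
    passes the reliability gate."""
    cohort = CohortConfig(
        n_subjects=3,
        n_trials=20,
        n_vertices=16,
        n_visits=2,
        seed=seed,
        snr=synth.ParamDist(snr_mean, 0.0, 0.0, 10.0),
    )
    # three subjects are too few for a rank-correlation report (n >= 4)
    return PipelineConfig(cohort=cohort, pairs=())


def make_fixture(out_dir: Path | str, seed: int = 7, snr_mean: float = 2.5) -> Path:
    return simulate(fixture_config(seed=seed, snr_mean=snr_mean), out_dir)
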