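"""On-disk layout: HDF5 epoch containers and TSV tables.

Each subject x visit is one HDF5 file ``<subject_id>_visit<k>.h5``::

    /epochs/<condition>      float dataset (trials, vertices, samples)
        attrs: sfreq (Hz), t0 (s), velocity (deg/s), visit (int)

``cohort.tsv`` holds one row per subject x visit: subject_id, visit, age,
sens_score, plus ground-truth generative parameters in ``truth_*`` columns
(present only for simulated cohorts).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import h5py
import pandas as pd

from .indices import SubjectIndices
from .synth import EpochSet, SubjectParams

__all__ = [
    "epochs_path",
    "write_subject_epochs",
    "read_subject_epochs",
    "write_cohort_table",
    "read_cohort_table",
    "indices_to_frame",
]

TRUTH_COLUMNS = ("alpha", "beta", "f0", "gamma_slope", "snr", "pink_exponent")


def epochs_path(out_dir: Path | str, subject_id: str, visit: int) -> Path:
    return Path(out_dir) / f"{subject_id}_visit{visit}.h5"


def write_subject_epochs(path: Path | str, epochs: Mapping[str, EpochSet]) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("epochs")
        for condition, es in epochs.items():
            ds = grp.create_dataset(condition, data=es.data)
            ds.attrs["sfreq"] = es.sfreq
            ds.attrs["t0"] = es.t0
            ds.attrs["velocity"] = es.velocity
            ds.attrs["visit"] = es.visit


def read_subject_epochs(path: Path | str) -> dict[str, EpochSet]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, EpochSet] = {}
    with h5py.File(path, "r") as f:
        if "epochs" not in f:
            raise ValueError(f"{path}: missing /epochs group")
        for condition, ds in f["epochs"].items():
            for attr in ("sfreq", "t0", "velocity"):
                if attr not in ds.attrs:
                    raise ValueError(f"{path}: dataset {condition!r} missing attribute {attr!r}")
            out[condition] = EpochSet(
                condition=condition,
                velocity=float(ds.attrs["velocity"]),
                data=ds[()],
                sfreq=float(ds.attrs["sfreq"]),
                t0=float(ds.attrs["t0"]),
                visit=int(ds.attrs.get("visit", 0)),
            )
    if not out:
        raise ValueError(f"{path}: no condition datasets under /epochs")
    return out


def write_cohort_table(path: Path | str, cohort: Iterable[SubjectParams], n_visits: int) -> None:
    rows = []
    for p in cohort:
        for visit in range(n_visits):
            row = {"subject_id": p.subject_id, "visit": visit, "age": p.age, "sens_score": p.sens_score}
            row.update({f"truth_{c}": getattr(p, c) for c in TRUTH_COLUMNS})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def indices_to_frame(indices: Iterable[SubjectIndices]) -> pd.DataFrame:
    """Flatten SubjectIndices records into the ``indices.tsv`` layout."""
    rows = []
    for si in indices:
        row = {"subject_id": si.subject_id, "visit": si.visit, "gss": si.gss, "gei": si.gei, "included": si.included}
        for c, v in si.gr_power.items():
            row[f"power_{c}"] = v
        for c, v in si.gr_freq.items():
            row[f"freq_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
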