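"""Bundled calibration data and CSV I/O for two-dose experiment records.

The package ships the published priming-dose experiment summaries it was
calibrated against, transcribed row by row: chromatid-break and
chromosome-aberration counts in human lymphocytes (three Shadley studies)
and chromosomal-inversion frequencies in mouse prostate and spleen (two Day
studies).  Every record carries the raw counts (or frequencies), the printed
delta, and per-row provenance (source table label, footnote markers).

CSV schema (RFC-4180, UTF-8, header required)::

    study, source_table, tissue, endpoint, d1_gy, d2_gy, dt_h, t_h,
    n2_events, n2_denom, n12_events, n12_denom, delta, footnote

Doses are in Gy and times in hours internally; readers accept an mGy flag.
Frequency data (per-cell rates x 10^-3) are stored as events = frequency,
denom = 1 so that a single schema covers both count and frequency studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .delta import delta_from_counts

__all__ = [
    "ExperimentRecord",
    "DatasetBundle",
    "BUNDLED_DATASETS",
    "load_bundled",
    "read_records_csv",
    "write_records_csv",
    "validate_printed_deltas",
]

REQUIRED_COLUMNS = [
    "study",
    "endpoint",
    "d1_gy",
    "d2_gy",
    "dt_h",
    "t_h",
    "n2_events",
    "n2_denom",
    "n12_events",
    "n12_denom",
    "delta",
]
NUMERIC_COLUMNS = REQUIRED_COLUMNS[2:]

VALID_ENDPOINTS = {"chromatid_breaks", "chromosome_aberrations", "chromosomal_inversions"}


@dataclass(frozen=True)
class ExperimentRecord:
    """One two-dose observation: doses/times, event counts and the printed delta."""

    study: str
    endpoint: str
    d1: float
    d2: float
    dt: float
    T: float
    n2_events: float
    n2_denom: float
    n12_events: float
    n12_denom: float
    delta: float

    @property
    def yonezawa_effect(self) -> bool:
        return self.delta > 0


@dataclass(frozen=True)
class DatasetBundle:
    """A set of experiment records with provenance and endpoint class."""

    name: str
    records: pd.DataFrame
    endpoint_class: str  # "lesions" or "mutations"
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def to_records(self) -> list[ExperimentRecord]:
        return [
            ExperimentRecord(
                study=r.study,
                endpoint=r.endpoint,
                d1=r.d1_gy,
                d2=r.d2_gy,
                dt=r.dt_h,
                T=r.t_h,
                n2_events=r.n2_events,
                n2_denom=r.n2_denom,
                n12_events=r.n12_events,
                n12_denom=r.n12_denom,
                delta=r.delta,
            )
            for r in self.records.itertuples()
        ]


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("yonezawa.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


_BUNDLE_SPECS = {
    "shadley_lesions": (
        "table2.csv",
        lambda df: df[df.study.isin(["shadley_wolff", "shadley_etal"])],
        "lesions",
        "chromatid/isochromatid breaks in human lymphocytes "
        "(Shadley & Wolff; Shadley et al.); 7 + 16 rows",
    ),
    "shadley_aberrations": (
        "table2.csv",
        lambda df: df[df.study == "shadley_dai"],
        "lesions",
        "chromosome aberrations (dicentrics, rings, deletions) in human "
        "lymphocytes (Shadley & Dai); 10 rows",
    ),
    "all_table2": (
        "table2.csv",
        lambda df: df,
        "lesions",
        "pooled lymphocyte data of the three Shadley studies; 33 rows",
    ),
    "day_inversions": (
        "table3.csv",
        lambda df: df,
        "mutations",
        "chromosomal inversion frequencies (x10^-3) in mouse prostate and "
        "spleen (two Day studies); 8 rows",
    ),
}

BUNDLED_DATASETS = tuple(_BUNDLE_SPECS)

# fixed transcription sizes, asserted at load
_BUNDLE_SIZES = {
    "shadley_lesions": 23,
    "shadley_aberrations": 10,
    "all_table2": 33,
    "day_inversions": 8,
}


def load_bundled(name: str) -> DatasetBundle:
    """Load one of the bundled calibration datasets by name."""
    if name not in _BUNDLE_SPECS:
        raise KeyError(
            f"unknown bundled dataset {name!r}; available: {sorted(_BUNDLE_SPECS)}"
        )
    fname, select, endpoint_class, provenance = _BUNDLE_SPECS[name]
    df = select(_read_packaged(fname)).reset_index(drop=True)
    assert len(df) == _BUNDLE_SIZES[name], f"transcription size changed for {name}"
    return DatasetBundle(name=name, records=df, endpoint_class=endpoint_class, provenance=provenance)


def read_records_csv(
    path: Union[str, Path],
    dose_unit: str = "gy",
    endpoint_class: str = "lesions",
) -> DatasetBundle:
    """Read experiment records from CSV, validating and normalising to Gy/h.

    ``dose_unit``: "gy" or "mgy"; mGy doses are divided by 1000 at load.
    Row-level problems are reported with 1-based data row numbers.
    """
    if dose_unit.lower() not in {"gy", "mgy"}:
        raise ValueError(f"dose_unit must be 'gy' or 'mgy', got {dose_unit!r}")
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    errors: list[str] = []
    for col in NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            errors.append(f"row {i + 1}: non-numeric {col}={df.loc[i, col]!r}")
        df[col] = coerced
    if not errors:
        for i, r in df.iterrows():
            if r.d1_gy < 0 or r.d2_gy <= 0:
                errors.append(f"row {i + 1}: require d1 >= 0 and d2 > 0")
            if not (0 <= r.dt_h < r.t_h):
                errors.append(f"row {i + 1}: require 0 <= dt_h < t_h")
            if r.n2_denom <= 0 or r.n12_denom <= 0:
                errors.append(f"row {i + 1}: denominators must be > 0")
    if errors:
        raise ValueError(f"{path}: invalid records:\n  " + "\n  ".join(errors))
    if dose_unit.lower() == "mgy":
        df["d1_gy"] = df["d1_gy"] / 1000.0
        df["d2_gy"] = df["d2_gy"] / 1000.0
    return DatasetBundle(
        name=path.stem, records=df, endpoint_class=endpoint_class, provenance=f"read from {path}"
    )


def write_records_csv(bundle: DatasetBundle, path: Union[str, Path]) -> None:
    """Write a bundle to CSV in the package schema (doses in Gy)."""
    bundle.records.to_csv(path, index=False)


def validate_printed_deltas(bundle: DatasetBundle, tol: float = 5e-4) -> pd.DataFrame:
    """Recompute delta from the raw counts of each record and compare.

    Returns a per-record report with the recomputed delta, the absolute
    deviation from the stored value, and a pass flag at ``tol`` (default
    5e-4, i.e. agreement within the printed 3-decimal rounding).
    """
    df = bundle.records
    recomputed = np.array(
        [
            delta_from_counts(r.n2_events, r.n2_denom, r.n12_events, r.n12_denom)
            for r in df.itertuples()
        ]
    )
    # the stored deltas are printed half-up at 3 decimals
    abs_err = np.abs(np.floor(recomputed * 1000 + 0.5) / 1000 - df["delta"].to_numpy())
    return pd.DataFrame(
        {
            "study": df["study"],
            "delta_printed": df["delta"],
            "delta_recomputed": recomputed,
            "abs_err": abs_err,
            "passed": abs_err <= tol,
        }
    )
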