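"""Paired-data ingestion and bundled fixtures.

The built-in ``diabetes_srcr`` dataset pairs the duration of diabetes
(years) with serum creatinine (mg/dl) for 19 patients with available
pathology reports; serum creatinine above 1.4 mg/dl indicates diabetic
nephropathy, so the pair captures how long-standing diabetes relates to
kidney complications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bivariate import BivariateSample

__all__ = ["PairedDataset", "load_paired_data", "builtin_dataset", "DIABETES_SRCR"]

log = logging.getLogger("bfgmplx")


@dataclass(frozen=True)
class PairedDataset:
    """Named, validated paired-lifetime dataset."""

    name: str
    x1: np.ndarray
    x2: np.ndarray
    x1_label: str = "x1"
    x2_label: str = "x2"
    source: str = ""

    def __post_init__(self) -> None:
        sample = BivariateSample(self.x1, self.x2)  # validates
        object.__setattr__(self, "x1", sample.x1)
        object.__setattr__(self, "x2", sample.x2)

    @property
    def n(self) -> int:
        return self.x1.size

    def as_sample(self) -> BivariateSample:
        return BivariateSample(self.x1, self.x2)

    def to_csv(self, path) -> None:
        pd.DataFrame({self.x1_label: self.x1, self.x2_label: self.x2}).to_csv(
            path, index=False
        )


# 19 patients: duration of diabetes (years) and serum creatinine (mg/dl)
_DURATION = np.array(
    [7.4, 9, 10, 11, 12, 13, 13.75, 14.92, 15.8286, 16.9333,
     18, 19, 20, 21, 22, 23, 24, 26, 26.6]
)
_SRCR = np.array(
    [1.925, 1.5, 2, 1.6, 1.7, 1.7533, 1.54, 1.694, 1.8843, 1.8433,
     1.832, 1.59, 1.7833, 1.2, 1.792, 1.5, 1.5033, 2, 2.14]
)

DIABETES_SRCR = "diabetes_srcr"
_BUILTINS = {DIABETES_SRCR}


def builtin_dataset(name: str = DIABETES_SRCR) -> PairedDataset:
    """Return a bundled dataset by name (currently only ``diabetes_srcr``)."""
    if name != DIABETES_SRCR:
        raise KeyError(f"unknown dataset {name!r}; available: {sorted(_BUILTINS)}")
    return PairedDataset(
        name=name,
        x1=_DURATION.copy(),
        x2=_SRCR.copy(),
        x1_label="duration_years",
        x2_label="serum_creatinine_mg_dl",
        source="19 diabetic patients, pathology-lab serum creatinine records",
    )


def load_paired_data(
    path,
    columns: tuple = (0, 1),
    name: str | None = None,
) -> PairedDataset:
    """Read a two-column CSV of paired positive lifetimes.

    ``columns`` selects by header name or 0-based position.  Rows with
    missing, non-numeric or non-positive values are dropped with a logged
    count; fewer than 4 valid rows is an error.
    """
    df = pd.read_csv(path)
    cols = []
    for c in columns:
        if isinstance(c, int):
            if c >= df.shape[1]:
                raise ValueError(f"column index {c} out of range for {df.shape[1]} columns")
            cols.append(df.columns[c])
        else:
            if c not in df.columns:
                raise ValueError(f"column {c!r} not found; have {list(df.columns)}")
            cols.append(c)
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    valid = sub.notna().all(axis=1) & (sub > 0).all(axis=1)
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("dropped %d row(s) with missing/non-positive values", n_bad)
    sub = sub[valid]
    if len(sub) < 4:
        raise ValueError(f"only {len(sub)} valid rows; need at least 4")
    return PairedDataset(
        name=name or str(path),
        x1=sub[cols[0]].to_numpy(),
        x2=sub[cols[1]].to_numpy(),
        x1_label=str(cols[0]),
        x2_label=str(cols[1]),
        source=str(path),
    )
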