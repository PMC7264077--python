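"""Structural (volumetric and intensity) variables and the TV-CGV ratio.

The package consumes FreeSurfer-style tabular exports: volumes in mm^3
(thalamic volume averaged over hemispheres on load) and mean normalized
intensities on the usual 0-255 scale.  No image processing happens here.
The bespoke composite is the TV-CGV ratio — thalamic volume divided by
cortical gray matter volume — indexing thalamic mass relative to the
cortical mass it regulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

GROUP_COL = "group"
OUTCOME_COLS = (
    "wisc_vci", "wisc_pri", "wisc_wmi", "wisc_psi",
    "cbcl_int", "cbcl_ext", "brief_bri", "brief_mci",
    "beery_vmi", "beery_vp", "beery_mc",
)
STRUCTURAL_COLS = ("TV", "CGV", "ICV", "TI", "CGI", "CWI")
NEONATAL_COLS = ("GA", "sex", "infection", "SNAP", "morphine", "pain")

GA_RANGE = (22.0, 43.0)
INTENSITY_RANGE = (0.0, 255.0)


@dataclass(frozen=True)
class StructuralRecord:
    """Per-subject structural measures.

    TV: thalamic volume, mm^3 (hemispheric mean); CGV: cortical gray
    matter volume; ICV: intracranial volume; TI/CGI/CWI: mean normalized
    intensities of thalamus, cortical gray, and cortical white matter
    (the latter sampled 2 mm below the gray/white surface).
    """

    TV: float
    CGV: float
    ICV: float
    TI: float
    CGI: float
    CWI: float


@dataclass(frozen=True)
class NeonatalRecord:
    """Per-subject neonatal chart variables.

    GA in weeks; sex as a 0/1 indicator; infection as 0/1; SNAP is the
    day-1 illness-severity score; morphine is the log-transformed
    cumulative equivalent dose; pain the log-transformed count of
    skin-breaking procedures.
    """

    GA: float
    sex: float
    infection: float
    SNAP: float
    morphine: float
    pain: float


def tv_cgv_ratio(tv, cgv):
    """Thalamic volume over cortical gray matter volume (dimensionless).

    Accepts scalars or aligned arrays; CGV must be positive wherever TV
    is defined.
    """
    tv = np.asarray(tv, dtype=float)
    cgv = np.asarray(cgv, dtype=float)
    if np.any(cgv[~np.isnan(cgv)] <= 0):
        raise DataError("CGV must be positive to form the TV-CGV ratio")
    out = tv / cgv
    return float(out) if out.ndim == 0 else out


def mean_hemispheric_volume(left, right):
    """Average left/right volumes into the bilateral-mean convention."""
    return (np.asarray(left, dtype=float) + np.asarray(right, dtype=float)) / 2.0


def validate_cohort_table(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Check a cohort table and report per-analysis complete-case counts.

    Returns the (unmodified) table and a report dict with:

    * ``availability``: complete-case counts for the group analysis,
      the neurocognitive block, the structural (MRI) block and the
      neonatal-regression block (MRI + neonatal predictors);
    * ``flags``: out-of-range or inconsistent values, listed per rule.

    Raises DataError on an empty table or duplicate subject IDs;
    validation is idempotent.
    """
    if len(table) == 0:
        raise DataError("cohort table is empty")
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate subject IDs: {dupes}")

    def complete(cols) -> int:
        cols = [c for c in cols if c in table.columns]
        if not cols:
            return 0
        return int((~table[cols].isna().any(axis=1)).sum())

    availability = {
        "group": complete([GROUP_COL]),
        "neurocognitive": complete(list(OUTCOME_COLS)),
        "structural": complete(list(STRUCTURAL_COLS)),
        "neonatal_regression": complete(["TI", "GA", "sex", "infection", "SNAP", "morphine", "pain"]),
    }

    flags: list[dict] = []

    def flag(rule: str, rows) -> None:
        for rid in rows:
            flags.append({"subject_id": str(rid), "rule": rule})

    if "GA" in table.columns:
        ga = table["GA"]
        bad = table.index[(ga.notna()) & ((ga <= GA_RANGE[0]) | (ga >= GA_RANGE[1]))]
        flag(f"GA outside {GA_RANGE}", bad)
    for col in ("TV", "CGV", "ICV"):
        if col in table.columns:
            v = table[col]
            flag(f"{col} must be positive", table.index[(v.notna()) & (v <= 0)])
    if {"TV", "CGV", "ICV"} <= set(table.columns):
        sub = table[["TV", "CGV", "ICV"]].dropna()
        bad = sub.index[~((sub["TV"] < sub["CGV"]) & (sub["CGV"] < sub["ICV"]))]
        flag("expected TV < CGV < ICV", bad)
    for col in ("TI", "CGI", "CWI"):
        if col in table.columns:
            v = table[col]
            bad = table.index[(v.notna()) & ((v < INTENSITY_RANGE[0]) | (v > INTENSITY_RANGE[1]))]
            flag(f"{col} outside normalized intensity range {INTENSITY_RANGE}", bad)
    for col in ("SNAP",):
        if col in table.columns:
            v = table[col]
            flag(f"{col} must be non-negative", table.index[(v.notna()) & (v < 0)])

    return table, {"availability": availability, "flags": flags}
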