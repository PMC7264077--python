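"""File exchange formats.

Everything tabular is delimited text: the band-power matrix as a CSV
with ``s<idx>_<band>`` columns, the cohort table as CSV with the
documented column dictionary, ground truth and run manifests as JSON.
Continuous recordings are a flat binary matrix with a JSON sidecar
(sampling rate, shapes, units); lead fields an ``.npz`` container.
Vendor MEG formats are out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import SensorRecording
from .errors import ConfigError, DataError
from .forward import LeadField
from .synthetic import SyntheticCohortConfig, SyntheticTruth

#: Column dictionary of the cohort CSV.
COHORT_COLUMNS = {
    "subject_id": "unique subject identifier (index column)",
    "group": "ELGA / VLGA / Term",
    "wisc_vci": "WISC-IV verbal comprehension index",
    "wisc_pri": "WISC-IV perceptual reasoning index",
    "wisc_wmi": "WISC-IV working memory index",
    "wisc_psi": "WISC-IV processing speed index",
    "cbcl_int": "CBCL internalizing behavior T-score",
    "cbcl_ext": "CBCL externalizing behavior T-score",
    "brief_bri": "BRIEF behavioral regulation index",
    "brief_mci": "BRIEF metacognition index",
    "beery_vmi": "BEERY visual-motor integration",
    "beery_vp": "BEERY visual perception",
    "beery_mc": "BEERY motor coordination",
    "GA": "gestational age at birth, weeks",
    "sex": "0 = male, 1 = female",
    "infection": "neonatal infection, 0/1 (preterm only)",
    "SNAP": "day-1 illness severity score (preterm only)",
    "morphine": "log1p cumulative morphine-equivalent dose, mg/kg (preterm only)",
    "pain": "log1p number of skin-breaking procedures (preterm only)",
    "TV": "thalamic volume, mm^3, hemispheric mean (MRI subset)",
    "CGV": "cortical gray matter volume, mm^3 (MRI subset)",
    "ICV": "intracranial volume, mm^3 (MRI subset)",
    "TI": "mean normalized thalamic intensity (MRI subset)",
    "CGI": "mean normalized cortical gray intensity (MRI subset)",
    "CWI": "mean normalized cortical white intensity (MRI subset)",
}


def load_config(path) -> dict:
    """Read a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def cohort_config_from_dict(d: dict, seed: int | None = None) -> SyntheticCohortConfig:
    """Build a cohort config from a plain mapping (e.g. a parsed file)."""
    d = dict(d)
    if seed is not None:
        d["seed"] = seed
    if "seed" not in d:
        raise ConfigError("cohort config requires a seed")
    if "planted_salience" in d and d["planted_salience"] is not None:
        d["planted_salience"] = np.asarray(d["planted_salience"], dtype=float)
    for key in ("n_per_group", "n_mri_per_group", "bands"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    try:
        return SyntheticCohortConfig(**d)
    except TypeError as exc:
        raise ConfigError(f"invalid cohort config: {exc}") from exc


def save_truth(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))


def load_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def save_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path)


def load_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col=0)
    if len(table) == 0:
        raise DataError(f"cohort table {path} is empty")
    return table


def save_recording(rec: SensorRecording, stem) -> None:
    """Write ``<stem>.npy`` (+ ``<stem>_headpos.npy``) and ``<stem>.json``."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), rec.data)
    meta = {"fs": rec.fs, "n_channels": rec.n_channels, "n_samples": rec.n_samples,
            "units": "T", "head_position_units": "mm"}
    if rec.head_position is not None:
        np.save(stem.parent / (stem.name + "_headpos.npy"), rec.head_position)
        meta["head_position"] = stem.name + "_headpos.npy"
    (stem.with_suffix(".json")).write_text(json.dumps(meta, indent=2))


def load_recording(stem) -> SensorRecording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npy"))
    head = None
    if "head_position" in meta:
        head = np.load(stem.parent / meta["head_position"])
    return SensorRecording(data, meta["fs"], head)


def save_leadfield(lf: LeadField, path) -> None:
    np.savez(
        path, gain=lf.gain, source_positions=lf.source_positions,
        sensor_positions=lf.sensor_positions, sensor_orientations=lf.sensor_orientations,
        sphere_radius_mm=lf.sphere_radius_mm,
    )


def load_leadfield(path) -> LeadField:
    with np.load(path) as z:
        return LeadField(
            z["gain"], z["source_positions"], z["sensor_positions"],
            z["sensor_orientations"], float(z["sphere_radius_mm"]),
        )
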