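"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a three-group developmental cohort (extremely /
very low gestational age at birth, and term-born controls) at two
levels:

* directly as relative band-power matrices plus a cohort table of
  neurocognitive, structural and neonatal variables, with a planted
  "spectral slowing" group contrast and a single latent factor linking
  the brain pattern to outcomes and structure; or
* upstream, as sensor-level time series through the toy spherical
  forward model, for exercising the beamformer chain.

Effects are planted on unconstrained per-source band logits and passed
through a softmax, so relative power is compositional (non-negative,
summing to one over bands) by construction.  All ground truth needed
for recovery tests — the planted salience map, group contrast, latent
scores and generating regression coefficients — is returned alongside
the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .bands import BAND_NAMES
from .containers import BandPowerMatrix, SensorRecording
from .errors import ConfigError
from .forward import LeadField, make_toy_leadfield  # noqa: F401  (re-exported)
from .spectral import bandpass
from .bands import CANONICAL_BANDS

GROUP_NAMES = ("ELGA", "VLGA", "Term")

#: The 11 neurocognitive outcome variables: four WISC index scores, two
#: CBCL behavior scales, two BRIEF executive-function indices and three
#: BEERY visual-motor subscales.
OUTCOME_VARS = (
    "wisc_vci", "wisc_pri", "wisc_wmi", "wisc_psi",
    "cbcl_int", "cbcl_ext", "brief_bri", "brief_mci",
    "beery_vmi", "beery_vp", "beery_mc",
)

#: (mean, SD) of each outcome on its published scale.
OUTCOME_SCALES = {
    "wisc_vci": (100.0, 14.0), "wisc_pri": (104.0, 15.0),
    "wisc_wmi": (99.0, 12.0), "wisc_psi": (98.0, 14.0),
    "cbcl_int": (50.5, 10.8), "cbcl_ext": (47.3, 10.5),
    "brief_bri": (51.0, 11.5), "brief_mci": (52.0, 12.5),
    "beery_vmi": (97.0, 11.0), "beery_vp": (105.0, 16.0), "beery_mc": (93.5, 10.5),
}

#: Loadings of each outcome on the brain latent factor (higher latent =
#: more slowing).  Cognitive/motor scores load negatively, behavior
#: problem scales positively.
DEFAULT_LATENT_LOADINGS = {
    "wisc_vci": -0.5, "wisc_pri": -0.5, "wisc_wmi": -0.5, "wisc_psi": -0.5,
    "cbcl_int": 0.3, "cbcl_ext": 0.3, "brief_bri": 0.3, "brief_mci": 0.3,
    "beery_vmi": -0.4, "beery_vp": -0.4, "beery_mc": -0.4,
}

STRUCTURAL_VARS = ("TV", "CGV", "ICV", "TI", "CGI", "CWI")

#: Group (mean, SD) for structural variables, mm^3 for volumes and
#: normalized-intensity units for intensities.  TI for the preterm
#: groups is generated from the neonatal linear model instead.
DEFAULT_STRUCTURAL_PARAMS = {
    "TV": {"ELGA": (6951.0, 697.0), "VLGA": (7494.0, 745.0), "Term": (8268.0, 603.0)},
    "CGV": {"ELGA": (536606.0, 40984.0), "VLGA": (555204.0, 57458.0), "Term": (589950.0, 60000.0)},
    "ICV": {"ELGA": (1515881.0, 122911.0), "VLGA": (1534179.0, 142595.0), "Term": (1589423.0, 58071.0)},
    "TI": {"ELGA": (88.0, 1.8), "VLGA": (89.2, 1.6), "Term": (89.5, 1.5)},
    "CGI": {"ELGA": (88.0, 8.7), "VLGA": (91.5, 8.2), "Term": (88.0, 6.7)},
    "CWI": {"ELGA": (108.0, 7.9), "VLGA": (114.7, 10.3), "Term": (110.0, 8.5)},
}

#: Correlation of each structural variable's within-group deviation with
#: the brain latent factor (higher latent = more slowing).
DEFAULT_STRUCTURAL_COUPLING = {
    "TV": -0.4, "CGV": -0.1, "ICV": 0.0, "TI": -0.4, "CGI": 0.3, "CWI": 0.2,
}

NEONATAL_VARS = ("GA", "sex", "infection", "SNAP", "morphine", "pain")

#: Distribution parameters of the neonatal predictors for the two
#: preterm groups (term-born controls have no neonatal chart data).
DEFAULT_NEONATAL_PARAMS = {
    "GA": {"ELGA": (27.1, 1.36), "VLGA": (31.0, 1.2), "Term": (39.9, 0.93)},
    "p_female": 0.5,
    "p_infection": {"ELGA": 0.54, "VLGA": 0.13},
    "SNAP": {"ELGA": (22.5, 9.73), "VLGA": (5.6, 7.5)},
    "morphine_mg_kg": {"ELGA": (2.7, 5.74), "VLGA": (0.06, 0.18)},
    "pain_count": {"ELGA": (153.6, 68.7), "VLGA": (65.1, 50.9)},
}

#: Coefficients generating thalamic intensity from the neonatal
#: predictors (morphine and pain enter log-transformed).
DEFAULT_NEONATAL_BETAS = {
    "GA": -0.104, "sex": -14.14, "infection": -1.084, "SNAP": -0.009,
    "morphine": -2.948, "pain": -0.064, "sex_x_GA": 0.487,
}

#: Population fraction of preterm TI variance explained by the neonatal
#: linear predictor.  Chosen so that an in-sample OLS fit with ~37
#: complete cases and 7 predictors shows R^2 near 0.37: sample R^2
#: carries optimism of roughly (1 - rho^2) * p / (n - 1), so the
#: generating rho^2 is the optimism-corrected 0.22.
DEFAULT_TI_R2 = 0.22

#: Baseline relative power per band (delta..gamma) at rest.
BASE_BAND_FRACTIONS = np.array([0.25, 0.20, 0.30, 0.15, 0.10])


@dataclass
class SyntheticCohortConfig:
    """Everything the power-level cohort generator needs; seed mandatory."""

    seed: int
    n_per_group: tuple[int, int, int] = (23, 36, 39)
    n_sources: int = 50
    bands: tuple[str, ...] = BAND_NAMES
    contrast_effect: float = 1.0
    planted_salience: np.ndarray | None = None     # (n_sources, n_bands)
    latent_loadings: dict[str, float] | None = None
    structural_params: dict | None = None
    structural_coupling: dict[str, float] | None = None
    neonatal_params: dict | None = None
    neonatal_betas: dict[str, float] | None = None
    ti_r2: float = DEFAULT_TI_R2
    noise_sd: float = 0.15
    n_mri_per_group: tuple[int, int, int] = (13, 24, 13)

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 2 for n in self.n_per_group):
            raise ConfigError("need three groups with n >= 2 each")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.n_sources < 1:
            raise ConfigError("n_sources must be >= 1")
        if self.planted_salience is not None:
            sal = np.asarray(self.planted_salience, dtype=float)
            if sal.shape != (self.n_sources, len(self.bands)):
                raise ConfigError(
                    f"planted_salience shape {sal.shape} does not match "
                    f"(n_sources, n_bands) = ({self.n_sources}, {len(self.bands)})"
                )
            norm = np.linalg.norm(sal)
            if norm == 0:
                raise ConfigError("planted_salience must be non-zero")
            self.planted_salience = sal / norm


@dataclass
class SyntheticTruth:
    """Ground truth recorded for recovery tests."""

    planted_salience: np.ndarray       # (n_sources, n_bands), unit norm
    planted_contrast: np.ndarray       # (3,), unit norm, ELGA vs rest
    latent_scores: np.ndarray          # (n_subjects,), z-scored
    generating_coefficients: dict[str, float]
    latent_loadings: dict[str, float]
    contrast_effect: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "planted_salience": self.planted_salience.tolist(),
            "planted_contrast": self.planted_contrast.tolist(),
            "latent_scores": self.latent_scores.tolist(),
            "generating_coefficients": dict(self.generating_coefficients),
            "latent_loadings": dict(self.latent_loadings),
            "contrast_effect": self.contrast_effect,
        }


def default_planted_salience(n_sources: int, n_bands: int = 5) -> np.ndarray:
    """A spatially smooth 'slowing' pattern: raised delta/theta, lowered
    alpha/beta, neutral gamma, with unit Euclidean norm and zero band-sum
    per source (a pure redistribution of power)."""
    if n_bands != 5:
        raise ConfigError("the default salience is defined for the five canonical bands")
    i = np.arange(n_sources)
    # smooth anterior-to-posterior-like spatial profile
    profile = 0.4 + np.exp(-0.5 * ((i - n_sources / 3.0) / (n_sources / 6.0)) ** 2)
    band_pattern = np.array([1.0, 1.0, -1.0, -1.0, 0.0])
    sal = profile[:, None] * band_pattern[None, :]
    return sal / np.linalg.norm(sal)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _gamma_draw(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size)


def _truncated_normal(rng, mean, sd, size, lo=-np.inf, hi=np.inf):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def generate_power_cohort(
    config: SyntheticCohortConfig,
) -> tuple[BandPowerMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a relative-power matrix, cohort table and ground truth.

    The ELGA-like group's band logits are shifted along the planted
    salience by ``contrast_effect`` (logit units); each subject's latent
    score is the projection of their logit field on the salience, and
    outcomes / structural variables are coupled to its z-score through
    the configured loadings.  Identical config and seed reproduce the
    output bit-identically.
    """
    rng = np.random.default_rng(config.seed)
    n_bands = len(config.bands)
    n_src = config.n_sources
    n_per = tuple(config.n_per_group)
    n = sum(n_per)

    sal = config.planted_salience
    if sal is None:
        sal = default_planted_salience(n_src, n_bands)

    group = np.repeat(np.arange(3), n_per)
    group_names = np.array(GROUP_NAMES)[group]
    is_elga = group == 0
    is_preterm = group < 2

    if BASE_BAND_FRACTIONS.size != n_bands:
        raise ConfigError("base band fractions are defined for five bands")
    base_logits = np.log(BASE_BAND_FRACTIONS)

    logits = base_logits[None, None, :] + rng.normal(0.0, config.noise_sd, (n, n_src, n_bands))
    logits[is_elga] += config.contrast_effect * sal[None, :, :]
    powers = _softmax(logits)

    sal_flat = sal.ravel()
    latent_raw = logits.reshape(n, -1) @ sal_flat
    latent_z = (latent_raw - latent_raw.mean()) / latent_raw.std()
    # within-group latent deviation: the group-level component of the
    # latent is carried by the planted group means / neonatal model, so
    # structural coupling uses only the subject-level deviation to avoid
    # double-counting group separation (and confounding the neonatal
    # predictors, which differ by group).
    latent_within = latent_raw.copy()
    for g in range(3):
        latent_within[group == g] -= latent_raw[group == g].mean()
    latent_within /= latent_within.std()

    loadings = dict(DEFAULT_LATENT_LOADINGS if config.latent_loadings is None else config.latent_loadings)
    cohort: dict[str, Any] = {
        "subject_id": [f"sub{i:03d}" for i in range(n)],
        "group": group_names,
    }
    for var in OUTCOME_VARS:
        mu, sd = OUTCOME_SCALES[var]
        rho = float(loadings.get(var, 0.0))
        if not -1.0 <= rho <= 1.0:
            raise ConfigError(f"latent loading for {var} must be in [-1, 1]")
        eps = rng.standard_normal(n)
        cohort[var] = mu + sd * (rho * latent_z + np.sqrt(1 - rho**2) * eps)

    # ---- neonatal predictors (preterm groups only) --------------------
    npar = DEFAULT_NEONATAL_PARAMS if config.neonatal_params is None else config.neonatal_params
    ga = np.empty(n)
    for g, name in enumerate(GROUP_NAMES):
        m, s = npar["GA"][name]
        ga[group == g] = _truncated_normal(rng, m, s, (group == g).sum(), 22.5, 42.5)
    sex = (rng.random(n) < npar["p_female"]).astype(float)
    infection = np.full(n, np.nan)
    snap = np.full(n, np.nan)
    morphine = np.full(n, np.nan)
    pain = np.full(n, np.nan)
    for g, name in ((0, "ELGA"), (1, "VLGA")):
        idx = group == g
        k = idx.sum()
        infection[idx] = (rng.random(k) < npar["p_infection"][name]).astype(float)
        snap[idx] = np.clip(rng.normal(*npar["SNAP"][name], k), 0, None)
        morphine[idx] = np.log1p(_gamma_draw(rng, *npar["morphine_mg_kg"][name], k))
        pain[idx] = np.log1p(_gamma_draw(rng, *npar["pain_count"][name], k))
    cohort["GA"] = ga
    cohort["sex"] = sex
    cohort["infection"] = infection
    cohort["SNAP"] = snap
    cohort["morphine"] = morphine
    cohort["pain"] = pain

    # ---- structural variables (MRI subset only) -----------------------
    spar = DEFAULT_STRUCTURAL_PARAMS if config.structural_params is None else config.structural_params
    coup = dict(DEFAULT_STRUCTURAL_COUPLING if config.structural_coupling is None else config.structural_coupling)
    has_mri = np.zeros(n, dtype=bool)
    offset = 0
    for g in range(3):
        k = min(config.n_mri_per_group[g], n_per[g])
        chosen = offset + rng.choice(n_per[g], size=k, replace=False)
        has_mri[chosen] = True
        offset += n_per[g]

    structural: dict[str, np.ndarray] = {}
    for var in ("TV", "CGV", "ICV", "CGI", "CWI"):
        rho = float(coup.get(var, 0.0))
        vals = np.empty(n)
        mix = rho * latent_within + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
        for g, name in enumerate(GROUP_NAMES):
            m, s = spar[var][name]
            vals[group == g] = m + s * mix[group == g]
        structural[var] = vals

    # thalamic intensity: neonatal linear model for preterms, group
    # distribution for terms; residual variance scaled to the target R^2
    betas = dict(DEFAULT_NEONATAL_BETAS if config.neonatal_betas is None else config.neonatal_betas)
    ti = np.empty(n)
    Xb = (
        betas["GA"] * ga
        + betas["sex"] * sex
        + np.nan_to_num(betas["infection"] * infection)
        + np.nan_to_num(betas["SNAP"] * snap)
        + np.nan_to_num(betas["morphine"] * morphine)
        + np.nan_to_num(betas["pain"] * pain)
        + betas["sex_x_GA"] * sex * ga
    )
    pre = is_preterm
    v_signal = Xb[pre].var()
    r2 = config.ti_r2
    if not 0 < r2 < 1:
        raise ConfigError("ti_r2 must be in (0, 1)")
    v_rest = v_signal * (1 - r2) / r2
    rho_ti = float(coup.get("TI", 0.0))
    rest = np.sqrt(v_rest) * (
        rho_ti * latent_within[pre]
        + np.sqrt(max(0.0, 1 - rho_ti**2)) * rng.standard_normal(pre.sum())
    )
    ti_target_mean = 0.5 * (spar["TI"]["ELGA"][0] + spar["TI"]["VLGA"][0])
    ti[pre] = ti_target_mean + (Xb[pre] - Xb[pre].mean()) + rest
    m_t, s_t = spar["TI"]["Term"]
    term = ~pre
    ti[term] = m_t + s_t * (
        rho_ti * latent_within[term]
        + np.sqrt(max(0.0, 1 - rho_ti**2)) * rng.standard_normal(term.sum())
    )
    structural["TI"] = ti

    for var in STRUCTURAL_VARS:
        vals = structural[var].copy()
        vals[~has_mri] = np.nan
        cohort[var] = vals
    # neonatal chart data is unavailable for term-born controls
    for var in ("infection", "SNAP", "morphine", "pain"):
        cohort[var] = np.where(is_preterm, cohort[var], np.nan)

    table = pd.DataFrame(cohort).set_index("subject_id")
    bpm = BandPowerMatrix(powers, tuple(config.bands), list(table.index))
    contrast = np.array([1.0, -0.5, -0.5])
    truth = SyntheticTruth(
        planted_salience=sal,
        planted_contrast=contrast / np.linalg.norm(contrast),
        latent_scores=latent_z,
        generating_coefficients=betas,
        latent_loadings=loadings,
        contrast_effect=config.contrast_effect,
    )
    return bpm, table, truth


# ---------------------------------------------------------------------------
# sensor-level generation through the toy forward model
# ---------------------------------------------------------------------------

def _tangential_orientations(leadfield: LeadField, rng: np.random.Generator) -> np.ndarray:
    """Random unit orientations tangential to the sphere at each source."""
    pos = leadfield.source_positions
    radial = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    out = np.empty_like(radial)
    for i, rad in enumerate(radial):
        helper = np.array([0.0, 0.0, 1.0])
        if abs(rad @ helper) > 0.95:
            helper = np.array([1.0, 0.0, 0.0])
        t1 = np.cross(rad, helper)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(rad, t1)
        phi = rng.uniform(0, 2 * np.pi)
        out[i] = np.cos(phi) * t1 + np.sin(phi) * t2
    return out


def generate_sensor_recording(
    leadfield: LeadField,
    source_spectra: np.ndarray,
    duration_s: float,
    fs: float = 1200.0,
    noise_sd: float = 0.0,
    motion_trace_params: dict | None = None,
    seed: int = 0,
    orientations: np.ndarray | None = None,
    bands=CANONICAL_BANDS,
    return_sources: bool = False,
):
    """Simulate a sensor recording from band-limited source activity.

    Each source emits a sum of band-limited noise processes with the
    requested per-band RMS amplitudes (``source_spectra``, shape
    (n_sources, n_bands), in A*m); sensor data are the lead-field
    projection plus white sensor noise of SD ``noise_sd`` (T).  A
    synthetic head-position trace of three fiducial coils is attached;
    ``motion_trace_params`` (keys ``onset_s``, ``duration_s``,
    ``amplitude_mm``) plants a displacement excursion in a known window.
    """
    rng = np.random.default_rng(seed)
    spectra = np.atleast_2d(np.asarray(source_spectra, dtype=float))
    if spectra.shape[0] != leadfield.n_sources or spectra.shape[1] != len(bands):
        raise ConfigError(
            f"source_spectra must be (n_sources, n_bands) = "
            f"({leadfield.n_sources}, {len(bands)}), got {spectra.shape}"
        )
    max_hi = max(b.hi for b in bands)
    if fs <= 2 * max_hi:
        raise ConfigError(f"fs={fs} must exceed twice the highest band edge ({max_hi} Hz)")
    n_samp = int(round(duration_s * fs))
    if orientations is None:
        orientations = _tangential_orientations(leadfield, rng)
    gains = leadfield.oriented_gain(orientations)  # (n_sources, n_sensors)

    source_ts = np.zeros((leadfield.n_sources, n_samp))
    for s in range(leadfield.n_sources):
        for j, band in enumerate(bands):
            amp = spectra[s, j]
            if amp == 0:
                continue
            x = bandpass(rng.standard_normal(n_samp), band, fs)
            sd = x.std()
            if sd > 0:
                source_ts[s] += amp * x / sd
    data = gains.T @ source_ts
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)

    # three fiducial coils (nasion, left/right preauricular), mm
    fid = np.array([[0.0, 85.0, -20.0], [-70.0, 0.0, -30.0], [70.0, 0.0, -30.0]])
    head_position = np.repeat(fid[:, :, None], n_samp, axis=2)
    if motion_trace_params:
        a = int(round(motion_trace_params["onset_s"] * fs))
        b = a + int(round(motion_trace_params["duration_s"] * fs))
        head_position[:, 0, a:b] += motion_trace_params["amplitude_mm"]
    rec = SensorRecording(data, fs, head_position)
    if return_sources:
        return rec, source_ts
    return rec
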