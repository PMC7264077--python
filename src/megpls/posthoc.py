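"""Secondary analyses downstream of the PLS fits.

Four families of computation:

* spatial correlation between two bootstrap-ratio (z-score) maps, used
  to quantify how similar two analyses' reliability patterns are;
* tail-power association: per band, select the locations in the skewed
  2.5% tail of the z-scores, average each subject's relative power over
  them, and correlate that average with a covariate per group and pooled;
* Pearson correlation of mean-centered-PLS brain scores with volumetric
  variables;
* ordinary least squares regression of a structural outcome (thalamic
  intensity or the TV-CGV ratio) on the seven neonatal predictors
  (GA, sex, infection, SNAP, morphine, pain, sex x GA).

The regression is a thin surface over statsmodels OLS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .containers import BandPowerMatrix
from .errors import ConfigError, DataError, NumericalError

DEFAULT_TAIL_FRACTION = 0.025

#: Predictors of the neonatal regression; "sex_x_GA" is formed in-place.
NEONATAL_PREDICTORS = ("GA", "sex", "infection", "SNAP", "morphine", "pain", "sex_x_GA")


@dataclass
class ZMap:
    """Bootstrap-ratio map over sources x bands, with provenance."""

    values: np.ndarray  # (n_sources, n_bands)
    band_names: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("ZMap values must be 2-d (sources x bands)")
        if self.values.shape[1] != len(self.band_names):
            raise ConfigError("band axis does not match band_names")
        if not np.all(np.isfinite(self.values)):
            raise DataError("ZMap contains non-finite values")


def correlate_zmaps(z1: ZMap, z2: ZMap) -> float:
    """Pearson correlation of two z-maps over all source x band features.

    The maps must share the same feature grid (shape and band order);
    the correlation pools every location and band into one vector, so it
    is symmetric and invariant to common affine rescaling of either map.
    """
    if z1.values.shape != z2.values.shape or z1.band_names != z2.band_names:
        raise ConfigError(
            f"z-maps are not aligned: {z1.values.shape}/{z1.band_names} vs "
            f"{z2.values.shape}/{z2.band_names}"
        )
    a = z1.values.ravel()
    b = z2.values.ravel()
    return float(stats.pearsonr(a, b).statistic)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def select_tail_locations(z_band: np.ndarray, fraction: float) -> tuple[np.ndarray, float]:
    """Locations in the skewed tail of one band's z-scores.

    The tail side follows the sign of the bias-corrected sample skewness
    (negative skew -> most-negative tail, otherwise most-positive).
    Exactly ceil(fraction * n_sources) locations are returned; ties at
    the cutoff are broken by ascending source index.
    """
    if not 0 < fraction < 0.5:
        raise ConfigError("tail fraction must be in (0, 0.5)")
    z_band = np.asarray(z_band, dtype=float)
    n = len(z_band)
    k = math.ceil(fraction * n)
    skew = float(stats.skew(z_band, bias=False)) if n > 2 else 0.0
    idx = np.arange(n)
    if skew < 0:
        order = np.lexsort((idx, z_band))          # most negative first
    else:
        order = np.lexsort((idx, -z_band))         # most positive first
    return np.sort(order[:k]), skew


@dataclass
class TailAssociation:
    """Per-band result of the tail-power association analysis."""

    band: str
    selected: np.ndarray          # source indices in the skewed tail
    skewness: float
    mean_power: np.ndarray        # (n_subjects,) tail-averaged relative power
    pooled: tuple[float, float, int]              # (r, p, n)
    per_group: dict[str, tuple[float, float, int]] = field(default_factory=dict)


def tail_power_association(
    zmap: ZMap,
    power: BandPowerMatrix,
    covariate: np.ndarray,
    groups: np.ndarray | None = None,
    fraction: float = DEFAULT_TAIL_FRACTION,
) -> dict[str, TailAssociation]:
    """Correlate tail-averaged band power with a covariate.

    For each band: find the skewed-side ``fraction`` tail of the z-map,
    average each subject's relative power over those locations, and
    report the Pearson correlation with ``covariate`` pooled over all
    subjects and within each group.  Subjects with a missing covariate
    are dropped pairwise.
    """
    if zmap.values.shape[0] != power.n_sources or zmap.band_names != power.band_names:
        raise ConfigError("z-map and power matrix are not on the same feature grid")
    covariate = np.asarray(covariate, dtype=float)
    if len(covariate) != power.n_subjects:
        raise ConfigError("covariate length must match the number of subjects")
    valid = ~np.isnan(covariate)
    out: dict[str, TailAssociation] = {}
    for j, band in enumerate(power.band_names):
        selected, skew = select_tail_locations(zmap.values[:, j], fraction)
        mean_power = power.values[:, selected, j].mean(axis=1)
        pooled_r, pooled_p = _pearson_with_p(mean_power[valid], covariate[valid])
        res = TailAssociation(
            band=band, selected=selected, skewness=skew, mean_power=mean_power,
            pooled=(pooled_r, pooled_p, int(valid.sum())),
        )
        if groups is not None:
            groups = np.asarray(groups)
            for lab in pd.unique(groups):
                m = valid & (groups == lab)
                if m.sum() >= 4:
                    r, p = _pearson_with_p(mean_power[m], covariate[m])
                    res.per_group[str(lab)] = (r, p, int(m.sum()))
        out[band] = res
    return out


def correlate_scores_with_volumes(
    scores: np.ndarray, volumes: pd.DataFrame | dict, lv: int = 0
) -> dict[str, tuple[float, float, int]]:
    """Pearson r (with two-sided t-based p) of brain scores vs each volume.

    ``scores`` may be (n,) or (n, n_lv); each volume column is handled
    separately with pairwise deletion of missing values.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 2:
        scores = scores[:, lv]
    if isinstance(volumes, dict):
        volumes = pd.DataFrame(volumes)
    out: dict[str, tuple[float, float, int]] = {}
    for col in volumes.columns:
        v = volumes[col].to_numpy(dtype=float)
        m = ~np.isnan(v) & ~np.isnan(scores)
        n = int(m.sum())
        if n < 4:
            raise DataError(f"fewer than 4 paired observations for {col}")
        if np.std(v[m]) == 0:
            raise DataError(f"volume variable {col} is constant")
        r, p = _pearson_with_p(scores[m], v[m])
        out[str(col)] = (r, p, n)
    return out


@dataclass
class RegressionResult:
    """OLS fit of a structural outcome on the neonatal predictors."""

    outcome: str
    betas: pd.Series
    p_values: pd.Series
    f_statistic: float
    df: tuple[int, int]
    r_squared: float
    n: int
    model_p_value: float

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table (predictor, beta, p) mirroring a journal layout."""
        return pd.DataFrame({"Beta": self.betas, "Sig.": self.p_values})

    def summary(self) -> str:
        lines = [
            f"OLS: {self.outcome} ~ {' + '.join(NEONATAL_PREDICTORS)}",
            f"  n = {self.n}, F({self.df[0]}, {self.df[1]}) = {self.f_statistic:.2f}, "
            f"p = {self.model_p_value:.4f}, R^2 = {self.r_squared:.2f}",
        ]
        for name in self.betas.index:
            lines.append(f"  {name:>10}: {self.betas[name]:+10.3f}  (p = {self.p_values[name]:.3f})")
        return "\n".join(lines)


def neonatal_regression(table: pd.DataFrame, outcome: str) -> RegressionResult:
    """OLS of ``outcome`` on GA, sex, infection, SNAP, morphine, pain and
    the sex x GA interaction, complete cases only, with intercept.

    Raises NumericalError on perfect collinearity among the predictors.
    """
    needed = ["GA", "sex", "infection", "SNAP", "morphine", "pain", outcome]
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise DataError(f"cohort table lacks columns: {missing_cols}")
    data = table[needed].dropna().astype(float)
    n = len(data)
    if n < 10:
        raise DataError(f"only {n} complete cases; too few for a 7-predictor regression")
    X = data[["GA", "sex", "infection", "SNAP", "morphine", "pain"]].copy()
    X["sex_x_GA"] = X["sex"] * X["GA"]
    Xd = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise NumericalError("perfectly collinear predictors: design matrix is rank deficient")
    fit = sm.OLS(data[outcome], Xd).fit()
    return RegressionResult(
        outcome=outcome,
        betas=fit.params.drop("const"),
        p_values=fit.pvalues.drop("const"),
        f_statistic=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        r_squared=float(fit.rsquared),
        n=n,
        model_p_value=float(fit.f_pvalue),
    )
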