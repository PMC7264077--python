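"""Linearly constrained minimum-variance (LCMV) source projection.

A scalar beamformer: per source, the dipole orientation is chosen
data-driven as the direction maximizing the vector filter's output power
(restricted to the tangential plane, since radial dipoles are silent in
a spherical conductor), then the classic unit-gain minimum-variance
weights w = C^-1 l / (l' C^-1 l) are formed from a diagonally loaded
sensor covariance.  Weights are computed separately per frequency band
from band-filtered epochs, so each band's spatial filter is optimized
for the covariance structure at those frequencies.

No weight normalization is applied: downstream analyses use relative
power, which already removes the beamformer's depth-dependent gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bands import Band, CANONICAL_BANDS
from .containers import EpochSet
from .errors import ConfigError, DataError, NumericalError
from .forward import LeadField
from .spectral import bandpass, relative_power

DEFAULT_REG_FRACTION = 0.05


@dataclass
class SensorCovariance:
    """Pooled, diagonally loaded sensor covariance (channels x channels)."""

    matrix: np.ndarray
    regularization: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ConfigError("covariance must be square")


@dataclass
class SpatialFilter:
    """Unit-gain LCMV weights with the per-source optimal orientations."""

    weights: np.ndarray        # (n_sources, n_channels)
    orientations: np.ndarray   # (n_sources, 3) unit vectors
    band: Band | None = None
    reg_fraction: float = DEFAULT_REG_FRACTION


def sensor_covariance(epochs: EpochSet, reg_fraction: float = DEFAULT_REG_FRACTION) -> SensorCovariance:
    """Covariance pooled over epochs after per-epoch mean removal,
    with ``reg_fraction`` x mean eigenvalue added to the diagonal.

    Raises NumericalError if the regularized matrix is not positive
    definite (e.g. rank-deficient data with reg_fraction=0).
    """
    if not np.all(np.isfinite(epochs.data)):
        raise DataError("epochs contain non-finite values")
    if reg_fraction < 0:
        raise ConfigError("reg_fraction must be non-negative")
    n_ep, n_ch, n_s = epochs.data.shape
    if n_ep * n_s <= n_ch:
        warnings.warn(
            f"covariance from {n_ep * n_s} samples for {n_ch} channels is poorly conditioned",
            stacklevel=2,
        )
    demeaned = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    flat = demeaned.transpose(1, 0, 2).reshape(n_ch, -1)
    cov = flat @ flat.T / (flat.shape[1] - n_ep)  # ddof: one mean per epoch
    cov = 0.5 * (cov + cov.T)
    # mean eigenvalue == mean of the diagonal (trace / n)
    loading = reg_fraction * np.trace(cov) / n_ch
    cov = cov + loading * np.eye(n_ch)
    min_eig = np.linalg.eigvalsh(cov)[0]
    if min_eig <= 0:
        raise NumericalError(
            "regularized sensor covariance is singular "
            f"(min eigenvalue {min_eig:.3e}); increase reg_fraction"
        )
    return SensorCovariance(cov, reg_fraction)


def lcmv_weights(leadfield: LeadField, cov: SensorCovariance, band: Band | None = None) -> SpatialFilter:
    """Scalar LCMV filter per source with data-driven optimal orientation.

    The 3-column lead field is first reduced to its two strongest field
    topographies (the near-silent radial direction is discarded); within
    that plane the orientation maximizing output power — the minimum
    eigenvector of L' C^-1 L — is selected.  The returned weights satisfy
    unit gain at the oriented lead-field column.
    """
    try:
        cinv = np.linalg.inv(cov.matrix)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("sensor covariance is singular") from exc
    n_src = leadfield.n_sources
    weights = np.empty((n_src, leadfield.n_sensors))
    orientations = np.empty((n_src, 3))
    for s in range(n_src):
        L = leadfield.gain[s].T  # (n_sensors, 3)
        # rank-2 reduction: drop the weakest (radial) moment direction
        u_l, s_l, vt_l = np.linalg.svd(L, full_matrices=False)
        basis = vt_l[:2].T  # (3, 2) moment-space basis of the tangential plane
        Lr = L @ basis      # (n_sensors, 2)
        G = Lr.T @ cinv @ Lr
        evals, evecs = np.linalg.eigh(G)
        # output power 1/(u'Gu) is maximized by the smallest eigenvalue
        u2 = evecs[:, 0]
        ori = basis @ u2
        ori = ori / np.linalg.norm(ori)
        l = L @ ori
        cl = cinv @ l
        denom = l @ cl
        if denom <= 0 or not np.isfinite(denom):
            raise NumericalError(f"degenerate lead field at source {s}")
        weights[s] = cl / denom
        orientations[s] = ori
    return SpatialFilter(weights, orientations, band=band, reg_fraction=cov.regularization)


def project_sources(filt: SpatialFilter, epochs: EpochSet) -> EpochSet:
    """Apply spatial-filter weights to sensor epochs -> source epochs."""
    if epochs.n_channels != filt.weights.shape[1]:
        raise ConfigError(
            f"filter expects {filt.weights.shape[1]} channels, epochs have {epochs.n_channels}"
        )
    src = np.einsum("sc,ecn->esn", filt.weights, epochs.data)
    return EpochSet(src, epochs.fs)


def source_band_power(
    epochs: EpochSet,
    leadfield: LeadField,
    bands: tuple[Band, ...] = CANONICAL_BANDS,
    reg_fraction: float = DEFAULT_REG_FRACTION,
) -> np.ndarray:
    """Per-source relative band power via per-band LCMV projection.

    For each band: filter the sensor epochs to the band, build the
    band-specific covariance and weights, project to source space, and
    take the mean per-epoch variance as absolute power.  Returns
    (n_sources, n_bands) relative power.
    """
    n_src = leadfield.n_sources
    abs_power = np.empty((n_src, len(bands)))
    for j, band in enumerate(bands):
        filtered = EpochSet(bandpass(epochs.data, band, epochs.fs), epochs.fs)
        cov = sensor_covariance(filtered, reg_fraction)
        filt = lcmv_weights(leadfield, cov, band=band)
        src = project_sources(filt, filtered)
        abs_power[:, j] = src.data.var(axis=-1).mean(axis=0)
    return relative_power(abs_power)
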