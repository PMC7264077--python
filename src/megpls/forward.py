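"""Toy spherical MEG forward model.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has a closed form (the classical sphere solution): the field
outside the conductor depends only on the dipole's tangential moment, so
radially oriented dipoles are magnetically silent.  That property is
exactly what the beamformer tests rely on, and it is preserved here even
though a realistic, anatomy-dependent head model is out of scope.

Units: source/sensor positions in mm internally converted to metres;
gain entries are Tesla per (A*m) of dipole moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A


@dataclass
class LeadField:
    """Linear map from dipole moments to sensor measurements.

    gain: (n_sources, 3, n_sensors), T per A*m, one slice per moment axis.
    Positions are in mm, head-centered; sensor normals are unit vectors.
    """

    gain: np.ndarray
    source_positions: np.ndarray        # (n_sources, 3), mm
    sensor_positions: np.ndarray        # (n_sensors, 3), mm
    sensor_orientations: np.ndarray     # (n_sensors, 3), unit normals
    sphere_radius_mm: float

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 3 or self.gain.shape[1] != 3:
            raise ConfigError("gain must be (n_sources, 3, n_sensors)")
        if not np.all(np.isfinite(self.gain)):
            raise ConfigError("gain contains non-finite values")

    @property
    def n_sources(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[2]

    def oriented_gain(self, orientations: np.ndarray) -> np.ndarray:
        """Collapse the moment axis with one unit orientation per source.

        Returns (n_sources, n_sensors)."""
        orientations = np.asarray(orientations, dtype=float)
        return np.einsum("sdc,sd->sc", self.gain, orientations)


def dipole_field(r0_mm: np.ndarray, q: np.ndarray, sensors_mm: np.ndarray,
                 sphere_radius_mm: float) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a homogeneous sphere.

    Parameters
    ----------
    r0_mm : (3,) dipole position, mm, sphere-centered; must be strictly
        inside the sphere and off-center.
    q : (3,) dipole moment, A*m.
    sensors_mm : (n, 3) field points, mm, strictly outside the sphere.

    Returns
    -------
    (n, 3) field vectors at the sensor points.
    """
    r0 = np.asarray(r0_mm, dtype=float) * 1e-3
    q = np.asarray(q, dtype=float)
    r = np.atleast_2d(np.asarray(sensors_mm, dtype=float)) * 1e-3
    R = sphere_radius_mm * 1e-3

    r0n = np.linalg.norm(r0)
    if r0n < 1e-9:
        raise ConfigError("dipole at the sphere center has no tangential component")
    if r0n >= R:
        raise ConfigError("dipole must lie strictly inside the sphere")
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn <= R):
        raise ConfigError("field points must lie strictly outside the sphere")

    a_vec = r - r0                                   # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    r0_dot_r = r @ r0
    F = a * (rn * a + rn**2 - r0_dot_r)
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)
    c1 = a**2 / rn + a_dot_r / a + 2 * a + 2 * rn
    c2 = a + 2 * rn + a_dot_r / a
    grad_F = c1[:, None] * r - c2[:, None] * r0[None, :]
    q_x_r0 = np.cross(q, r0)
    B = (MU0 / (4 * np.pi * F**2))[:, None] * (
        F[:, None] * q_x_r0[None, :] - (r @ q_x_r0)[:, None] * grad_F
    )
    return B


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper two thirds of the unit sphere."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    # restrict to z in [-1/3, 1] like a sensor helmet
    z = 1 - (i + 0.5) / n * (4 / 3)
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def make_toy_leadfield(
    grid_spacing_mm: float = 20.0,
    n_sensors: int = 60,
    sphere_radius_mm: float = 90.0,
) -> LeadField:
    """Build a spherical-head lead field on a regular source grid.

    Sources are placed on a cubic grid of the given spacing, retained if
    strictly inside 80% of the sphere radius and at least one grid step
    away from the center (the center has no tangential moment).  Sensors
    sit on a helmet-like shell at 1.2x the sphere radius, each measuring
    the radial field component.  Deterministic.
    """
    if grid_spacing_mm <= 0 or sphere_radius_mm <= 0:
        raise ConfigError("grid spacing and sphere radius must be positive")
    if n_sensors < 1:
        raise ConfigError("need at least one sensor")

    lim = 0.8 * sphere_radius_mm
    coords = np.arange(-lim, lim + 1e-9, grid_spacing_mm)
    grid = np.array(np.meshgrid(coords, coords, coords, indexing="ij")).reshape(3, -1).T
    radii = np.linalg.norm(grid, axis=1)
    keep = (radii < lim) & (radii > 0.5 * grid_spacing_mm)
    sources = grid[keep]
    if len(sources) == 0:
        raise ConfigError("no grid points fall inside the sphere; reduce grid_spacing_mm")

    sensor_pos = _fibonacci_sphere(n_sensors) * (1.2 * sphere_radius_mm)
    sensor_ori = sensor_pos / np.linalg.norm(sensor_pos, axis=1, keepdims=True)

    gain = np.empty((len(sources), 3, n_sensors))
    eye = np.eye(3)
    for s, pos in enumerate(sources):
        for d in range(3):
            B = dipole_field(pos, eye[d], sensor_pos, sphere_radius_mm)
            gain[s, d] = np.einsum("ij,ij->i", B, sensor_ori)
    return LeadField(gain, sources, sensor_pos, sensor_ori, sphere_radius_mm)
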