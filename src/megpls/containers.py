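"""In-memory containers exchanged between pipeline stages.

``BandPowerMatrix`` is the central "brain block": per subject and source
grid point, the relative power in each canonical band.  Its on-disk form
is a flat delimited table whose columns are named ``s<idx>_<band>`` so
that the (source, band) feature index survives a round trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError


@dataclass
class BandPowerMatrix:
    """Subjects x sources x bands relative power.

    Values are compositional: non-negative and summing to one over the
    band axis for every subject/source pair.
    """

    values: np.ndarray  # (n_subjects, n_sources, n_bands)
    band_names: tuple[str, ...]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ConfigError("BandPowerMatrix values must be 3-d (subjects, sources, bands)")
        if self.values.shape[2] != len(self.band_names):
            raise ConfigError("band axis does not match band_names")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:03d}" for i in range(self.values.shape[0])]
        if len(self.subject_ids) != self.values.shape[0]:
            raise ConfigError("subject_ids length does not match subject axis")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sources(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def feature_names(self) -> list[str]:
        return [f"s{s}_{b}" for s in range(self.n_sources) for b in self.band_names]

    def flatten(self) -> np.ndarray:
        """Subjects x (sources*bands) feature matrix, band fastest."""
        return self.values.reshape(self.n_subjects, -1)

    @property
    def feature_index(self) -> list[tuple[int, str]]:
        """(source, band) pair for every flattened feature column."""
        return [(s, b) for s in range(self.n_sources) for b in self.band_names]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.flatten(), index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.feature_names,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BandPowerMatrix":
        pairs = []
        for col in df.columns:
            if not col.startswith("s") or "_" not in col:
                raise DataError(f"column {col!r} does not follow the s<idx>_<band> layout")
            idx, band = col[1:].split("_", 1)
            pairs.append((int(idx), band))
        sources = sorted({s for s, _ in pairs})
        bands = list(dict.fromkeys(b for _, b in pairs))
        expected = [f"s{s}_{b}" for s in sources for b in bands]
        if list(df.columns) != expected:
            raise DataError("power table columns are not in s-major, band-minor order")
        values = df.to_numpy(dtype=float).reshape(len(df), len(sources), len(bands))
        return cls(values, tuple(bands), [str(i) for i in df.index])

    @classmethod
    def from_csv(cls, path) -> "BandPowerMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))


@dataclass
class EpochSet:
    """Fixed-length epochs of multichannel (or multi-source) data."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigError("EpochSet data must be 3-d (epochs, channels, samples)")
        if self.data.shape[0] < 1:
            raise DataError("EpochSet must contain at least one epoch")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise DataError("EpochSet contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def epoch_length_s(self) -> float:
        return self.data.shape[2] / self.fs


@dataclass
class SensorRecording:
    """Continuous multichannel recording with a head-position trace.

    ``head_position`` holds the coordinates of the head-localization
    fiducial coils over time, shaped (n_fiducials, 3, n_samples), in mm.
    """

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    head_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError("SensorRecording data must be 2-d (channels, samples)")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise DataError("SensorRecording contains non-finite values")
        if self.head_position is not None:
            self.head_position = np.asarray(self.head_position, dtype=float)
            if self.head_position.ndim != 3 or self.head_position.shape[1] != 3:
                raise ConfigError(
                    "head_position must be (n_fiducials, 3, n_samples)"
                )
            if self.head_position.shape[2] != self.data.shape[1]:
                raise ConfigError("head_position sample axis does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
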