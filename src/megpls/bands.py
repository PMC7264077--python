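"""Canonical frequency bands for resting-state analysis.

Band edges are half-open ``[lo, hi)`` so that adjacent bands sharing an
edge (4, 8, 12, 25 Hz) never double-count spectral content.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError


@dataclass(frozen=True)
class Band:
    """A named frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ConfigError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: Delta through gamma, the five bands used throughout the analysis.
CANONICAL_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 25.0),
    Band("gamma", 25.0, 55.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)


def bands_by_name(names) -> tuple[Band, ...]:
    """Resolve a sequence of canonical band names to Band objects."""
    lookup = {b.name: b for b in CANONICAL_BANDS}
    try:
        return tuple(lookup[n] for n in names)
    except KeyError as exc:
        raise ConfigError(f"unknown band name: {exc.args[0]!r}") from None
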