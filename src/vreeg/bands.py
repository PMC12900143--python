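"""EEG frequency-band definitions.

The five analysis bands tile 4-45 Hz under a half-open ``[low, high)``
convention, so band powers partition the in-range spectrum without
double counting: theta 4-8, alpha 8-12, low-beta 12-16, high-beta 16-25,
gamma 25-45 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

__all__ = ["BandDefinition", "DEFAULT_BANDS", "BAND_NAMES", "validate_bands"]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band covering ``[low, high)`` Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ParameterError(f"band {self.name}: need low < high, got [{self.low}, {self.high})")
        if self.low < 0:
            raise ParameterError(f"band {self.name}: low must be >= 0")

    @property
    def width(self) -> float:
        return self.high - self.low


DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("betaL", 12.0, 16.0),
    BandDefinition("betaH", 16.0, 25.0),
    BandDefinition("gamma", 25.0, 45.0),
)

BAND_NAMES = tuple(band.name for band in DEFAULT_BANDS)


def validate_bands(bands) -> tuple:
    """Check bands are ordered, contiguous and non-overlapping."""
    bands = tuple(bands)
    for prev, nxt in zip(bands, bands[1:]):
        if nxt.low < prev.high:
            raise ParameterError(f"bands {prev.name} and {nxt.name} overlap")
    return bands
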