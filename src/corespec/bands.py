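"""Frequency band scheme for multi-band spectral power analysis.

Eight analysis bands from delta to fast ripple.  The bands are
non-contiguous by design: the gaps (4-5, 7-8, 12-15 Hz) belong to no band
and are excluded from both the numerator and the denominator of relative
power.  Band edges are inclusive at both ends except where two bands share
an edge (90 Hz), which is assigned to the lower band (gamma2) only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

#: (bands, rate) pairs already warned about, to avoid per-subject log spam
_WARNED_DROPS: set = set()


@dataclass(frozen=True)
class Band:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ConfigurationError(
                f"band {self.name!r}: f_lo must be < f_hi, got "
                f"[{self.f_lo}, {self.f_hi}]"
            )


class BandScheme:
    """An ordered collection of non-overlapping bands.

    Bands may share a single edge frequency (e.g. gamma2 ends at 90 Hz where
    ripple begins); the shared bin is counted once, in the earlier band.
    """

    def __init__(self, bands: list[Band] | tuple[Band, ...]):
        bands = tuple(bands)
        names = [b.name for b in bands]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate band names: {names}")
        for lo, hi in zip(bands, bands[1:]):
            if hi.f_lo < lo.f_hi:
                raise ConfigurationError(
                    f"bands {lo.name!r} and {hi.name!r} overlap"
                )
        self.bands = bands

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self) -> Iterator[Band]:
        return iter(self.bands)

    def __getitem__(self, name: str) -> Band:
        for band in self.bands:
            if band.name == name:
                return band
        raise KeyError(name)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BandScheme) and self.bands == other.bands

    def effective(self, rate: float) -> "BandScheme":
        """Drop bands whose upper edge exceeds the Nyquist frequency.

        A dropped band triggers a logged warning; the relative-power
        denominator downstream then re-spans the remaining bands.
        """
        nyquist = rate / 2.0
        kept = [b for b in self.bands if b.f_hi <= nyquist]
        dropped = [b.name for b in self.bands if b.f_hi > nyquist]
        if dropped:
            key = (tuple(dropped), rate)
            if key not in _WARNED_DROPS:
                _WARNED_DROPS.add(key)
                logger.warning(
                    "dropping bands %s (upper edge above Nyquist %g Hz at "
                    "rate %g Hz)", dropped, nyquist, rate,
                )
        if not kept:
            raise ConfigurationError(
                f"no band fits below Nyquist {nyquist:g} Hz"
            )
        return BandScheme(kept)

    def bin_assignment(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        """Map each frequency bin to at most one band.

        Returns a dict band name -> boolean mask over `freqs`.  Edges are
        inclusive; a bin landing on a shared edge goes to the earlier band.
        Gap frequencies belong to no band.
        """
        freqs = np.asarray(freqs, dtype=float)
        taken = np.zeros(freqs.shape, dtype=bool)
        masks: dict[str, np.ndarray] = {}
        for band in self.bands:
            mask = (freqs >= band.f_lo) & (freqs <= band.f_hi) & ~taken
            masks[band.name] = mask
            taken |= mask
        return masks


#: The eight analysis bands (Hz).
DEFAULT_BANDS = BandScheme(
    [
        Band("delta", 2.0, 4.0),
        Band("theta", 5.0, 7.0),
        Band("alpha", 8.0, 12.0),
        Band("beta", 15.0, 29.0),
        Band("gamma1", 30.0, 59.0),
        Band("gamma2", 60.0, 90.0),
        Band("ripple", 90.0, 250.0),
        Band("fast_ripple", 250.0, 500.0),
    ]
)
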