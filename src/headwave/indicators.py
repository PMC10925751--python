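"""Frequency-domain injury indicators from a wavelet packet spectrum.

Three quantities summarise where impact energy concentrates in frequency:
the peak sub-band energy, the (frequency-ordered, 0-based) index of the
peak band, and the peak band's share of total energy.  The band index maps
to a physical frequency range through the band width (4.88 Hz at the
default 5000 Hz / 9-level configuration); both band edges are reported
because the index addresses a band, not a point frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wpt import WPSpectrum


class DegenerateSignalError(ValueError):
    """Raised for an all-zero spectrum, where the indicators are undefined."""


@dataclass(frozen=True)
class FreqIndicators:
    """Peak sub-band energy, its band position, and its energy share."""

    e_max: float
    band_index: int
    band_low_hz: float
    band_high_hz: float
    proportion: float

    def to_row(self, label: str = "") -> dict:
        return {
            "signal_label": label,
            "e_max": self.e_max,
            "band_index": self.band_index,
            "f_low_hz": self.band_low_hz,
            "f_high_hz": self.band_high_hz,
            "proportion": self.proportion,
        }


def compute_indicators(spectrum: WPSpectrum) -> FreqIndicators:
    """Locate the maximal-energy sub-band and its share of total energy.

    Ties are broken toward the lowest band index (deterministic).  An
    all-zero spectrum raises :class:`DegenerateSignalError` rather than
    silently dividing 0/0.
    """
    if spectrum.total_energy <= 0:
        raise DegenerateSignalError("degenerate signal: total energy is zero")
    j = int(np.argmax(spectrum.energies))  # argmax returns the first maximum
    low, high = spectrum.band_edges(j)
    return FreqIndicators(
        e_max=float(spectrum.energies[j]),
        band_index=j,
        band_low_hz=low,
        band_high_hz=high,
        proportion=float(spectrum.energies[j] / spectrum.total_energy),
    )
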