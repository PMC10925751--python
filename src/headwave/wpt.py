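"""Wavelet packet decomposition and sub-band energy spectra.

The full wavelet packet transform recursively splits a signal with a
quadrature-mirror filter pair, applying both the low- and high-pass branch
at every node, so that depth ``i`` tiles the interval [0, fs/2) with 2^i
equal-width sub-bands.  The transform is periodized (circular convolution),
which makes it exactly orthogonal: the sum of terminal sub-band energies
equals the energy of the input samples (Parseval).

The per-band energy is the sum of squared terminal coefficients,

    E_ij = sum_k x_{i,j}(k)^2,          E = sum_j E_ij,

reported in frequency order: terminal nodes are permuted by the Gray-code
map so that band index increases monotonically with physical frequency.

The shipped basis is the 4-tap Symlet-2 (sym2) orthogonal filter; any other
orthogonal pair can be plugged in through :class:`QMFPair`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import AccelSignal

#: Symlet-2 analysis low-pass taps, (1±sqrt(3))-type closed form,
#: frozen from the standard published coefficient table.
SYM2_DEC_LO = (
    -0.12940952255092145,
    0.22414386804185735,
    0.83651630373746899,
    0.48296291314469025,
)

#: Cap on the number of terminal bands (2^levels).
MAX_BANDS = 2 ** 16


@dataclass(frozen=True)
class QMFPair:
    """An orthogonal analysis filter pair (low-pass h, high-pass g).

    The high-pass taps are the alternating flip of the low-pass taps,
    g_k = (-1)^(k+1) h_{L-1-k} — the standard quadrature-mirror relation
    (equal, up to an even circular shift and a global sign, to the
    two-scale form g_k = (-1)^k h_{1-k} taken modulo the filter support).
    """

    h: np.ndarray
    g: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "g", g)
        if h.ndim != 1 or h.shape != g.shape or h.size % 2:
            raise ValueError("filter taps must be 1-D, equal length, even length")
        self.validate()

    def validate(self, tol: float = 1e-10) -> None:
        """Check the orthonormal-QMF identities."""
        h, g = self.h, self.g
        if abs(h.sum() - math.sqrt(2.0)) > tol:
            raise ValueError("sum of low-pass taps must be sqrt(2)")
        if abs((h * h).sum() - 1.0) > tol:
            raise ValueError("low-pass taps must have unit energy")
        for m in range(1, h.size // 2):
            if abs(np.dot(h[: -2 * m], h[2 * m:])) > tol:
                raise ValueError("low-pass taps must be shift-orthogonal")
        flip = np.array([(-1.0) ** (k + 1) * h[h.size - 1 - k] for k in range(h.size)])
        if np.max(np.abs(g - flip)) > tol:
            raise ValueError("high-pass taps must be the alternating flip of the low-pass taps")


def build_sym2() -> QMFPair:
    """The Symlet-2 analysis pair used throughout the pipeline."""
    h = np.array(SYM2_DEC_LO)
    g = np.array([(-1.0) ** (k + 1) * h[h.size - 1 - k] for k in range(h.size)])
    return QMFPair(h=h, g=g, name="sym2")


def _analysis_step(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Periodized convolve-and-downsample: a[j] = sum_k f[k] x[(2j + L/2 - k) mod n]."""
    n = x.size
    length = taps.size
    idx = (2 * np.arange(n // 2)[:, None] + length // 2 - np.arange(length)[None, :]) % n
    return x[idx] @ taps


def wp_coefficients(values: np.ndarray, levels: int, filters: QMFPair | None = None) -> list[np.ndarray]:
    """Terminal wavelet packet coefficient arrays in natural (filter-path) order.

    The input must have a length divisible by 2^levels (see
    :func:`wp_decompose` for the padding rule).
    """
    if filters is None:
        filters = build_sym2()
    if levels < 0:
        raise ValueError("levels must be >= 0")
    values = np.asarray(values, dtype=float)
    if values.size % (2 ** levels):
        raise ValueError("signal length must be a multiple of 2**levels")
    nodes = [values]
    for _ in range(levels):
        nodes = [child for arr in nodes for child in (_analysis_step(arr, filters.h),
                                                      _analysis_step(arr, filters.g))]
    return nodes


def frequency_order(natural_index: int, level: int) -> int:
    """Map a natural (filter-path) node index to its frequency-ordered position.

    High-pass branches fold the spectrum, so the children of every high-pass
    node appear in reversed frequency order; undoing this recursively is the
    Gray-code-to-binary permutation (cumulative XOR of the path bits).
    Bijective on {0 .. 2^level - 1}.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if not 0 <= natural_index < 2 ** level:
        raise ValueError("natural_index out of range")
    out = 0
    prev = 0
    for i in range(level - 1, -1, -1):
        prev ^= (natural_index >> i) & 1
        out = (out << 1) | prev
    return out


def band_range(j: int, level: int, fs: float) -> tuple[float, float]:
    """Half-open frequency interval [j*df, (j+1)*df) of band ``j`` (0-based).

    ``df = fs / 2^(level+1)``; the union over all j is exactly [0, fs/2).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0 <= j < 2 ** level:
        raise ValueError("band index out of range")
    df = fs / 2.0 ** (level + 1)
    return (j * df, (j + 1) * df)


@dataclass(frozen=True)
class WPSpectrum:
    """Frequency-ordered terminal sub-band energies at a given depth."""

    level: int
    energies: np.ndarray
    fs: float
    total_energy: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "energies", np.asarray(self.energies, dtype=float))
        if self.energies.size != 2 ** self.level:
            raise ValueError("need 2**level band energies")
        if np.any(self.energies < 0):
            raise ValueError("band energies must be non-negative")

    @property
    def band_width(self) -> float:
        """Bandwidth of each sub-band in Hz (= fs / 2^(level+1))."""
        return self.fs / 2.0 ** (self.level + 1)

    def band_edges(self, j: int) -> tuple[float, float]:
        return band_range(j, self.level, self.fs)

    def to_frame(self) -> pd.DataFrame:
        j = np.arange(self.energies.size)
        return pd.DataFrame({
            "band_index": j,
            "f_low_hz": j * self.band_width,
            "f_high_hz": (j + 1) * self.band_width,
            "energy": self.energies,
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def wp_decompose(signal: AccelSignal, levels: int = 9, filters: QMFPair | None = None) -> WPSpectrum:
    """Full wavelet packet decomposition to ``levels`` and per-band energies.

    The signal is zero-padded at the tail to the next multiple of 2^levels
    samples (zero padding leaves the sample energy unchanged).  Energies are
    returned in frequency order; ``total_energy`` is their sum.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    if 2 ** levels > MAX_BANDS:
        raise ValueError(f"2**levels exceeds the configured cap of {MAX_BANDS}")
    block = 2 ** levels
    npad = max(block, int(math.ceil(signal.n / block)) * block)
    padded = np.zeros(npad)
    padded[: signal.n] = signal.values
    nodes = wp_coefficients(padded, levels, filters)
    energies = np.empty(len(nodes))
    for i, coeffs in enumerate(nodes):
        energies[frequency_order(i, levels)] = float(np.dot(coeffs, coeffs))
    return WPSpectrum(level=levels, energies=energies, fs=signal.fs,
                      total_energy=float(energies.sum()))
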