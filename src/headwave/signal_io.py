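"""Reading, writing and unit conversion of acceleration time series.

A signal is a uniformly sampled scalar acceleration channel stored as plain
CSV with a header row (columns ``time_s`` and ``accel`` by default).  The
sampling interval is inferred from the time column; files with jittered or
non-monotone time stamps are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Standard gravity, m/s^2 per g.
G_STANDARD = 9.80665

#: Allowed unit tags.
UNITS = ("g", "m_per_s2")

#: Relative tolerance for sampling-interval jitter.  Transient solvers emit
#: slightly jittered output times; tighter tolerances reject valid files.
DT_REL_TOL = 1e-3


@dataclass(frozen=True)
class AccelSignal:
    """A uniformly sampled acceleration trace.

    Attributes
    ----------
    values : numpy.ndarray
        Acceleration samples, in ``unit``.
    dt : float
        Sampling interval in seconds.
    unit : str
        Either ``"g"`` or ``"m_per_s2"``.
    label : str
        Free-text identifier (e.g. a scenario id).
    """

    values: np.ndarray
    dt: float
    unit: str = "m_per_s2"
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if values.ndim != 1 or values.size < 2:
            raise ValueError("length >= 2 violated: need at least two samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("acceleration samples must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def time(self) -> np.ndarray:
        """Reconstructed time stamps t_k = k*dt."""
        return np.arange(self.n) * self.dt


def load_signal(
    path: str | Path,
    time_col: str = "time_s",
    accel_col: str = "accel",
    unit: str = "m_per_s2",
    label: str | None = None,
) -> AccelSignal:
    """Read an :class:`AccelSignal` from a two-column CSV file.

    The sampling interval is the median successive time difference; any
    successive difference deviating from it by more than 0.1 % (relative)
    makes the file non-uniform and is an error.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in (time_col, accel_col):
        if col not in frame.columns:
            raise ValueError(f"missing column {col!r} in {path.name}")
    t = frame[time_col].to_numpy(dtype=float)
    a = frame[accel_col].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("length >= 2 violated: need at least two samples")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite time stamps")
    diffs = np.diff(t)
    if np.any(diffs <= 0):
        raise ValueError("non-monotone time column")
    dt = float(np.median(diffs))
    if np.max(np.abs(diffs - dt)) > DT_REL_TOL * dt:
        raise ValueError("non-uniform sampling: time steps deviate by more than 0.1%")
    return AccelSignal(values=a, dt=dt, unit=unit, label=label if label is not None else path.stem)


def write_signal(signal: AccelSignal, path: str | Path,
                 time_col: str = "time_s", accel_col: str = "accel") -> Path:
    """Write a signal as CSV; round-trips through :func:`load_signal`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{time_col},{accel_col}\n")
        for t, a in zip(signal.time(), signal.values):
            fh.write(f"{t:.17g},{a:.17g}\n")
    return path


def convert_units(signal: AccelSignal, target: str) -> AccelSignal:
    """Convert between g and m/s^2 using standard gravity (9.80665).

    Idempotent when ``target`` equals the current unit; length and dt are
    preserved exactly.
    """
    if target not in UNITS:
        raise ValueError(f"unknown unit {target!r}; expected one of {UNITS}")
    if target == signal.unit:
        return signal
    if target == "g":
        values = signal.values / G_STANDARD
    else:
        values = signal.values * G_STANDARD
    return replace(signal, values=values, unit=target)
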