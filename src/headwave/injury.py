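"""Time-domain head injury criterion (HIC) and external MPS intake.

HIC is the maximum, over all time windows [t1, t2] no wider than a cap
(15 ms for HIC15, 36 ms for HIC36), of

    (t2 - t1) * [ (1/(t2-t1)) * integral of a(t) dt ] ** 2.5,

with acceleration expressed in g.  The search here is exhaustive over
sample-aligned windows with a cumulative trapezoidal integral, which is
exact for the piecewise-linear interpolant of the samples.

Maximum principal strain (MPS) is a tissue-level metric produced by
finite-element post-processing; it enters this package only as an
externally supplied column joined onto a results table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_io import AccelSignal, convert_units


@dataclass(frozen=True)
class HICResult:
    """HIC value with the maximizing window (sample-aligned, in seconds)."""

    value: float
    t1: float
    t2: float
    max_window: float

    def __post_init__(self) -> None:
        if self.value < 0 or not 0 <= self.t2 - self.t1 <= self.max_window + 1e-12:
            raise ValueError("inconsistent HIC window")


def compute_hic(signal: AccelSignal, max_window: float = 0.015,
                rectify: bool = False) -> HICResult:
    """Head injury criterion over all sample-aligned windows up to ``max_window``.

    Parameters
    ----------
    signal : AccelSignal
        Input trace; converted to g internally (the criterion is defined on g).
    max_window : float
        Cap on t2 - t1 in seconds; 0.015 gives HIC15, 0.036 HIC36.
    rectify : bool
        If True, the absolute value of the acceleration is integrated.  By
        default the signed samples are used; a maximizing window with a
        negative mean contributes |mean|**2.5 and triggers a warning.
    """
    sig_g = convert_units(signal, "g")
    a = np.abs(sig_g.values) if rectify else sig_g.values
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite samples")
    dt = sig_g.dt
    if max_window <= dt:
        raise ValueError("max_window must exceed the sampling interval")
    # cumulative trapezoidal integral on sample boundaries
    integral = np.concatenate([[0.0], np.cumsum(0.5 * dt * (a[1:] + a[:-1]))])
    w_max = min(int(np.floor(max_window / dt + 1e-9)), a.size - 1)
    best = -1.0
    best_i = 0
    best_w = 1
    for w in range(1, w_max + 1):
        means = (integral[w:] - integral[:-w]) / (w * dt)
        vals = (w * dt) * np.abs(means) ** 2.5
        i = int(np.argmax(vals))
        if vals[i] > best:
            best, best_i, best_w = float(vals[i]), i, w
            best_negative = means[i] < 0
    if best_negative and best > 0:
        warnings.warn("HIC window has negative mean acceleration; using its magnitude")
    return HICResult(value=best, t1=best_i * dt, t2=(best_i + best_w) * dt,
                     max_window=max_window)


def attach_external_mps(table: pd.DataFrame, mps_file: str | Path,
                        key: str = "scenario_id") -> pd.DataFrame:
    """Join an externally computed MPS column onto a results table.

    The file must be a CSV with columns ``scenario_id`` and ``mps``.  Rows of
    the table without a matching MPS value are kept and flagged
    (``mps_matched`` False); duplicate keys or a completely disjoint file
    are errors.
    """
    mps = pd.read_csv(mps_file)
    for col in (key, "mps"):
        if col not in mps.columns:
            raise ValueError(f"MPS file is missing column {col!r}")
    if mps[key].duplicated().any():
        raise ValueError("duplicate keys in MPS file")
    if key not in table.columns:
        raise ValueError(f"results table is missing column {key!r}")
    if not set(mps[key]) & set(table[key]):
        raise ValueError("no overlap between MPS file and results table")
    joined = table.merge(mps[[key, "mps"]], on=key, how="left")
    joined["mps_matched"] = joined["mps"].notna()
    return joined
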