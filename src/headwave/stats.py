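"""Factorial statistics: normalization, rank tests, linear fits.

The factorial results table has one row per impact scenario with factor
columns (position, material, velocity, size) and response columns (e_max,
band_index, proportion, hic, optionally mps).  Each factor's influence on
each response is assessed marginally with a Kruskal-Wallis rank test
(pooling over the other factors); responses are min-max normalized for
joint display; and pairwise linear relations between responses are fit by
ordinary least squares with R^2 = 1 - SS_res/SS_tot.

p-values are reported raw, without multiple-testing correction, one per
factor-response cell.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

FACTOR_COLUMNS = ("position", "material", "velocity", "size")
RESPONSE_COLUMNS = ("e_max", "band_index", "proportion", "hic")


def normalize_responses(table: pd.DataFrame, columns: Sequence[str] | None = None,
                        method: str = "minmax") -> pd.DataFrame:
    """Normalize response columns; min-max to [0, 1] by default, or z-score.

    Constant columns are rejected (their normalization is undefined).
    """
    if method not in ("minmax", "zscore"):
        raise ValueError(f"unknown normalization method {method!r}")
    if columns is None:
        columns = [c for c in RESPONSE_COLUMNS if c in table.columns]
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"constant column {col!r} cannot be normalized")
        if method == "minmax":
            out[col] = (x - x.min()) / np.ptp(x)
        else:
            out[col] = (x - x.mean()) / x.std(ddof=1)
    return out


def factor_test(table: pd.DataFrame, factor: str, response: str) -> float:
    """Kruskal-Wallis p-value for the marginal effect of ``factor`` on ``response``.

    Observations are pooled over all other factors; ties are handled by
    mid-ranks with the standard tie correction (scipy's implementation).
    """
    groups = [g[response].to_numpy(dtype=float) for _, g in table.groupby(factor, sort=True)]
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} needs at least 2 levels")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each factor level needs at least 2 observations")
    return float(sps.kruskal(*groups).pvalue)


def factor_test_matrix(table: pd.DataFrame,
                       factors: Sequence[str] = FACTOR_COLUMNS,
                       responses: Sequence[str] | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """p-value matrix (factors x responses) with significance stars at ``alpha``."""
    if responses is None:
        responses = [c for c in RESPONSE_COLUMNS if c in table.columns]
    rows = []
    for factor in factors:
        row: dict = {"factor": factor}
        for resp in responses:
            p = factor_test(table, factor, resp)
            row[resp] = p
            row[f"{resp}_sig"] = "*" if p < alpha else ""
        rows.append(row)
    return pd.DataFrame(rows)


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def linear_fit(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares line y = slope*x + intercept with R^2.

    A constant y is a degenerate fit: the slope is 0 and R^2 is reported
    as 0 (with a warning), since SS_tot vanishes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope is undefined")
    if np.ptp(y) == 0:
        warnings.warn("constant y: degenerate fit, R^2 reported as 0")
        return LinearFit(0.0, float(y[0]), 0.0)
    res = sps.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue ** 2))


def fit_matrix(table: pd.DataFrame, x_cols: Sequence[str], y_col: str) -> pd.DataFrame:
    """OLS fit of ``y_col`` against each column in ``x_cols``."""
    rows = []
    for col in x_cols:
        try:
            fit = linear_fit(table[col].to_numpy(), table[y_col].to_numpy())
            rows.append({"x": col, "y": y_col, "slope": fit.slope,
                         "intercept": fit.intercept, "r_squared": fit.r_squared})
        except ValueError as exc:
            rows.append({"x": col, "y": y_col, "slope": np.nan,
                         "intercept": np.nan, "r_squared": np.nan, "note": str(exc)})
    return pd.DataFrame(rows)
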