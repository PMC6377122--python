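"""Two-sample Hotelling's T-squared test on per-second activity windows.

The multivariate unit is one larva (or larva x trial): its vector of
activities at each second of a short window, e.g. the three seconds just
after light onset. With group sizes ``n_a`` and ``n_b`` and window length
``p``::

    T^2 = (n_a * n_b / (n_a + n_b)) * dbar' S_pooled^{-1} dbar

where ``dbar`` is the difference of the two group mean vectors and
``S_pooled`` the pooled unbiased sample covariance. Under multivariate
normality with equal covariances,

    F = T^2 * (n_a + n_b - p - 1) / ((n_a + n_b - 2) * p)

follows an F(p, n_a + n_b - p - 1) distribution, which supplies the
p-value. For ``p = 1`` the statistic reduces to the squared pooled-variance
two-sample t statistic.

Singular pooled covariances raise rather than being silently regularized;
shortening the window (fewer seconds than larvae) is the remedy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plate_data import subset_window

__all__ = ["HotellingResult", "hotelling_t2", "hotelling_from_matrices"]


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    window: tuple
    group_a: tuple
    group_b: tuple
    n_a: int
    n_b: int
    n_excluded_a: int = 0
    n_excluded_b: int = 0


def hotelling_from_matrices(X: np.ndarray, Y: np.ndarray):
    """T-squared for two samples of row vectors.

    Returns ``(t2, f_stat, df1, df2, p_value)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D with equal column counts")
    n_a, p = X.shape
    n_b = Y.shape[0]
    if n_a + n_b - 2 < p:
        raise ValueError(
            f"too few observations: need n_a + n_b - 2 >= p, "
            f"got {n_a}+{n_b}-2 < {p}")
    dbar = X.mean(axis=0) - Y.mean(axis=0)
    S = ((n_a - 1) * np.cov(X, rowvar=False).reshape(p, p)
         + (n_b - 1) * np.cov(Y, rowvar=False).reshape(p, p)) / (n_a + n_b - 2)
    # refuse near-singular pooled covariance instead of regularizing
    if np.linalg.matrix_rank(S, tol=None) < p or np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular or ill-conditioned; "
            "shorten the window or pool more larvae")
    t2 = float(n_a * n_b / (n_a + n_b) * dbar @ np.linalg.solve(S, dbar))
    df1 = p
    df2 = n_a + n_b - p - 1
    f_stat = t2 * df2 / ((n_a + n_b - 2) * p)
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return t2, float(f_stat), df1, df2, p_value


def _window_matrix(table: pd.DataFrame, window, unit: str):
    """One complete p-vector per larva (or larva x trial) over the window."""
    t_min, t_max = window
    sub = subset_window(table, t_min, t_max)
    seconds = list(range(t_min, t_max + 1))
    if unit == "larva_trial":
        wide = sub.pivot_table(index=["larva_id", "trial"], columns="t",
                               values="activity", aggfunc="mean")
    elif unit == "larva_mean":
        wide = (sub.groupby(["larva_id", "t"])["activity"].mean()
                .unstack("t"))
    else:
        raise ValueError(f"unit must be larva_trial|larva_mean, got {unit!r}")
    missing_cols = [s for s in seconds if s not in wide.columns]
    if missing_cols:
        raise ValueError(
            f"no records at second(s) {missing_cols} in window {window}")
    wide = wide[seconds]
    complete = wide.dropna()
    return complete.to_numpy(float), len(wide) - len(complete)


def hotelling_t2(table_a: pd.DataFrame, table_b: pd.DataFrame, window,
                 unit: str = "larva_trial",
                 group_a: tuple = ("A",), group_b: tuple = ("B",)
                 ) -> HotellingResult:
    """Compare the mean activity vectors of two samples over a window.

    Each larva (by default each larva x trial) contributes one vector of
    per-second activities; larvae missing any second of the window are
    excluded and counted in the result metadata.
    """
    X, excl_a = _window_matrix(table_a, window, unit)
    Y, excl_b = _window_matrix(table_b, window, unit)
    t2, f_stat, df1, df2, p_value = hotelling_from_matrices(X, Y)
    return HotellingResult(
        t2=t2, f_stat=f_stat, df1=df1, df2=df2, p_value=p_value,
        window=(int(window[0]), int(window[1])),
        group_a=tuple(group_a), group_b=tuple(group_b),
        n_a=X.shape[0], n_b=Y.shape[0],
        n_excluded_a=excl_a, n_excluded_b=excl_b)
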