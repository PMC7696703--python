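"""Per-variable significance statistics: loadings w and p, and BH-FDR.

Two criteria describe each variable's contribution to an OPLS-EP model:

* the **w criterion**: a paired two-tailed t-test on the variable's
  difference column, ``t = mean / (sd / sqrt(n))`` with ``n - 1``
  degrees of freedom;
* the **p criterion**: a t-test on the (uncentered) cosine similarity
  ``cs`` between the sd-scaled variable column and the model-estimated
  response, ``t = cs * sqrt(n - 1) / sqrt(1 - cs²)`` with ``n - 2``
  degrees of freedom.

A variable is *multivariate significant* when the model itself is
significant (CV-ANOVA p < 0.05) and both criteria reach p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_TINY = 1e-12


@dataclass
class VariableStats:
    """Per-variable w/p statistics for one model subset."""

    variable_ids: list[str]
    t_w: np.ndarray
    p_w: np.ndarray
    cs: np.ndarray
    t_p: np.ndarray
    p_p: np.ndarray
    mean_d: np.ndarray
    univariate: np.ndarray  # p_w < 0.05
    fdr: np.ndarray  # univariate after BH-FDR
    multivariate: np.ndarray  # model significant and p_w < .05 and p_p < .05

    def to_frame(self) -> pd.DataFrame:
        """Table with one row per variable, mirroring a results table."""
        return pd.DataFrame(
            {
                "variable": self.variable_ids,
                "t_w": self.t_w,
                "p_w": self.p_w,
                "cs": self.cs,
                "t_p": self.t_p,
                "p_p": self.p_p,
                "direction": np.sign(self.mean_d).astype(int),
                "univariate": self.univariate,
                "fdr": self.fdr,
                "multivariate": self.multivariate,
            }
        ).set_index("variable")


def w_statistic(D_col: np.ndarray) -> tuple[float, float]:
    """Paired t-test on one difference column: t = mean/(sd/sqrt(n)).

    Returns (t, two-tailed p with n-1 df); (nan, nan) for zero spread.
    """
    D_col = np.asarray(D_col, dtype=float)
    n = len(D_col)
    if n < 2:
        raise ValueError("w_statistic needs at least 2 observations")
    sd = np.std(D_col, ddof=1)
    if sd <= _TINY:
        return (np.nan, np.nan)
    t = D_col.mean() / (sd / np.sqrt(n))
    return float(t), float(2 * stats.t.sf(abs(t), df=n - 1))


def w_statistics_matrix(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized `w_statistic` over the columns of a matrix."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    sd = np.std(D, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > _TINY, D.mean(axis=0) / (sd / np.sqrt(n)), np.nan)
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    return t, p


def cosine_t(cs: float, n: int) -> tuple[float, float]:
    """t statistic for a cosine similarity: t = cs*sqrt(n-1)/sqrt(1-cs²).

    Two-tailed p with n-2 degrees of freedom.  |cs| = 1 returns a signed
    infinite t with p = 0.
    """
    if not -1.0 <= cs <= 1.0:
        raise ValueError(f"cosine similarity must lie in [-1, 1], got {cs}")
    if n < 3:
        raise ValueError("cosine_t needs at least 3 observations")
    if abs(cs) >= 1.0 - _TINY:
        return (float(np.sign(cs) * np.inf), 0.0)
    t = cs * np.sqrt(n - 1) / np.sqrt(1.0 - cs**2)
    return float(t), float(2 * stats.t.sf(abs(t), df=n - 2))


def cosine_t_matrix(cs: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized `cosine_t` over an array of cosine similarities."""
    cs = np.asarray(cs, dtype=float)
    near_one = np.abs(cs) >= 1.0 - _TINY
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(near_one, np.sign(cs) * np.inf, cs * np.sqrt(n - 1) / np.sqrt(1.0 - cs**2))
    p = np.where(near_one, 0.0, 2 * stats.t.sf(np.abs(t), df=n - 2))
    return t, p


def cosine_similarities(Z: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Uncentered cosine between each column of Z and the estimated response."""
    Z = np.asarray(Z, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ny = np.linalg.norm(y_hat)
    col_norms = np.linalg.norm(Z, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cs = np.where((col_norms > _TINY) & (ny > _TINY), Z.T @ y_hat / (col_norms * ny), 0.0)
    return np.clip(cs, -1.0, 1.0)


def bh_fdr(pvals: np.ndarray, q: float = 0.2) -> np.ndarray:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    NaN p-values are never selected.
    """
    pvals = np.asarray(pvals, dtype=float)
    flags = np.zeros(pvals.shape, dtype=bool)
    ok = ~np.isnan(pvals)
    p = pvals[ok]
    m = len(p)
    if m == 0:
        return flags
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= q * (np.arange(1, m + 1) / m)
    if below.any():
        k = np.max(np.flatnonzero(below))
        sel = np.zeros(m, dtype=bool)
        sel[order[: k + 1]] = True
        flags[np.flatnonzero(ok)] = sel
    return flags


def variable_stats(
    D: np.ndarray,
    y_hat: np.ndarray,
    p_cvanova: float,
    variable_ids: list[str] | None = None,
    alpha: float = 0.05,
    fdr_q: float = 0.2,
) -> VariableStats:
    """Compute the full per-variable statistics table for one subset.

    ``D`` is the raw (unscaled) difference matrix of the subset and
    ``y_hat`` the model-estimated response on the same observations.
    The multivariate flag gates on the model's CV-ANOVA p-value: a
    non-significant (or non-computable, NaN) model flags nothing.
    """
    D = np.asarray(D, dtype=float)
    n, p_vars = D.shape
    if variable_ids is None:
        variable_ids = [f"v{j}" for j in range(p_vars)]
    t_w, p_w = w_statistics_matrix(D)
    sd = np.std(D, axis=0, ddof=1)
    safe_sd = np.where(sd > _TINY, sd, 1.0)
    cs = cosine_similarities(D / safe_sd, y_hat)
    cs = np.where(sd > _TINY, cs, np.nan)
    t_p, p_p = cosine_t_matrix(np.nan_to_num(cs), n)
    t_p = np.where(np.isnan(cs), np.nan, t_p)
    p_p = np.where(np.isnan(cs), np.nan, p_p)
    univariate = np.nan_to_num(p_w, nan=1.0) < alpha
    fdr = bh_fdr(p_w, q=fdr_q)
    model_sig = (not np.isnan(p_cvanova)) and p_cvanova < alpha
    multivariate = (
        model_sig
        & (np.nan_to_num(p_w, nan=1.0) < alpha)
        & (np.nan_to_num(p_p, nan=1.0) < alpha)
    )
    return VariableStats(
        variable_ids=list(variable_ids),
        t_w=t_w, p_w=p_w, cs=cs, t_p=t_p, p_p=p_p,
        mean_d=D.mean(axis=0),
        univariate=univariate, fdr=fdr, multivariate=multivariate,
    )


def multivariate_flags(p_cvanova: float, stats_table: VariableStats, alpha: float = 0.05) -> np.ndarray:
    """Recompute the multivariate flag from a stats table and a model p."""
    model_sig = (not np.isnan(p_cvanova)) and p_cvanova < alpha
    return (
        model_sig
        & (np.nan_to_num(stats_table.p_w, nan=1.0) < alpha)
        & (np.nan_to_num(stats_table.p_p, nan=1.0) < alpha)
    )
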