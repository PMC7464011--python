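"""Permutation ANCOVA, permutation regression, and BH-FDR adjustment.

Group comparisons (baseline brain activity; cognitive change scores) use a
covariate-adjusted partial F statistic whose null distribution comes from
Freedman–Lane residual permutation: residuals of the covariates-only model
are permuted, added back to that model's fitted values, and the full-model
F is recomputed.  When the number of distinct permutations does not exceed
the requested count the test is exact by enumeration; otherwise Monte Carlo
with ``p = (b + 1) / (B + 1)``.

The permutation multiple regression standardizes all continuous variables,
reports the focal predictor's standardized coefficient and t statistic, and
obtains a two-sided permutation p the same Freedman–Lane way.

False-discovery-rate control is the Benjamini–Hochberg step-up procedure,
implemented directly (it is part of the contract under test, cross-checked
against an independent reference in the test suite).
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .types import PermTestResult, RegressionResult

__all__ = [
    "change_scores",
    "ancova_permutation",
    "eta_squared",
    "perm_regression",
    "fdr_adjust",
    "attach_fdr",
]

_REL_TOL = 1e-12  # relative slack when counting permuted statistics >= observed


# --------------------------------------------------------------------------
# basics
# --------------------------------------------------------------------------

def change_scores(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Post-intervention minus pre-intervention score, elementwise."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have the same shape")
    if not (np.isfinite(pre).all() and np.isfinite(post).all()):
        raise ValueError("scores must be finite")
    return post - pre


def eta_squared(ss_effect: float, ss_total: float) -> float:
    """Effect size eta^2 = SS_effect / SS_total (in [0, 1])."""
    if ss_total <= 0:
        raise ValueError("ss_total must be positive")
    if not 0 <= ss_effect <= ss_total * (1 + 1e-12):
        raise ValueError("ss_effect must lie in [0, ss_total]")
    return min(ss_effect / ss_total, 1.0)


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Monotone in the input ranks, capped at 1, returned in input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def attach_fdr(results: Sequence) -> None:
    """Set ``p_adjusted`` across one family of result objects, in place."""
    adjusted = fdr_adjust([r.p_perm for r in results])
    for r, q in zip(results, adjusted):
        r.p_adjusted = float(q)


# --------------------------------------------------------------------------
# design-matrix helpers
# --------------------------------------------------------------------------

def _as_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        mat = covariates.to_numpy(dtype=float)
    else:
        mat = np.asarray(covariates, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"covariate_{i}" for i in range(mat.shape[1])]
    if mat.shape[0] != n:
        raise ValueError("covariates must have one row per observation")
    if not np.isfinite(mat).all():
        raise ValueError("covariates must be finite")
    return mat, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in range(X.shape[1])
               if diag[j] < 1e-10 * max(1.0, diag.max())]
        raise ValueError(f"design matrix is singular; collinear columns: {bad or names}")


def _q_basis(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q


def _ssr(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (columns) after projection on span(Q)."""
    total = np.sum(Y * Y, axis=0)
    proj = Q.T @ Y
    return total - np.sum(proj * proj, axis=0)


def _perm_index_matrix(rng: np.random.Generator, n: int, B: int) -> np.ndarray:
    idx = np.tile(np.arange(n), (B, 1))
    return rng.permuted(idx, axis=1)


# --------------------------------------------------------------------------
# permutation ANCOVA
# --------------------------------------------------------------------------

def _group_indicator(group) -> tuple[np.ndarray, tuple]:
    group = np.asarray(group)
    levels = tuple(pd.unique(group))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    return (group == levels[0]).astype(float), levels


def ancova_permutation(
    y: np.ndarray,
    group,
    covariates=None,
    n_perm: int = 10_000,
    seed: int | None = None,
    outcome: str = "",
) -> PermTestResult:
    """Covariate-adjusted two-group comparison with a permutation p-value.

    The statistic is the partial F for the group factor after the
    covariates: ``F = (SSR_reduced - SSR_full) / (SSR_full / df_resid)``.
    ``eta2`` relates the group sum of squares to the total sum of squares
    of ``y`` about its mean.

    With no covariates and at most ``n_perm`` distinct group labelings the
    p-value is exact over all labelings; with covariates and ``n! <= n_perm``
    it is exact over all permutations of the reduced-model residuals;
    otherwise Monte Carlo Freedman–Lane with ``p = (b + 1)/(B + 1)``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a 1-D vector")
    n = y.size
    if not np.isfinite(y).all():
        raise ValueError("y must be finite")
    g, _levels = _group_indicator(group)
    if g.size != n:
        raise ValueError("group must match y in length")
    cov, cov_names = _as_matrix(covariates, n)
    p_full = 2 + cov.shape[1]
    if n < p_full + 2:
        raise ValueError(f"need n >= {p_full + 2} observations, got {n}")

    X_red = np.column_stack([np.ones(n), cov])
    X_full = np.column_stack([X_red, g])
    _check_rank(X_full, ["intercept", *cov_names, "group"])

    Q_red = _q_basis(X_red)
    Q_full = _q_basis(X_full)
    ssr_red = float(_ssr(Q_red, y[:, None])[0])
    ssr_full = float(_ssr(Q_full, y[:, None])[0])
    df_resid = n - p_full
    ss_group = max(ssr_red - ssr_full, 0.0)
    if ssr_full <= 0:
        f_obs = math.inf if ss_group > 0 else 0.0
    else:
        f_obs = (ss_group / 1.0) / (ssr_full / df_resid)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    eta2 = eta_squared(ss_group, ss_total) if ss_total > 0 else 0.0

    n1 = int(g.sum())
    if math.isfinite(f_obs):
        thresh = f_obs - _REL_TOL * max(1.0, abs(f_obs))
    else:
        thresh = f_obs  # inf >= inf counts ties correctly

    if cov.shape[1] == 0 and math.comb(n, n1) <= n_perm:
        # exact: F depends only on which observations carry the first label
        f_all = _enumerate_two_group_f(y, n1)
        p = float(np.mean(f_all >= thresh))
        return PermTestResult(outcome, f_obs, 1, df_resid, eta2, p,
                              n_perm=f_all.size, method="exact")

    if cov.shape[1] > 0 and math.factorial(n) <= n_perm:
        perms = np.array(list(itertools.permutations(range(n))))
        f_star = _freedman_lane_f(y, Q_red, Q_full, df_resid, perms)
        p = float(np.mean(f_star >= thresh))
        return PermTestResult(outcome, f_obs, 1, df_resid, eta2, p,
                              n_perm=perms.shape[0], method="exact")

    rng = np.random.default_rng(seed)
    idx = _perm_index_matrix(rng, n, n_perm)
    f_star = _freedman_lane_f(y, Q_red, Q_full, df_resid, idx)
    p = (int(np.sum(f_star >= thresh)) + 1) / (n_perm + 1)
    return PermTestResult(outcome, f_obs, 1, df_resid, eta2, p,
                          n_perm=n_perm, method="monte-carlo")


def _enumerate_two_group_f(y: np.ndarray, n1: int) -> np.ndarray:
    """F over every distinct assignment of n1 observations to group 1."""
    n = y.size
    ss_total = float(np.sum((y - y.mean()) ** 2))
    n2 = n - n1
    total = y.sum()
    f_vals = np.empty(math.comb(n, n1))
    for k, combo in enumerate(itertools.combinations(range(n), n1)):
        s1 = y[list(combo)].sum()
        m1 = s1 / n1
        m2 = (total - s1) / n2
        gm = total / n
        ss_between = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
        ssr = ss_total - ss_between
        f_vals[k] = math.inf if ssr <= 0 else ss_between / (ssr / (n - 2))
    return f_vals


def _freedman_lane_f(y: np.ndarray, Q_red: np.ndarray, Q_full: np.ndarray,
                     df_resid: int, idx: np.ndarray) -> np.ndarray:
    """Partial-F values under Freedman–Lane permutation of reduced residuals.

    ``idx`` is a (B, n) array of permutation indices.
    """
    fitted = Q_red @ (Q_red.T @ y)
    resid = y - fitted
    y_star = (fitted[None, :] + resid[idx]).T  # (n, B)
    ssr_red = _ssr(Q_red, y_star)
    ssr_full = _ssr(Q_full, y_star)
    ss_group = np.maximum(ssr_red - ssr_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = ss_group / (ssr_full / df_resid)
    f_star[~np.isfinite(f_star)] = np.inf
    return f_star


# --------------------------------------------------------------------------
# permutation multiple regression
# --------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance variable")
    return (x - x.mean()) / sd


def _is_binary(x: np.ndarray) -> bool:
    return np.unique(x).size <= 2


def perm_regression(
    change: np.ndarray,
    brain: np.ndarray,
    covariates=None,
    n_perm: int = 10_000,
    seed: int | None = None,
    direction: str = "change_on_brain",
    outcome: str = "",
    side: str = "left",
) -> RegressionResult:
    """Permutation multiple regression linking a change score to brain activity.

    ``direction="change_on_brain"`` (default) regresses the cognitive change
    score on baseline activity; ``"brain_on_change"`` swaps response and
    focal predictor.  Continuous variables (response, predictor, continuous
    covariates) are z-scored before fitting; binary covariates are left as
    indicators.  The reported ``beta_std`` and ``t`` belong to the focal
    predictor; the two-sided p-value permutes reduced-model residuals
    (Freedman–Lane).
    """
    change = np.asarray(change, dtype=float)
    brain = np.asarray(brain, dtype=float)
    if change.shape != brain.shape or change.ndim != 1:
        raise ValueError("change and brain must be equal-length 1-D vectors")
    if direction == "change_on_brain":
        y, x = change, brain
    elif direction == "brain_on_change":
        y, x = brain, change
    else:
        raise ValueError("direction must be 'change_on_brain' or 'brain_on_change'")
    n = y.size
    if x.std(ddof=1) == 0:
        raise ValueError("focal predictor has zero variance")
    cov, cov_names = _as_matrix(covariates, n)

    y_z = _zscore(y)
    x_z = _zscore(x)
    cov_z = np.column_stack([
        cov[:, j] if _is_binary(cov[:, j]) else _zscore(cov[:, j])
        for j in range(cov.shape[1])
    ]) if cov.shape[1] else cov

    X_red = np.column_stack([np.ones(n), cov_z])
    X_full = np.column_stack([X_red, x_z])
    p_full = X_full.shape[1]
    if n < p_full + 2:
        raise ValueError(f"need n >= {p_full + 2} observations, got {n}")
    _check_rank(X_full, ["intercept", *cov_names, "predictor"])

    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    beta = xtx_inv @ (X_full.T @ y_z)
    resid_full = y_z - X_full @ beta
    df_resid = n - p_full
    ssr_full = float(resid_full @ resid_full)
    var_j = xtx_inv[-1, -1]
    beta_j = float(beta[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        se = math.sqrt(max(ssr_full, 0.0) / df_resid * var_j)
        t_obs = beta_j / se if se > 0 else math.copysign(math.inf, beta_j)

    # Freedman-Lane on the focal predictor
    Q_red = _q_basis(X_red)
    fitted_red = Q_red @ (Q_red.T @ y_z)
    resid_red = y_z - fitted_red
    rng = np.random.default_rng(seed)
    idx = _perm_index_matrix(rng, n, n_perm)
    y_star = (fitted_red[None, :] + resid_red[idx]).T  # (n, B)
    c_row = (xtx_inv @ X_full.T)[-1]  # picks out the focal coefficient
    beta_star = c_row @ y_star
    Q_full = _q_basis(X_full)
    ssr_star = _ssr(Q_full, y_star)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_star = np.sqrt(np.maximum(ssr_star, 0.0) / df_resid * var_j)
        t_star = np.where(se_star > 0, beta_star / se_star,
                          np.sign(beta_star) * np.inf)
    abs_obs = abs(t_obs)
    thresh = abs_obs - _REL_TOL * max(1.0, abs_obs) if math.isfinite(abs_obs) else abs_obs
    b = int(np.sum(np.abs(t_star) >= thresh))
    p = (b + 1) / (n_perm + 1)
    return RegressionResult(outcome, side, beta_j, t_obs, p, n,
                            direction=direction, df_resid=df_resid)
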