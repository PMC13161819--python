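"""Empirical-Bayes batch harmonization of regional values (ComBat).

Multi-site MRI studies carry scanner/site effects that confound group
comparisons.  ComBat models each region's value as

    y_ijg = alpha_g + X_ij beta_g + gamma_ig + delta_ig eps_ijg

(site i, subject j, region g) and removes the per-site location shifts
gamma and scale factors delta while preserving the biological covariates in
X (group, age, sex, TIV by default).  Site parameters are shrunk across
regions with empirical Bayes: parametrically with normal / inverse-gamma
priors and iterative conditional updates, or nonparametrically by weighting
every other region's estimates by their likelihood (Monte-Carlo integration
of the posterior over the empirical prior).  Harmonization here is applied
to regional MIND values after network construction; the same routine works
at any regions x subjects matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BatchModel", "combat_harmonize"]


@dataclass(frozen=True)
class BatchModel:
    """Fitted ComBat parameters: per-(batch, region) location and scale."""

    batches: list
    gamma_star: np.ndarray  # (B, G) shrunken location shifts
    delta2_star: np.ndarray  # (B, G) shrunken squared scale factors
    grand_mean: np.ndarray  # (G,)
    pooled_var: np.ndarray  # (G,)
    beta: np.ndarray  # (C, G) preserved covariate coefficients

    def __post_init__(self) -> None:
        if (self.delta2_star <= 0).any():
            raise ValueError("scale factors must be positive")


def _parametric_eb(z_b: np.ndarray, tol: float = 1e-6, max_iter: int = 500):
    """Parametric shrinkage for one batch: z_b is (G, n_b) standardized data."""
    n = z_b.shape[1]
    g_hat = z_b.mean(axis=1)
    d_hat = z_b.var(axis=1, ddof=1)
    g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
    # inverse-gamma prior moment-matched to the spread of d_hat
    v, s2 = d_hat.mean(), d_hat.var(ddof=1)
    lam = (2 * s2 + v**2) / s2
    th = (v * s2 + v**3) / s2
    g_star, d_star = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_star * g_bar) / (n * t2 + d_star)
        ss = ((z_b - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (th + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        change = max(
            np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max()
        )
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


def _nonparametric_eb(z_b: np.ndarray):
    """Nonparametric shrinkage: posterior over the other regions' estimates."""
    g, n = z_b.shape
    g_hat = z_b.mean(axis=1)
    d_hat = z_b.var(axis=1, ddof=1)
    sum_z = z_b.sum(axis=1)
    sum_z2 = (z_b**2).sum(axis=1)
    # SS[i, j] = sum_k (z_ik - g_hat_j)^2, for all region pairs (i, j)
    ss = sum_z2[:, None] - 2.0 * np.outer(sum_z, g_hat) + n * g_hat[None, :] ** 2
    log_lik = -0.5 * n * np.log(2.0 * np.pi * d_hat)[None, :] - ss / (
        2.0 * d_hat[None, :]
    )
    np.fill_diagonal(log_lik, -np.inf)  # leave own estimate out
    log_lik -= log_lik.max(axis=1, keepdims=True)
    w = np.exp(log_lik)
    w /= w.sum(axis=1, keepdims=True)
    return w @ g_hat, w @ d_hat


def combat_harmonize(
    data: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    mode: str = "nonparametric",
) -> tuple[pd.DataFrame, BatchModel]:
    """Remove batch location/scale effects from a regions x subjects table.

    ``batch`` maps subject -> site label (indexed like ``data``'s columns);
    ``covariates`` is a subjects x covariates design of biological effects
    to preserve (no intercept needed).  With a single batch the data are
    returned unchanged.  Singleton batches are refused.
    """
    if mode not in ("parametric", "nonparametric"):
        raise ValueError(f"mode must be parametric|nonparametric, got {mode!r}")
    y = data.to_numpy(dtype=float)  # (G, N)
    n_reg, n_sub = y.shape
    batch = pd.Series(batch).loc[list(data.columns)]
    levels = list(pd.unique(batch))
    counts = batch.value_counts()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(
            f"singleton batch(es) {bad}: ComBat needs >= 2 subjects per "
            "site; merge or drop these sites first"
        )
    n_cov = 0
    cov = np.empty((n_sub, 0))
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[list(data.columns)].to_numpy(dtype=float)
        n_cov = cov.shape[1]
    onehot = np.column_stack(
        [(batch == lv).to_numpy(dtype=float) for lv in levels]
    )
    design = np.hstack([onehot, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        r = np.linalg.qr(design, mode="r")
        names = [f"batch:{lv}" for lv in levels] + list(
            covariates.columns if covariates is not None else []
        )
        bad = [names[j] for j in range(design.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"covariate design is rank deficient; collinear: {bad}")

    if len(levels) == 1:
        model = BatchModel(
            batches=levels,
            gamma_star=np.zeros((1, n_reg)),
            delta2_star=np.ones((1, n_reg)),
            grand_mean=y.mean(axis=1),
            pooled_var=y.var(axis=1, ddof=0),
            beta=np.zeros((n_cov, n_reg)),
        )
        return data.copy(), model

    b_hat = np.linalg.solve(design.T @ design, design.T @ y.T)  # (B+C, G)
    frac = np.array([counts[lv] / n_sub for lv in levels])
    grand = frac @ b_hat[: len(levels)]
    beta = b_hat[len(levels):]
    fitted = design @ b_hat
    pooled = ((y.T - fitted) ** 2).mean(axis=0)
    pooled = np.where(pooled == 0, 1e-12, pooled)
    stand_mean = grand[None, :] + cov @ beta  # (N, G)
    z = (y.T - stand_mean) / np.sqrt(pooled)  # (N, G)

    gamma_star = np.empty((len(levels), n_reg))
    delta2_star = np.empty((len(levels), n_reg))
    shrink = _parametric_eb if mode == "parametric" else _nonparametric_eb
    for i, lv in enumerate(levels):
        z_b = z[(batch == lv).to_numpy()].T  # (G, n_b)
        gamma_star[i], delta2_star[i] = shrink(z_b)
    delta2_star = np.maximum(delta2_star, 1e-12)

    z_adj = z.copy()
    for i, lv in enumerate(levels):
        rows = (batch == lv).to_numpy()
        z_adj[rows] = (z[rows] - gamma_star[i]) / np.sqrt(delta2_star[i])
    y_adj = (z_adj * np.sqrt(pooled) + stand_mean).T
    model = BatchModel(
        batches=levels,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        grand_mean=grand,
        pooled_var=pooled,
        beta=beta,
    )
    return (
        pd.DataFrame(y_adj, index=data.index, columns=data.columns),
        model,
    )
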