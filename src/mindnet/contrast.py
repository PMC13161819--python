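"""Region-wise group contrasts of regional MIND values.

Each region's weighted node degree is regressed on group membership with a
general linear model controlling for age, sex, total intracranial volume
(TIV) and, by default, all pairwise interactions among those covariates.
Group is coded patient=1 / control=0 so t > 0 means patient > control.
Region-level families are Bonferroni-corrected; exploratory clinical
associations use partial Spearman correlations with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignSpec",
    "ContrastMap",
    "build_design",
    "fit_region_glm",
    "bonferroni",
    "bh_fdr",
    "network_aggregate",
    "partial_spearman",
]


@dataclass(frozen=True)
class DesignSpec:
    """Columns of the GLM design.

    ``interactions=True`` adds all pairwise products among the covariates
    (not involving group); ``group_interactions=True`` additionally adds
    group x covariate terms.  Continuous covariates are internally centred
    and scaled before products are formed, purely for conditioning; the
    group coefficient and its t are unaffected.
    """

    group_col: str = "group"
    covariates: tuple = ("age", "sex", "tiv")
    interactions: bool = True
    group_interactions: bool = False
    extras: tuple = ()


@dataclass(frozen=True)
class ContrastMap:
    """Per-region group-effect t statistics with raw and Bonferroni p.

    Sign convention: t > 0 means patient > control.
    """

    region_ids: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_bonf: np.ndarray
    df: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "p": self.p, "p_bonf": self.p_bonf},
            index=pd.Index(self.region_ids, name="region_id"),
        )

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.region_ids[self.p_bonf < alpha]


def _standardize_continuous(col: pd.Series) -> np.ndarray:
    x = col.to_numpy(dtype=float)
    uniq = np.unique(x)
    if len(uniq) <= 2:  # binary stays as coded
        return x
    return (x - x.mean()) / x.std(ddof=1)


def build_design(
    pheno: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, list[str]]:
    """Assemble the design matrix (intercept, group, covariates, products).

    Raises on rank deficiency, naming the aliased columns.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(pheno))}
    group = pheno[design.group_col].to_numpy(dtype=float)
    if not set(np.unique(group)) <= {0.0, 1.0}:
        raise ValueError("group column must be coded patient=1, control=0")
    cols["group"] = group
    covs = list(design.covariates) + list(design.extras)
    for c in covs:
        cols[c] = _standardize_continuous(pheno[c])
    if design.interactions:
        for a, b in combinations(covs, 2):
            cols[f"{a}:{b}"] = cols[a] * cols[b]
    if design.group_interactions:
        for c in covs:
            cols[f"group:{c}"] = group * cols[c]
    names = list(cols)
    x = np.column_stack([cols[c] for c in names])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify aliased columns via pivoted QR
        r = np.linalg.qr(x, mode="r")
        bad = [names[j] for j in range(x.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"design is rank deficient; aliased columns: {bad}")
    return x, names


def _glm_group_t(y: np.ndarray, x: np.ndarray, g_idx: int):
    """Vectorized OLS of each column of y on x; t for column ``g_idx``."""
    n, p = x.shape
    if n <= p + 2:
        raise ValueError(
            f"need more than {p + 2} subjects for {p} design columns, got {n}"
        )
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[g_idx, g_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[g_idx] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return t, pvals, df


def fit_region_glm(
    profiles: pd.DataFrame,
    pheno: pd.DataFrame,
    design: DesignSpec | None = None,
) -> ContrastMap:
    """GLM of regional MIND on group + covariates, one fit per region.

    ``profiles`` is regions x subjects (index = region ids, columns =
    subject ids matching ``pheno``'s ``subject_id`` order).
    """
    design = design or DesignSpec()
    pheno = pheno.set_index("subject_id").loc[list(profiles.columns)].reset_index()
    x, names = build_design(pheno, design)
    y = profiles.to_numpy(dtype=float).T  # subjects x regions
    t, p, df = _glm_group_t(y, x, names.index("group"))
    m = profiles.shape[0]
    return ContrastMap(
        region_ids=np.asarray(profiles.index),
        t=t,
        p=p,
        p_bonf=bonferroni(p, m),
        df=df,
    )


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Family-wise correction: min(1, m * p)."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def network_aggregate(
    profiles: pd.DataFrame,
    mapping: Mapping[str, str],
    pheno: pd.DataFrame,
    design: DesignSpec | None = None,
) -> ContrastMap:
    """Average regions into functional networks, then run the same GLM.

    ``mapping`` assigns every region id to a network label (e.g. Yeo-7);
    Bonferroni correction uses the number of networks as the family size.
    """
    missing = [r for r in profiles.index if r not in mapping]
    if missing:
        raise ValueError(f"regions without a network label: {missing}")
    labels = pd.Series({r: mapping[r] for r in profiles.index})
    net_profiles = profiles.groupby(labels).mean()
    return fit_region_glm(net_profiles, pheno, design)


def partial_spearman(
    values: np.ndarray,
    score: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Spearman correlation of two variables given covariates.

    Both variables are rank-transformed, residualized on the covariates
    (plus intercept) by least squares, and the Pearson correlation of the
    residuals is returned with a t-approximation p-value.  With no
    covariates this reduces to the plain Spearman correlation.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(score, dtype=float)
    if len(v) < 10:
        raise ValueError("need at least 10 subjects")
    if np.ptp(s) == 0 or np.ptp(v) == 0:
        raise ValueError("correlation undefined for a constant variable")
    rv = stats.rankdata(v)
    rs = stats.rankdata(s)
    n_cov = 0
    if covariates is not None and np.size(covariates):
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != len(v):
            z = z.T
        n_cov = z.shape[1]
        zi = np.column_stack([np.ones(len(v)), z])
        rv = rv - zi @ np.linalg.lstsq(zi, rv, rcond=None)[0]
        rs = rs - zi @ np.linalg.lstsq(zi, rs, rcond=None)[0]
    rho = float(np.corrcoef(rv, rs)[0, 1])
    df = len(v) - 2 - n_cov
    tstat = rho * np.sqrt(df / max(1e-12, 1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return rho, p


def clinical_associations(
    profiles: pd.DataFrame,
    pheno: pd.DataFrame,
    score_col: str,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Partial Spearman of every region's MIND with a clinical score.

    Runs :func:`partial_spearman` per region against ``score_col`` given
    the covariate columns, then BH-FDR across regions.  Returns a table
    (region_id, rho, p, q).
    """
    pheno = pheno.set_index("subject_id").loc[list(profiles.columns)]
    score = pheno[score_col].to_numpy(dtype=float)
    covs = (
        pheno[list(covariates)].to_numpy(dtype=float)
        if covariates else None
    )
    rows = []
    for region, values in profiles.iterrows():
        rho, p = partial_spearman(values.to_numpy(), score, covs)
        rows.append((region, rho, p))
    out = pd.DataFrame(rows, columns=["region_id", "rho", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
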