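"""PLS regression linking regional gene expression to case-control maps.

The case-control t-map (one value per left-hemisphere region) is regressed
on the regions x genes expression matrix with partial least squares: gene
expression serves as the predictor block, the t-map as the single response.
Components are retained when they explain more than 20% of the response
variance AND beat a spin-permutation null (p_spin < 0.05).  Gene-wise
stability of the first component is assessed by bootstrap resampling of
regions: z = weight / bootstrap SE, two-sided normal p, Benjamini-Hochberg
q, and significant genes are split into PLS1+ / PLS1- lists by weight sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .contrast import ContrastMap, bh_fdr
from .spin import SpinEnsemble

__all__ = [
    "ExpressionMatrix",
    "PLSModel",
    "align_regions",
    "fit_pls",
    "retain_components",
    "bootstrap_gene_z",
    "select_pls_genes",
    "gene_map_correlation",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Regions x genes expression values (left-hemisphere regions)."""

    region_ids: np.ndarray
    gene_ids: np.ndarray
    values: np.ndarray  # (R, G)
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.region_ids), len(self.gene_ids)):
            raise ValueError("values shape must be (regions, genes)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.region_ids, name="region_id"),
            columns=self.gene_ids,
        )


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS with per-component response-variance fractions.

    ``weights`` are the predictor (gene) weight vectors, columns per
    component, sign-fixed so each component's region scores correlate
    non-negatively with the response.
    """

    weights: np.ndarray  # (G, C)
    scores: np.ndarray  # (R, C)
    var_explained: np.ndarray  # (C,) fraction of response variance
    n_components: int
    region_ids: np.ndarray
    gene_ids: np.ndarray


@dataclass(frozen=True)
class AlignedData:
    """Expression predictors and response map matched on region ids."""

    X: np.ndarray  # (R, G) per-gene z-scored
    y: np.ndarray  # (R,) standardized response
    region_ids: np.ndarray
    gene_ids: np.ndarray


def _zscore_cols(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def align_regions(
    expr: ExpressionMatrix, contrast: ContrastMap, hemisphere: str = "L"
) -> AlignedData:
    """Match expression rows to contrast-map regions (left hemisphere).

    Genes are z-scored across the aligned regions; the response is
    standardized.  Duplicated expression region ids are an error.
    """
    ids, counts = np.unique(expr.region_ids, return_counts=True)
    dups = ids[counts > 1]
    if dups.size:
        raise ValueError(f"duplicated region id(s) in expression: {list(dups)}")
    cm = pd.Series(contrast.t, index=contrast.region_ids)
    hemi_ids = [
        r for r in expr.region_ids
        if r in cm.index and str(r).startswith(hemisphere)
    ]
    if len(hemi_ids) == 0:
        raise ValueError("no overlapping regions between expression and map")
    if len(hemi_ids) < 10:
        raise ValueError(
            f"only {len(hemi_ids)} overlapping regions; need >= 10"
        )
    pos = pd.Series(
        np.arange(len(expr.region_ids)), index=expr.region_ids
    )[hemi_ids].to_numpy()
    x = _zscore_cols(expr.values[pos].astype(float))
    yv = cm[hemi_ids].to_numpy(dtype=float)
    y = (yv - yv.mean()) / yv.std(ddof=1)
    return AlignedData(
        X=x, y=y, region_ids=np.asarray(hemi_ids), gene_ids=expr.gene_ids
    )


def _pls1_direction(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """First PLS weight vector: the normalized covariance direction X'y."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    w = xc.T @ yc
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("response is orthogonal to every predictor")
    return w / nrm


def fit_pls(
    X: np.ndarray, y: np.ndarray, n_components: int = 15,
    region_ids=None, gene_ids=None,
) -> PLSModel:
    """Fit PLS with a single response and report response variance explained.

    Components are extracted by covariance-maximizing iteration with
    deflation (NIPALS); x-scores are mutually orthogonal, so the fraction of
    response variance captured by component c is corr(scores_c, y)^2 and
    the fractions sum to at most 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_c = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_c:
        raise ValueError(
            f"n_components must be in [1, {max_c}], got {n_components}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y residual may vanish early
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X, y)
    weights = pls.x_weights_.copy()
    scores = pls.x_scores_.copy()
    yc = y - y.mean()
    var_exp = np.empty(n_components)
    for c in range(n_components):
        t = scores[:, c]
        tv = t @ t
        if tv < 1e-12:
            var_exp[c] = 0.0
            continue
        r = float(t @ yc) / np.sqrt(tv * (yc @ yc))
        if r < 0:  # sign convention: scores correlate positively with y
            weights[:, c] *= -1
            scores[:, c] *= -1
            r = -r
        var_exp[c] = r**2
    return PLSModel(
        weights=weights,
        scores=scores,
        var_explained=var_exp,
        n_components=n_components,
        region_ids=np.asarray(region_ids) if region_ids is not None else None,
        gene_ids=np.asarray(gene_ids) if gene_ids is not None else None,
    )


def _subset_perms(spins: SpinEnsemble, region_ids: np.ndarray) -> np.ndarray:
    """Restrict a spin ensemble to an aligned subset of regions.

    The subset must be spin-closed (every permutation source also in the
    subset); in practice this means all regions of one hemisphere.
    """
    pos = pd.Series(
        np.arange(len(spins.region_ids)), index=spins.region_ids
    )
    idx = pos[list(region_ids)].to_numpy()
    sub = spins.perms[:, idx]
    back = -np.ones(len(spins.region_ids), dtype=np.intp)
    back[idx] = np.arange(len(idx))
    mapped = back[sub]
    if (mapped < 0).any():
        raise ValueError(
            "spin ensemble maps outside the aligned region subset; "
            "align all regions of the hemisphere before spinning"
        )
    return mapped


def retain_components(
    model: PLSModel,
    spins: SpinEnsemble,
    X: np.ndarray,
    y: np.ndarray,
    region_ids: np.ndarray,
    var_threshold: float = 0.20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spin-based component retention.

    The response map is spun, the PLS refit, and each component's variance
    explained compared against its null distribution (add-one p).  A
    component is retained iff variance explained > ``var_threshold`` and
    p_spin < ``alpha``.  Returns a table (component, var_explained, p_spin,
    retained), components numbered from 1.
    """
    sub = _subset_perms(spins, region_ids)
    obs = model.var_explained
    exceed = np.zeros(model.n_components)
    for j in range(spins.n_perm):
        y_null = y[sub[j]]
        if np.ptp(y_null) == 0:
            exceed += 1  # degenerate spin counted as exceeding
            continue
        null = fit_pls(X, y_null, model.n_components)
        exceed += null.var_explained >= obs
    p_spin = (1.0 + exceed) / (spins.n_perm + 1.0)
    retained = (obs > var_threshold) & (p_spin < alpha)
    return pd.DataFrame(
        {
            "component": np.arange(1, model.n_components + 1),
            "var_explained": obs,
            "p_spin": p_spin,
            "retained": retained,
        }
    )


def bootstrap_gene_z(
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    gene_ids: np.ndarray | None = None,
    q_threshold: float = 0.001,
) -> pd.DataFrame:
    """Bootstrap stability of first-component gene weights.

    Regions are resampled with replacement; the first component is refit on
    each replicate and sign-aligned to the original solution by correlating
    replicate region scores with the original scores on the resampled
    regions.  z = weight / bootstrap SE; two-sided normal p; BH q.  Returns
    the gene statistics table sorted as input (gene_id, weight, se, z, p, q,
    sign_class).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, g = X.shape
    rng = np.random.default_rng(seed)
    w0 = _pls1_direction(X, y)
    t0 = (X - X.mean(axis=0)) @ w0
    boots = np.empty((n_boot, g))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.ptp(y[idx]) == 0:
            n_redrawn += 1
            continue
        xb = X[idx]
        wb = _pls1_direction(xb, y[idx])
        tb = (xb - xb.mean(axis=0)) @ wb
        t0b = t0[idx]
        if (tb - tb.mean()) @ (t0b - t0b.mean()) < 0:
            wb = -wb
        boots[b] = wb
        b += 1
    se = boots.std(axis=0, ddof=1)
    se = np.where(se == 0, np.inf, se)
    z = w0 / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_fdr(p)
    sign_class = np.where(
        q < q_threshold, np.where(w0 > 0, "PLS1+", "PLS1-"), "n.s."
    )
    table = pd.DataFrame(
        {
            "gene_id": (
                gene_ids if gene_ids is not None
                else [f"g{i}" for i in range(g)]
            ),
            "weight": w0,
            "se": se,
            "z": z,
            "p": p,
            "q": q,
            "sign_class": sign_class,
        }
    )
    table.attrs["n_redrawn"] = n_redrawn
    return table


def select_pls_genes(
    table: pd.DataFrame, q_threshold: float = 0.001
) -> tuple[list[str], list[str]]:
    """Split bootstrap-significant genes into PLS1+ / PLS1- ranked by |z|."""
    sig = table[table["q"] < q_threshold].copy()
    sig = sig.reindex(sig["z"].abs().sort_values(ascending=False).index)
    plus = sig.loc[sig["weight"] > 0, "gene_id"].tolist()
    minus = sig.loc[sig["weight"] < 0, "gene_id"].tolist()
    return plus, minus


def gene_map_correlation(
    expr: ExpressionMatrix,
    contrast: ContrastMap,
    genes: list[str],
    hemisphere: str = "L",
) -> pd.DataFrame:
    """Spearman correlation of single-gene maps with the t-map.

    Genes absent from the expression matrix are reported with
    ``measured=False`` rather than dropped silently; BH FDR is applied
    across the measured genes of the supplied list.
    """
    aligned = align_regions(expr, contrast, hemisphere)
    col = {gid: i for i, gid in enumerate(aligned.gene_ids)}
    rows = []
    for gid in genes:
        if gid in col:
            r, p = stats.spearmanr(aligned.X[:, col[gid]], aligned.y)
            rows.append((gid, True, float(r), float(p)))
        else:
            rows.append((gid, False, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["gene_id", "measured", "r", "p"])
    out["q"] = np.nan
    meas = out["measured"]
    if meas.any():
        out.loc[meas, "q"] = bh_fdr(out.loc[meas, "p"].to_numpy())
    return out
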