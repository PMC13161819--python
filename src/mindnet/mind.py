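"""Morphometric Inverse Divergence (MIND) similarity networks.

A cortical region is represented by the cloud of its surface vertices in a
5-dimensional morphometric feature space (cortical thickness CT, gray matter
volume GMV, mean curvature MC, surface area SA, sulcal depth SD).  The MIND
similarity between two regions is an inverse transform of the symmetrized
Kullback-Leibler divergence between the two feature distributions,

    MIND(a, b) = 1 / (1 + D_sym),   D_sym = (KL(a||b) + KL(b||a)) / 2,

which lies in (0, 1] with 1 meaning identical distributions.  The divergence
is estimated non-parametrically from the samples with the k-nearest-neighbour
estimator of Wang, Kulkarni & Verdu (2009): for each point the log-ratio of
its k-th neighbour distance in the other sample to that in its own sample,
plus the m/(n-1) bias term.  A histogram-based Jensen-Shannon mode is
available as an alternative divergence.

Per-subject networks are square region-by-region matrices; the regional MIND
value of a region (its weighted node degree) is the mean of its similarities
to all other regions, and global MIND is the mean of regional values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, jensenshannon

from ._knn import kth_sq_dists

__all__ = [
    "FEATURE_NAMES",
    "VertexFeatureSet",
    "MINDMatrix",
    "RegionalProfile",
    "DegenerateFeatureError",
    "InsufficientSampleError",
    "RegionTooSmallError",
    "zscore_vertex_features",
    "knn_kl_divergence",
    "js_divergence",
    "mind_similarity",
    "compute_mind_matrix",
    "regional_and_global_mind",
    "threshold_by_density",
]

FEATURE_NAMES = ("CT", "GMV", "MC", "SA", "SD")

_DIST_FLOOR = 1e-12  # duplicate points give zero NN distances; floor before log


class DegenerateFeatureError(ValueError):
    """A feature column has zero variance and cannot be z-scored."""


class InsufficientSampleError(ValueError):
    """Too few points for the requested neighbour count."""


class RegionTooSmallError(ValueError):
    """One or more regions fall below the vertex floor."""


@dataclass(frozen=True)
class VertexFeatureSet:
    """One subject's vertex-by-feature matrix with region assignments."""

    subject_id: str
    features: np.ndarray  # (V, 5)
    region_ids: np.ndarray  # (R,) ordered region labels
    vertex_region_idx: np.ndarray  # (V,) index into region_ids
    feature_names: tuple = FEATURE_NAMES
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[1] != len(
            self.feature_names
        ):
            raise ValueError(
                f"features must be (V, {len(self.feature_names)}), "
                f"got {self.features.shape}"
            )
        if len(self.vertex_region_idx) != len(self.features):
            raise ValueError("vertex_region_idx length must match features")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def region_vertices(self, r: int) -> np.ndarray:
        return self.features[self.vertex_region_idx == r]


@dataclass(frozen=True)
class MINDMatrix:
    """Symmetric region-by-region similarity matrix, diagonal excluded (NaN)."""

    values: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.region_ids):
            raise ValueError("values must be square and match region_ids")
        off = ~np.eye(len(v), dtype=bool)
        if not np.allclose(v[off], v.T[off], atol=1e-9, equal_nan=True):
            raise ValueError("MIND matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def offdiag(self) -> np.ndarray:
        """Upper-triangle edge weights as a flat vector."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class RegionalProfile:
    """Per-region weighted node degree and its global mean for one subject."""

    subject_id: str
    region_ids: np.ndarray
    regional_mind: np.ndarray
    global_mind: float


def zscore_vertex_features(fs: VertexFeatureSet) -> VertexFeatureSet:
    """Z-score each feature across *all* vertices of the subject.

    Scaling is across the whole cortex, not per region, so that regional
    distributions remain comparable.  Uses the population (ddof=0) standard
    deviation.
    """
    x = fs.features
    if not np.isfinite(x).all():
        raise ValueError("features contain non-finite values")
    if len(x) < 2:
        raise ValueError("need at least 2 vertices to standardize")
    sd = x.std(axis=0, ddof=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [fs.feature_names[i] for i in dead]
        raise DegenerateFeatureError(
            f"zero-variance feature column(s): {names}"
        )
    z = (x - x.mean(axis=0)) / sd
    return replace(fs, features=z, standardized=True)


def knn_kl_divergence(
    sample_p: np.ndarray, sample_q: np.ndarray, k: int = 1
) -> float:
    """k-NN estimate of KL(P || Q) from samples, clipped below at zero.

    Estimator: (d/n) * sum_i log(nu_k(i) / rho_k(i)) + log(m / (n - 1)),
    where rho_k is the k-th neighbour distance of x_i within sample_p
    (excluding itself) and nu_k its k-th neighbour distance in sample_q.
    """
    p = np.asarray(sample_p, dtype=float)
    q = np.asarray(sample_q, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if q.ndim == 1:
        q = q[:, None]
    n, d = p.shape
    m = q.shape[0]
    if q.shape[1] != d:
        raise ValueError("samples must share dimensionality")
    if n <= k or m < k:
        raise InsufficientSampleError(
            f"need more than k={k} points per sample, got n={n}, m={m}"
        )
    rho = cKDTree(p).query(p, k=k + 1)[0][:, k]
    nu = cKDTree(q).query(p, k=k)[0]
    if k > 1:
        nu = nu[:, k - 1]
    rho = np.maximum(rho, _DIST_FLOOR)
    nu = np.maximum(nu, _DIST_FLOOR)
    est = d * np.mean(np.log(nu / rho)) + np.log(m / (n - 1))
    return max(float(est), 0.0)


def js_divergence(
    sample_p: np.ndarray, sample_q: np.ndarray, bins: int | None = None
) -> float:
    """Histogram-based Jensen-Shannon distance (base 2, in [0, 1]).

    Both samples are binned on a common grid spanning their joint range;
    by default the bin count per dimension grows slowly with sample size
    (about (n/20)^(1/d), floored at 2) to keep joint cells populated.
    Coarse by construction; provided as an alternative to the k-NN KL
    estimator.
    """
    p = np.atleast_2d(np.asarray(sample_p, dtype=float))
    q = np.atleast_2d(np.asarray(sample_q, dtype=float))
    both = np.vstack([p, q])
    if bins is None:
        bins = max(2, int((len(both) / 20) ** (1.0 / both.shape[1])))
    edges = [
        np.linspace(both[:, j].min(), both[:, j].max() + 1e-9, bins + 1)
        for j in range(both.shape[1])
    ]
    hp = np.histogramdd(p, bins=edges)[0].ravel()
    hq = np.histogramdd(q, bins=edges)[0].ravel()
    return float(jensenshannon(hp, hq, base=2))


def mind_similarity(
    sample_a: np.ndarray, sample_b: np.ndarray, k: int = 1, mode: str = "kl"
) -> float:
    """Similarity in (0, 1] between two vertex clouds.

    ``kl`` mode: 1 / (1 + D_sym) with the symmetrized k-NN KL estimate.
    ``js`` mode: 1 - Jensen-Shannon distance of binned distributions.
    """
    if mode == "kl":
        d_sym = 0.5 * (
            knn_kl_divergence(sample_a, sample_b, k)
            + knn_kl_divergence(sample_b, sample_a, k)
        )
        return 1.0 / (1.0 + d_sym)
    if mode == "js":
        return 1.0 - js_divergence(sample_a, sample_b)
    raise ValueError(f"unknown mode {mode!r}")


# above ~8000 vertices the full pairwise-distance matrix is dropped in favour
# of per-region KD-trees to bound memory
_DENSE_VERTEX_LIMIT = 8000


def _knn_logs_dense(x, starts, counts, k):
    """Full-distance-matrix path: per-vertex k-NN log distances.

    Returns (log_nu, log_rho): log_nu[i, s] is the log k-th-neighbour
    distance of vertex i in region s; log_rho[i] the same within the vertex's
    own region (self excluded).  Vertices must be grouped by region.
    Works on squared distances and halves the logs; the k-th-smallest
    selection runs in a compiled kernel.
    """
    d2 = cdist(x, x, "sqeuclidean")
    nu, rho = kth_sq_dists(
        d2, np.asarray(starts, dtype=np.int64),
        np.asarray(counts, dtype=np.int64), k,
    )
    floor2 = _DIST_FLOOR**2
    log_nu = 0.5 * np.log(np.maximum(nu, floor2))
    log_rho = 0.5 * np.log(np.maximum(rho, floor2))
    return log_nu, log_rho


def _knn_logs_trees(x, starts, counts, k):
    """KD-tree path for large vertex counts; same contract as the dense path."""
    n_reg = len(starts)
    log_nu = np.empty((len(x), n_reg))
    log_rho = np.empty(len(x))
    for s in range(n_reg):
        rows = slice(starts[s], starts[s] + counts[s])
        tree = cKDTree(x[rows])
        nu = tree.query(x, k=k)[0]
        if k > 1:
            nu = nu[:, k - 1]
        log_nu[:, s] = np.log(np.maximum(nu, _DIST_FLOOR))
        rho = tree.query(x[rows], k=k + 1)[0][:, k]
        log_rho[rows] = np.log(np.maximum(rho, _DIST_FLOOR))
    return log_nu, log_rho


def default_neighbours(n_min: int) -> int:
    """Default neighbour count for the divergence estimator, k ~ n^0.4.

    Growing k with the sample keeps the estimator's variance over the many
    region pairs of a network small enough that identical distributions
    score near 1; k=3 at the floor protects tiny regions.
    """
    return max(3, int(round(n_min**0.4)))


def compute_mind_matrix(
    fs: VertexFeatureSet,
    k: int | None = None,
    min_vertices: int = 10,
    mode: str = "kl",
) -> MINDMatrix:
    """Build the full region-by-region MIND similarity matrix for a subject.

    All unordered region pairs are evaluated once and mirrored; the diagonal
    is NaN by convention (self-similarity of the estimator is undefined).
    Numerically identical to calling :func:`mind_similarity` per pair, but
    amortizes the neighbour searches across pairs.  ``k=None`` selects
    :func:`default_neighbours` of the smallest region.
    """
    if not fs.standardized:
        raise ValueError("features must be z-scored first "
                         "(zscore_vertex_features)")
    n_reg = fs.n_regions
    counts = np.bincount(fs.vertex_region_idx, minlength=n_reg)
    if k is None:
        k = default_neighbours(int(counts[counts > 0].min()))
    small = np.flatnonzero(counts < max(min_vertices, k + 1))
    if small.size:
        raise RegionTooSmallError(
            "regions below the vertex floor "
            f"({max(min_vertices, k + 1)}): {list(fs.region_ids[small])}"
        )

    order = np.argsort(fs.vertex_region_idx, kind="stable")
    x = fs.features[order]
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])

    if mode == "js":
        sim = np.full((n_reg, n_reg), np.nan)
        clouds = [x[starts[s] : starts[s] + counts[s]] for s in range(n_reg)]
        for a in range(n_reg):
            for b in range(a + 1, n_reg):
                sim[a, b] = sim[b, a] = 1.0 - js_divergence(
                    clouds[a], clouds[b]
                )
        return MINDMatrix(values=sim, region_ids=fs.region_ids)
    if mode != "kl":
        raise ValueError(f"unknown mode {mode!r}")

    if len(x) <= _DENSE_VERTEX_LIMIT:
        log_nu, log_rho = _knn_logs_dense(x, starts, counts, k)
    else:
        log_nu, log_rho = _knn_logs_trees(x, starts, counts, k)

    d = x.shape[1]
    # region-wise sums of the per-vertex log terms
    group = np.zeros((n_reg, len(x)))
    for s in range(n_reg):
        group[s, starts[s] : starts[s] + counts[s]] = 1.0
    sum_nu = group @ log_nu  # (R, R): sum over i in r of log nu_s(i)
    sum_rho = group @ log_rho  # (R,)

    n_r = counts.astype(float)
    kl = (d / n_r)[:, None] * (sum_nu - sum_rho[:, None]) + np.log(
        n_r[None, :] / (n_r[:, None] - 1.0)
    )
    np.maximum(kl, 0.0, out=kl)
    d_sym = 0.5 * (kl + kl.T)
    sim = 1.0 / (1.0 + d_sym)
    np.fill_diagonal(sim, np.nan)
    return MINDMatrix(values=sim, region_ids=fs.region_ids)


def regional_and_global_mind(m: MINDMatrix) -> RegionalProfile:
    """Weighted node degree per region and its mean over regions."""
    vals = m.values.copy()
    np.fill_diagonal(vals, np.nan)
    regional = np.nanmean(vals, axis=1)
    return RegionalProfile(
        subject_id="",
        region_ids=m.region_ids,
        regional_mind=regional,
        global_mind=float(regional.mean()),
    )


def threshold_by_density(m: MINDMatrix, density: float) -> MINDMatrix:
    """Keep the top ceil(density * E) strongest edges, zero the rest."""
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = m.n_regions
    iu = np.triu_indices(n, k=1)
    w = m.values[iu]
    n_keep = int(np.ceil(density * len(w)))
    keep = np.argsort(w)[::-1][:n_keep]
    new_w = np.zeros_like(w)
    new_w[keep] = w[keep]
    out = np.full((n, n), np.nan)
    out[iu] = new_w
    out.T[iu] = new_w
    return MINDMatrix(values=out, region_ids=m.region_ids)
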