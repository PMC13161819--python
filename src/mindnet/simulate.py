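"""Synthetic study generator with known ground truth.

Every input of the analysis pipeline can be simulated here: subject cohorts
of vertex-level morphometric features with injected group, site and
covariate effects; spatially autocorrelated regional gene expression with an
embedded map-aligned signal; and annotation gene-set collections with one
truly enriched set.  All generators are pure functions of their arguments
and a seed, which is what makes the downstream null-calibration and
recovery tests meaningful.

Generative model for a subject's vertex features (each of the 5 features):

    x_v = mu[r(v)] + delta[r(v)] * group + site_offset + beta_age * age_c
          + beta_tiv * tiv_c + beta_sex * sex + eps_v,   eps_v ~ N(0, sd^2)

where mu[r] is a fixed per-region baseline (drawn once per geometry) and
delta is the standardized group effect map.  With all effects zero the
model is exchangeable across groups and sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .geometry import ParcellationGeometry
from .mind import FEATURE_NAMES, VertexFeatureSet
from .pls import ExpressionMatrix

__all__ = [
    "CohortSpec",
    "ExpressionTruth",
    "generate_cohort",
    "generate_expression",
    "generate_gene_sets",
    "generate_stage_region_sets",
]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and injected effects.

    ``effect_map`` holds the per-region standardized group effect delta_r
    applied to patients' feature means (in units of the vertex noise sd).
    ``site_offsets`` maps site name -> additive feature shift and
    ``site_scales`` (optional) site name -> multiplicative factor on the
    region signal + noise; subjects are assigned to sites round-robin.
    Covariate slopes operate on centred age (years - 12) and standardized
    TIV.
    """

    n_patients: int = 50
    n_controls: int = 50
    effect_map: np.ndarray | None = None
    site_offsets: dict = field(default_factory=lambda: {"siteA": 0.0})
    site_scales: dict | None = None
    age_slope: float = 0.0
    tiv_slope: float = 0.0
    sex_shift: float = 0.0
    sex_p: float = 0.5
    noise_sd: float = 1.0
    region_mean_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth of the synthetic expression matrix.

    ``signal_strength`` is the loading of the standardized target map on
    the signal genes; ``autocorr_length`` the e-folding arc length (in
    radians) of the spatial kernel exp(-d / lambda).  Signal genes emulate
    a co-expressed module: a fraction ``module_coherence`` of their spatial
    noise is a single shared Gaussian-process draw, the rest gene-specific,
    as real transcriptomic signal genes share module-level variation that
    does not average away across the module.
    """

    signal_gene_ids: tuple = ()
    signal_strength: float = 1.0
    autocorr_length: float = 2.0
    module_coherence: float = 0.7

    def __post_init__(self) -> None:
        if self.autocorr_length <= 0:
            raise ValueError("autocorr_length must be positive")
        if not 0 <= self.module_coherence <= 1:
            raise ValueError("module_coherence must be in [0, 1]")


def _region_baselines(geometry: ParcellationGeometry, sd: float) -> np.ndarray:
    """Per-region, per-feature baseline means, fixed by the geometry seed."""
    rng = np.random.default_rng(geometry.seed + 1_000_003)
    return rng.normal(0.0, sd, size=(geometry.n_regions, len(FEATURE_NAMES)))


def generate_cohort(
    geometry: ParcellationGeometry, spec: CohortSpec
) -> tuple[list[VertexFeatureSet], pd.DataFrame]:
    """Simulate a patient/control cohort of vertex feature sets.

    Returns the per-subject feature sets (unstandardized) and a phenotype
    table with columns subject_id, group (patient=1), age, sex, site, tiv,
    fsiq, inattention, hyperactivity.
    """
    delta = (
        np.zeros(geometry.n_regions)
        if spec.effect_map is None
        else np.asarray(spec.effect_map, dtype=float)
    )
    if len(delta) != geometry.n_regions:
        raise ValueError(
            f"effect_map has {len(delta)} entries for "
            f"{geometry.n_regions} regions"
        )
    rng = np.random.default_rng(spec.seed)
    mu = _region_baselines(geometry, spec.region_mean_sd)
    sites = list(spec.site_offsets)
    n_total = spec.n_patients + spec.n_controls
    rows = []
    subjects = []
    vidx = geometry.vertex_region_idx
    for i in range(n_total):
        patient = i < spec.n_patients
        sid = f"{'P' if patient else 'C'}{i:04d}"
        site = sites[i % len(sites)]
        age = float(rng.uniform(8.0, 16.0))
        sex = int(rng.random() < spec.sex_p)
        tiv = float(rng.normal(1500.0, 150.0))
        fsiq = float(rng.normal(100.0 if patient else 110.0, 12.0))
        inatt = float(
            np.clip(rng.normal(20.0 if patient else 5.0, 4.0), 0, 27)
        )
        hyper = float(
            np.clip(rng.normal(16.0 if patient else 4.0, 4.0), 0, 27)
        )
        shift = (
            delta * float(patient)
            + spec.site_offsets[site]
            + spec.age_slope * (age - 12.0)
            + spec.tiv_slope * (tiv - 1500.0) / 150.0
            + spec.sex_shift * sex
        )
        scale = 1.0 if spec.site_scales is None else spec.site_scales[site]
        feats = shift[vidx, None] + scale * (
            mu[vidx] + rng.normal(
                0.0, spec.noise_sd,
                size=(geometry.n_vertices, len(FEATURE_NAMES)),
            )
        )
        subjects.append(
            VertexFeatureSet(
                subject_id=sid,
                features=feats,
                region_ids=geometry.region_ids,
                vertex_region_idx=vidx,
            )
        )
        rows.append(
            (sid, int(patient), age, sex, site, tiv, fsiq, inatt, hyper)
        )
    pheno = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "group", "age", "sex", "site", "tiv",
            "fsiq", "inattention", "hyperactivity",
        ],
    )
    return subjects, pheno


def _great_circle(centroids: np.ndarray) -> np.ndarray:
    dots = np.clip(centroids @ centroids.T, -1.0, 1.0)
    return np.arccos(dots)


def spatial_covariance(
    centroids: np.ndarray, autocorr_length: float, jitter: float = 1e-8
) -> np.ndarray:
    """Exponential kernel exp(-d / lambda) on great-circle distances."""
    if autocorr_length <= 0:
        raise ValueError("autocorr_length must be positive")
    cov = np.exp(-_great_circle(centroids) / autocorr_length)
    cov[np.diag_indices_from(cov)] += jitter
    return cov


def generate_expression(
    geometry: ParcellationGeometry,
    n_genes: int,
    truth: ExpressionTruth,
    target_map: np.ndarray,
    seed: int = 0,
) -> ExpressionMatrix:
    """Spatially autocorrelated expression on left-hemisphere regions.

    Non-signal genes are independent Gaussian-process samples over region
    centroids with kernel exp(-d / lambda); signal genes additionally load
    on the standardized ``target_map`` with strength alpha:

        g_signal = alpha * z(target_map) + GP noise.

    ``target_map`` must be given on the left-hemisphere regions (in atlas
    order).
    """
    left = geometry.hemisphere_regions("L")
    target = np.asarray(target_map, dtype=float)
    if len(target) != len(left):
        raise ValueError(
            f"target_map must cover the {len(left)} left-hemisphere regions"
        )
    rng = np.random.default_rng(seed)
    cov = spatial_covariance(geometry.centroids[left], truth.autocorr_length)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:  # pathological lambda: escalate jitter
        cov[np.diag_indices_from(cov)] += 1e-4
        chol = np.linalg.cholesky(cov)
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)])
    signal = frozenset(truth.signal_gene_ids)
    unknown = signal - set(gene_ids)
    if unknown:
        raise ValueError(f"signal genes outside the universe: {sorted(unknown)}")
    values = chol @ rng.standard_normal((len(left), n_genes))
    is_signal = np.isin(gene_ids, sorted(signal))
    if is_signal.any():
        if target.std(ddof=1) == 0:
            raise ValueError(
                "target_map is constant; cannot embed signal genes"
            )
        z_target = (target - target.mean()) / target.std(ddof=1)
        c = truth.module_coherence
        shared = chol @ rng.standard_normal(len(left))
        values[:, is_signal] = (
            truth.signal_strength * z_target[:, None]
            + np.sqrt(1.0 - c**2) * values[:, is_signal]
            + c * shared[:, None]
        )
    return ExpressionMatrix(
        region_ids=geometry.region_ids[left],
        gene_ids=gene_ids,
        values=values,
    )


def generate_gene_sets(
    universe,
    truth: ExpressionTruth,
    n_sets: int = 8,
    set_size: int = 50,
    seed: int = 0,
    enrichment_ratio: float = 1.0,
    enriched_set: str = "SET01",
) -> GeneSetCollection:
    """Annotation sets with one designated set enriched for signal genes.

    The enriched set contains signal genes at ``enrichment_ratio`` times
    their base rate in the universe; the remaining sets are uniform draws.
    """
    univ = np.asarray(sorted(str(g) for g in universe))
    if set_size >= len(univ):
        raise ValueError("set_size must be smaller than the universe")
    signal = np.asarray(
        sorted(set(truth.signal_gene_ids) & set(univ))
    )
    base_rate = len(signal) / len(univ)
    n_sig = int(round(enrichment_ratio * base_rate * set_size))
    if n_sig > min(set_size, len(signal)):
        raise ValueError(
            f"enrichment ratio {enrichment_ratio} needs {n_sig} signal genes; "
            f"only {len(signal)} exist"
        )
    rng = np.random.default_rng(seed)
    non_signal = np.asarray(sorted(set(univ) - set(signal)))
    sets = {}
    for j in range(n_sets):
        name = f"SET{j + 1:02d}"
        if name == enriched_set and enrichment_ratio != 1.0:
            picked = np.concatenate(
                [
                    rng.choice(signal, size=n_sig, replace=False),
                    rng.choice(
                        non_signal, size=set_size - n_sig, replace=False
                    ),
                ]
            )
        else:
            picked = rng.choice(univ, size=set_size, replace=False)
        sets[name] = frozenset(picked)
    return GeneSetCollection(sets=sets, universe=frozenset(univ))


def generate_stage_region_sets(
    universe,
    truth: ExpressionTruth,
    n_stages: int = 15,
    n_brain_regions: int = 12,
    set_size: int = 30,
    seed: int = 0,
    enrichment_ratio: float = 1.0,
    enriched_cell: tuple = ("stage08", "regionA"),
) -> GeneSetCollection:
    """Developmental stage x brain-region grid sets (names ``stage|region``).

    One designated cell is enriched for signal genes at the given ratio;
    all other cells are uniform draws from the universe.
    """
    univ = np.asarray(sorted(str(g) for g in universe))
    signal = np.asarray(sorted(set(truth.signal_gene_ids) & set(univ)))
    non_signal = np.asarray(sorted(set(univ) - set(signal)))
    base_rate = len(signal) / len(univ)
    n_sig = int(round(enrichment_ratio * base_rate * set_size))
    if n_sig > min(set_size, len(signal)):
        raise ValueError("enrichment ratio implies more signal genes than exist")
    rng = np.random.default_rng(seed)
    stages = [f"stage{i + 1:02d}" for i in range(n_stages)]
    regions = [f"region{chr(ord('A') + j)}" for j in range(n_brain_regions)]
    sets = {}
    for s in stages:
        for r in regions:
            name = f"{s}|{r}"
            if (s, r) == tuple(enriched_cell) and enrichment_ratio != 1.0:
                picked = np.concatenate(
                    [
                        rng.choice(signal, size=n_sig, replace=False),
                        rng.choice(
                            non_signal, size=set_size - n_sig, replace=False
                        ),
                    ]
                )
            else:
                picked = rng.choice(univ, size=set_size, replace=False)
            sets[name] = frozenset(picked)
    return GeneSetCollection(sets=sets, universe=frozenset(univ))
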