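"""End-to-end orchestration: simulate -> mind -> harmonize -> match ->
contrast -> spin -> pls -> enrich.

One config object drives the whole run; the master seed deterministically
derives independent per-stage seeds, so identical configs produce
bitwise-identical output files.  Every stage writes plain-text tables into
the output directory and the run ends with a JSON manifest recording
parameters, per-stage outputs and their content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .contrast import ContrastMap, DesignSpec, fit_region_glm, network_aggregate
from .enrich import (
    overlap_permutation,
    rank_enrichment,
    read_gmt,
    stage_region_grid,
    write_gmt,
)
from .geometry import generate_parcellation
from .harmonize import combat_harmonize
from .matching import balance_report, fit_propensity, match_caliper
from .mind import compute_mind_matrix, regional_and_global_mind, \
    threshold_by_density, zscore_vertex_features
from .pls import (
    align_regions,
    bootstrap_gene_z,
    fit_pls,
    gene_map_correlation,
    retain_components,
    select_pls_genes,
)
from .simulate import (
    CohortSpec,
    ExpressionTruth,
    generate_cohort,
    generate_expression,
    generate_gene_sets,
    generate_stage_region_sets,
)
from .spin import generate_spins, spin_correlation_test

log = logging.getLogger("mindnet")

STAGES = (
    "simulate", "mind", "harmonize", "match",
    "contrast", "spin", "pls", "enrich",
)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults follow the reference analysis.

    The master seed derives one child seed per stage via SeedSequence
    spawning, so stages are independently reproducible.
    """

    out_dir: str = "mindnet_run"
    master_seed: int = 0
    stages: tuple = STAGES
    # synthetic cohort
    n_regions: int = 60
    vertices_per_region: int = 50
    n_patients: int = 30
    n_controls: int = 30
    effect_delta: float = 0.8
    n_affected_regions: int = 10
    site_offsets: dict = field(default_factory=lambda: {"siteA": 0.0,
                                                        "siteB": 0.4})
    noise_sd: float = 1.0
    # expression / gene sets
    n_genes: int = 500
    n_signal_genes: int = 50
    signal_strength: float = 0.8
    autocorr_length: float = 2.0
    n_gene_sets: int = 8
    gene_set_size: int = 50
    grid_set_size: int = 30
    enrichment_ratio: float = 5.0
    # network construction
    k_neighbours: int | None = None  # None = adaptive
    min_vertices: int = 10
    divergence_mode: str = "kl"
    density: float | None = None
    # harmonization / matching
    combat_mode: str = "nonparametric"
    preserve_covariates: tuple = ("group", "age", "sex", "tiv")
    caliper: float = 0.073
    match_covariates: tuple = ("sex", "age")
    # statistics
    covariates: tuple = ("age", "sex", "tiv")
    n_perm: int = 10_000
    n_boot: int = 10_000
    n_components: int = 15
    var_threshold: float = 0.20
    q_threshold: float = 0.001
    bonf_alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        child = np.random.SeedSequence(self.master_seed).spawn(len(STAGES))
        return int(child[idx].generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "preserve_covariates", "match_covariates",
                    "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        for key, val in raw.items():
            if isinstance(val, tuple):
                raw[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    Stages consume the outputs of earlier stages from ``out_dir``; a stage
    whose inputs are missing raises an error naming the stage that should
    have produced them.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    manifest["config"]["stages"] = list(config.stages)
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        runner = globals()[f"_stage_{stage}"]
        outputs = runner(config, out, state)
        dt = time.perf_counter() - t0
        log.info("stage %-9s done in %.2fs", stage, dt)
        manifest["stages"][stage] = {
            "seconds": round(dt, 3),
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in outputs.items()
            },
        }
    mio.write_json(manifest, out / "manifest.json")
    return manifest


def _require(out: Path, name: str, producer: str) -> Path:
    p = out / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing {p}; run the '{producer}' stage first"
        )
    return p


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> dict:
    seed = config.stage_seed("simulate")
    rng = np.random.default_rng(seed)
    geom = generate_parcellation(
        config.n_regions, config.vertices_per_region, seed=seed
    )
    delta = np.zeros(config.n_regions)
    # split affected regions across hemispheres so the left-hemisphere
    # t-map (the PLS response) carries part of the effect
    left_idx = geom.hemisphere_regions("L")
    right_idx = geom.hemisphere_regions("R")
    n_l = config.n_affected_regions // 2 + config.n_affected_regions % 2
    n_r = config.n_affected_regions // 2
    affected = np.sort(
        np.concatenate(
            [
                rng.choice(left_idx, n_l, replace=False),
                rng.choice(right_idx, n_r, replace=False),
            ]
        )
    )
    delta[affected] = config.effect_delta
    spec = CohortSpec(
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        effect_map=delta,
        site_offsets=dict(config.site_offsets),
        noise_sd=config.noise_sd,
        seed=seed + 1,
    )
    subjects, pheno = generate_cohort(geom, spec)
    # expression signal genes track the expected group-effect map: injected
    # feature shifts lower regional MIND in patients, so t approx -delta
    target = -delta[left_idx]
    if np.ptp(target) == 0:
        target = rng.standard_normal(len(left_idx))
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    signal = tuple(
        sorted(rng.choice(gene_ids, config.n_signal_genes, replace=False))
    )
    truth = ExpressionTruth(
        signal_gene_ids=signal,
        signal_strength=config.signal_strength,
        autocorr_length=config.autocorr_length,
    )
    expr = generate_expression(
        geom, config.n_genes, truth, target, seed=seed + 2
    )
    sets = generate_gene_sets(
        gene_ids, truth, config.n_gene_sets, config.gene_set_size,
        seed=seed + 3, enrichment_ratio=config.enrichment_ratio,
    )
    grid = generate_stage_region_sets(
        gene_ids, truth, set_size=config.grid_set_size, seed=seed + 4,
        enrichment_ratio=config.enrichment_ratio,
    )
    feats_dir = out / "vertex_features"
    feats_dir.mkdir(exist_ok=True)
    outputs = {}
    for fs in subjects:
        p = feats_dir / f"{fs.subject_id}.tsv"
        mio.write_vertex_features(fs, p)
    outputs["vertex_features_dir"] = feats_dir / f"{subjects[0].subject_id}.tsv"
    pheno.to_csv(out / "phenotype.csv", index=False)
    mio.write_centroids(geom, out / "centroids.tsv")
    mio.write_expression(expr, out / "expression.tsv")
    write_gmt(sets, out / "gene_sets.gmt")
    write_gmt(grid, out / "stage_region_sets.gmt")
    mio.write_json(
        {
            "seed": seed,
            "affected_regions": [str(geom.region_ids[i]) for i in affected],
            "effect_delta": config.effect_delta,
            "signal_genes": list(signal),
            "target_map": target,
            "enriched_set": "SET01" if config.enrichment_ratio != 1 else None,
        },
        out / "ground_truth.json",
    )
    state.update(
        geometry=geom, subjects=subjects, pheno=pheno, expr=expr,
        gene_sets=sets, grid_sets=grid, truth=truth,
    )
    outputs.update(
        {
            "phenotype": out / "phenotype.csv",
            "centroids": out / "centroids.tsv",
            "expression": out / "expression.tsv",
            "gene_sets": out / "gene_sets.gmt",
            "stage_region_sets": out / "stage_region_sets.gmt",
            "ground_truth": out / "ground_truth.json",
        }
    )
    return outputs


def _stage_mind(config: PipelineConfig, out: Path, state: dict) -> dict:
    if "subjects" not in state:
        raise FileNotFoundError(
            "mind stage needs in-memory subjects; run 'simulate' first "
            "(file-based entry points are available via the CLI)"
        )
    profiles = {}
    glob_rows = []
    mat_dir = out / "mind_matrices"
    mat_dir.mkdir(exist_ok=True)
    for fs in state["subjects"]:
        m = compute_mind_matrix(
            zscore_vertex_features(fs),
            k=config.k_neighbours,
            min_vertices=config.min_vertices,
            mode=config.divergence_mode,
        )
        if config.density is not None:
            m = threshold_by_density(m, config.density)
        prof = regional_and_global_mind(m)
        profiles[fs.subject_id] = prof.regional_mind
        glob_rows.append((fs.subject_id, prof.global_mind))
        mio.write_matrix(m, mat_dir / f"{fs.subject_id}.tsv")
    profiles = pd.DataFrame(profiles, index=state["geometry"].region_ids)
    mio.write_profiles(profiles, out / "regional_mind.tsv")
    pd.DataFrame(glob_rows, columns=["subject_id", "global_mind"]).to_csv(
        out / "global_mind.csv", index=False
    )
    state["profiles"] = profiles
    return {
        "regional_mind": out / "regional_mind.tsv",
        "global_mind": out / "global_mind.csv",
    }


def _stage_harmonize(config: PipelineConfig, out: Path, state: dict) -> dict:
    if "profiles" not in state:
        raise FileNotFoundError("harmonize needs regional_mind; run 'mind'")
    pheno = state["pheno"].set_index("subject_id")
    covs = pheno.loc[
        list(state["profiles"].columns), list(config.preserve_covariates)
    ].astype(float)
    harmonized, model = combat_harmonize(
        state["profiles"], pheno["site"], covs, mode=config.combat_mode
    )
    mio.write_profiles(harmonized, out / "regional_mind_harmonized.tsv")
    state["profiles_harmonized"] = harmonized
    return {"regional_mind_harmonized": out / "regional_mind_harmonized.tsv"}


def _stage_match(config: PipelineConfig, out: Path, state: dict) -> dict:
    pheno = state["pheno"]
    scores = fit_propensity(pheno, covariates=config.match_covariates)
    result = match_caliper(
        scores, pheno.set_index("subject_id")["group"], config.caliper
    )
    report = balance_report(
        pheno, config.match_covariates, result
    )
    pd.DataFrame(result.pairs, columns=["patient_id", "control_id"]).to_csv(
        out / "matched_pairs.csv", index=False
    )
    report.to_csv(out / "balance_report.csv", index=False)
    state["matched_ids"] = result.matched_ids()
    return {
        "matched_pairs": out / "matched_pairs.csv",
        "balance_report": out / "balance_report.csv",
    }


def _stage_contrast(config: PipelineConfig, out: Path, state: dict) -> dict:
    profiles = state.get("profiles_harmonized", state.get("profiles"))
    if profiles is None:
        raise FileNotFoundError("contrast needs regional MIND; run 'mind'")
    if "matched_ids" in state:
        keep = [s for s in profiles.columns if s in state["matched_ids"]]
        profiles = profiles[keep]
    design = DesignSpec(covariates=tuple(config.covariates))
    cm = fit_region_glm(profiles, state["pheno"], design)
    mio.write_contrast(cm, out / "contrast.tsv")
    # aggregate into interleaved pseudo-functional networks (7 labels)
    labels = {
        r: f"net{i % 7 + 1}" for i, r in enumerate(profiles.index)
    }
    net = network_aggregate(profiles, labels, state["pheno"], design)
    mio.write_contrast(net, out / "contrast_networks.tsv")
    state["contrast"] = cm
    return {
        "contrast": out / "contrast.tsv",
        "contrast_networks": out / "contrast_networks.tsv",
    }


def _stage_spin(config: PipelineConfig, out: Path, state: dict) -> dict:
    geom = state["geometry"]
    spins = generate_spins(
        geom, config.n_perm, seed=config.stage_seed("spin")
    )
    np.savetxt(out / "spin_perms.tsv", spins.perms, fmt="%d", delimiter="\t")
    state["spins"] = spins
    return {"spin_perms": out / "spin_perms.tsv"}


def _stage_pls(config: PipelineConfig, out: Path, state: dict) -> dict:
    for need, producer in (("contrast", "contrast"), ("spins", "spin"),
                           ("expr", "simulate")):
        if need not in state:
            raise FileNotFoundError(f"pls needs '{need}'; run '{producer}'")
    aligned = align_regions(state["expr"], state["contrast"])
    n_comp = min(config.n_components, len(aligned.y) - 1)
    model = fit_pls(
        aligned.X, aligned.y, n_comp,
        region_ids=aligned.region_ids, gene_ids=aligned.gene_ids,
    )
    retention = retain_components(
        model, state["spins"], aligned.X, aligned.y, aligned.region_ids,
        var_threshold=config.var_threshold,
    )
    table = bootstrap_gene_z(
        aligned.X, aligned.y, n_boot=config.n_boot,
        seed=config.stage_seed("pls"), gene_ids=aligned.gene_ids,
        q_threshold=config.q_threshold,
    )
    plus, minus = select_pls_genes(table, config.q_threshold)
    r_obs, p_spin = spin_correlation_test(
        np.asarray(model.scores[:, 0]),
        aligned.y,
        _restrict_spins(state["spins"], aligned.region_ids),
    )
    retention.to_csv(out / "pls_components.tsv", sep="\t", index=False)
    table.to_csv(out / "pls_gene_stats.tsv", sep="\t", index=False,
                 float_format="%.10g")
    (out / "pls1_plus_genes.txt").write_text("\n".join(plus) + "\n")
    (out / "pls1_minus_genes.txt").write_text("\n".join(minus) + "\n")
    mio.write_json(
        {
            "n_components": n_comp,
            "var_explained": model.var_explained,
            "retained": retention[retention["retained"]][
                "component"
            ].tolist(),
            "pls1_score_map_r": r_obs,
            "pls1_score_map_p_spin": p_spin,
            "n_pls1_plus": len(plus),
            "n_pls1_minus": len(minus),
        },
        out / "pls_model.json",
    )
    state.update(pls_model=model, gene_table=table,
                 pls_genes=(plus, minus), aligned=aligned)
    return {
        "pls_components": out / "pls_components.tsv",
        "pls_gene_stats": out / "pls_gene_stats.tsv",
        "pls1_plus": out / "pls1_plus_genes.txt",
        "pls1_minus": out / "pls1_minus_genes.txt",
        "pls_model": out / "pls_model.json",
    }


def _restrict_spins(spins, region_ids):
    from .pls import _subset_perms
    from .spin import SpinEnsemble

    sub = _subset_perms(spins, region_ids)
    return SpinEnsemble(
        perms=sub, region_ids=np.asarray(region_ids), seed=spins.seed
    )


def _stage_enrich(config: PipelineConfig, out: Path, state: dict) -> dict:
    if "gene_table" not in state:
        raise FileNotFoundError("enrich needs PLS gene lists; run 'pls'")
    table = state["gene_table"]
    plus, minus = state["pls_genes"]
    universe = list(table["gene_id"])
    seed = config.stage_seed("enrich")
    rows = []
    candidate = plus if len(plus) >= len(minus) else minus
    for name, members in state["gene_sets"].sets.items():
        res = overlap_permutation(
            candidate, members, universe,
            n_perm=config.n_perm, seed=seed,
        )
        rows.append((name, res.observed, res.p_perm, res.p_exact))
    overlap = pd.DataFrame(
        rows, columns=["set", "overlap", "p_perm", "p_exact"]
    )
    from .contrast import bh_fdr

    overlap["q_perm"] = bh_fdr(overlap["p_perm"].to_numpy())
    ranked = table.reindex(
        table["z"].abs().sort_values(ascending=False).index
    )
    rank_rows = []
    for name, members in state["gene_sets"].sets.items():
        res = rank_enrichment(
            ranked["gene_id"].tolist(), ranked["z"].tolist(), members,
            n_perm=min(config.n_perm, 2000), seed=seed,
        )
        rank_rows.append((name, res.observed, res.p_perm))
    rank = pd.DataFrame(rank_rows, columns=["set", "es", "p_perm"])
    rank["q_perm"] = bh_fdr(rank["p_perm"].to_numpy())
    grid = stage_region_grid(candidate, state["grid_sets"], universe)
    overlap.to_csv(out / "enrichment_overlap.tsv", sep="\t", index=False)
    rank.to_csv(out / "enrichment_rank.tsv", sep="\t", index=False)
    grid.to_csv(out / "enrichment_grid.tsv", sep="\t", index=False)
    state["enrichment"] = {"overlap": overlap, "rank": rank, "grid": grid}
    return {
        "enrichment_overlap": out / "enrichment_overlap.tsv",
        "enrichment_rank": out / "enrichment_rank.tsv",
        "enrichment_grid": out / "enrichment_grid.tsv",
    }
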