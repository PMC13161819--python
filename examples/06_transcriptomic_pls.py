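"""Link a case-control map to regional gene expression with PLS.

Synthetic left-hemisphere expression (500 genes) embeds 50 signal genes
that track a target map.  PLS1 is retained when it explains >20% of the
response variance and beats the spin null; bootstrap z-scores then pick
out the signal genes at q < 0.001.
"""

import numpy as np

from mindnet import (
    ContrastMap,
    ExpressionTruth,
    align_regions,
    bootstrap_gene_z,
    fit_pls,
    generate_expression,
    generate_parcellation,
    generate_spins,
    retain_components,
    select_pls_genes,
)

geometry = generate_parcellation(308, 10, seed=0)
left = geometry.hemisphere_regions("L")
rng = np.random.default_rng(1)
target = rng.standard_normal(len(left))
signal = tuple(sorted(f"G{i:05d}"
                      for i in rng.choice(500, 50, replace=False)))

expr = generate_expression(
    geometry, 500,
    ExpressionTruth(signal_gene_ids=signal, signal_strength=0.4),
    target, seed=2,
)
t_map = np.zeros(geometry.n_regions)
t_map[left] = target
contrast = ContrastMap(
    region_ids=geometry.region_ids, t=t_map,
    p=np.ones_like(t_map), p_bonf=np.ones_like(t_map), df=100,
)

aligned = align_regions(expr, contrast)
model = fit_pls(aligned.X, aligned.y, n_components=15)
spins = generate_spins(geometry, 1000, seed=3)
retention = retain_components(
    model, spins, aligned.X, aligned.y, aligned.region_ids
)
row = retention.iloc[0]
print(f"PLS1 variance explained: {100 * row.var_explained:.1f}%  "
      f"p_spin = {row.p_spin:.4f}  retained = {bool(row.retained)}")

table = bootstrap_gene_z(
    aligned.X, aligned.y, n_boot=2000, seed=4, gene_ids=aligned.gene_ids
)
plus, minus = select_pls_genes(table, q_threshold=0.001)
selected = set(plus) | set(minus)
precision = len(selected & set(signal)) / len(selected) if selected else 0
print(f"genes selected at q<0.001: {len(selected)} "
      f"(PLS1+ {len(plus)}, PLS1- {len(minus)})")
print(f"fraction of selected genes that are true signal genes: "
      f"{precision:.2f}")
print("A retained PLS1 whose bootstrap-stable genes are the embedded "
      "signal genes means the transcriptomic association is recovered, "
      "not an artifact of spatial autocorrelation.")
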