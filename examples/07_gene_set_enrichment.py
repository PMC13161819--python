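"""Annotate a gene list against gene-set collections.

Three testing styles: overlap permutation with an exact hypergeometric
cross-check (cell-type style), weighted running-sum rank enrichment
(cortical-layer style), and a developmental stage x brain-region
over-representation grid with one planted enriched cell.
"""

import numpy as np

from mindnet import (
    ExpressionTruth,
    generate_gene_sets,
    overlap_permutation,
    rank_enrichment,
    stage_region_grid,
)
from mindnet.simulate import generate_stage_region_sets

universe = [f"G{i:04d}" for i in range(500)]
rng = np.random.default_rng(0)
signal = tuple(sorted(rng.choice(universe, 50, replace=False)))
truth = ExpressionTruth(signal_gene_ids=signal)

sets = generate_gene_sets(universe, truth, n_sets=8, set_size=50, seed=1,
                          enrichment_ratio=5.0)
for name in ("SET01", "SET02"):
    res = overlap_permutation(signal, sets.sets[name], universe,
                              n_perm=10_000, seed=2)
    print(f"{name}: overlap {res.observed:.0f}/50  "
          f"p_perm={res.p_perm:.4f}  p_exact={res.p_exact:.2e}")

ranked = list(signal) + sorted(set(universe) - set(signal))
weights = np.linspace(3, 0.1, len(ranked))
res = rank_enrichment(ranked, weights, sets.sets["SET01"], n_perm=2000,
                      seed=3)
print(f"rank enrichment of SET01 in the signal-first ordering: "
      f"ES={res.observed:.2f}  p={res.p_perm:.4f}")

grid = generate_stage_region_sets(universe, truth, set_size=30, seed=4,
                                  enrichment_ratio=5.0,
                                  enriched_cell=("stage08", "regionA"))
out = stage_region_grid(list(signal), grid, universe)
best = out.nsmallest(1, "q").iloc[0]
print(f"grid cell with smallest q: {best.stage}|{best.region}  "
      f"overlap={best.overlap}  q={best.q:.2e}")
print("SET01 and stage08|regionA were constructed with 5x signal-gene "
      "enrichment; small p/q for exactly those confirms the tests find "
      "planted structure and nothing else.")
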