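"""Imaging-transcriptomics: gene scores and ensemble-based category enrichment.

A synthetic expression bundle is processed AHBA-style (intensity filter,
RNA-seq-guided representative probes, left-hemisphere atlas restriction,
scaled-robust-sigmoid normalisation, differential-stability top-50%).  Each
surviving gene's spatial correlation with a reference map sampled at the
tissue locations is its gene score; category scores are tested against
surrogate maps that preserve the reference map's value distribution and
spatial autocorrelation.
"""

import numpy as np

import falffmap as fm
from falffmap.io import BrainMask
from falffmap.simulate import _grid_affine, gen_parcellation, gen_reference_map

dims = (12, 12, 12)
mask = BrainMask(data=np.ones(dims, bool), affine=_grid_affine(dims))
atlas = gen_parcellation(dims)  # 90-region block atlas
reference = gen_reference_map(mask, seed=100)

cfg = fm.ExpressionSimConfig(n_samples=200, n_genes=400, planted_r=0.8, seed=4)
bundle, annotations, planted = fm.gen_expression_bundle(cfg, reference, mask)
expr = fm.process_expression(bundle, atlas)
print(f"processed matrix: {expr.values.shape[0]} samples x {expr.values.shape[1]} genes "
      f"(from {bundle.probe_expr.shape[0]} probes; decoys and low-DS genes removed)")

samples = fm.extract_values_at_samples(
    reference, expr.sample_mni[["x", "y", "z"]].to_numpy(),
    sample_ids=list(expr.values.index),
)
scores = fm.gene_scores(expr, samples)
print(f"planted genes mean score: {scores[planted].mean():+.3f} "
      f"(target spatial r = {cfg.planted_r}); background: "
      f"{scores.drop(planted).mean():+.3f}")

params = fm.fit_spatial_lag(samples, seed=5)
print(f"fitted spatial-lag surrogate model: rho = {params.rho}, d0 = {params.d0:.1f} mm")
ensemble = fm.generate_surrogates(samples, params, n_surrogate=1000, seed=6)

results = fm.gcea(scores, annotations, expr, samples, ensemble)
print(f"\n{'category':>12} {'n':>4} {'score':>7} {'null mean':>9} {'p':>8} direction")
for c in results[:5]:
    print(f"{c.category_id:>12} {c.n_genes:>4} {c.observed_score:>7.3f} "
          f"{c.null_mean:>9.3f} {c.p_two_sided:>8.4f} {c.direction}")
print("\nCAT_PLANTED aggregates the map-correlated genes: its score sits far "
      "above the surrogate null (p at the estimator floor); random categories "
      "land inside the null band.")
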