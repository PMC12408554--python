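"""Correlate cluster-level imaging summaries with burnout subscale scores.

Within the burnout group, each subject's mean map value over a cluster is
correlated with the Maslach subscales (EE = emotional exhaustion,
DP = depersonalization, PA = personal accomplishment).  Two-sided p-values
come analytically from t = r*sqrt(n-2)/sqrt(1-r^2).
"""

import numpy as np

import falffmap as fm

# At n = 51 the Student-t transform alone reproduces published-scale results:
for r in (-0.290, -0.312, 0.287, -0.308):
    print(f"r = {r:+.3f}, n = 51  ->  p = {fm.pearson_p(r, 51):.3f}")

cfg = fm.SimulationConfig(
    grid_dims=(10, 10, 10), n_timepoints=100, n_per_group=25,
    clinical_coupling=0.5, seed=3,
)
vols, mask, parc, records = fm.gen_bold_cohort(cfg)
cluster = fm.BrainMask(data=parc.labels == cfg.effect_region, affine=mask.affine)
means = [fm.cluster_mean(fm.falff_map(v, mask), cluster) for v in vols]

print("\nsynthetic cohort, coupling 0.5, burnout group (n = 25):")
for a in fm.associate({"effect_cluster_falff": means}, records):
    print(f"  {a.imaging_measure} vs {a.score}: r = {a.r:+.3f}, p = {a.p:.3f}")
print("EE and DP couple negatively to the planted amplitude factor, PA "
      "positively — the correlations above should mirror those signs.")
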