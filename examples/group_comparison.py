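"""Covariate-adjusted group comparison with permutation cluster-level FWE.

A synthetic cohort plants a doubled control-group oscillation amplitude in
one region; the burnout group therefore shows lower fALFF there.  The
voxelwise GLM (intercept, group, age, education, TIV, BAI, BDI) yields a
t-map; clusters above the two-sided voxel p < 0.001 threshold are tested
against the Freedman-Lane permutation distribution of the maximum cluster
size.
"""

import falffmap as fm

cfg = fm.SimulationConfig(
    grid_dims=(12, 12, 12), n_timepoints=120, n_per_group=12,
    amplitude_ratio=2.0, seed=1,
)
vols, mask, parc, records = fm.gen_bold_cohort(cfg)
maps = [fm.fisher_z_standardize(fm.falff_map(v, mask)) for v in vols]

spec = fm.InferenceSpec(voxel_p=0.001, alpha_fwe=0.05, n_perm=500, seed=2)
tmap, clusters = fm.permutation_cluster_fwe(maps, fm.build_design_matrix(records), spec)

print(f"{len(clusters)} suprathreshold cluster(s) "
      f"(voxel p < {spec.voxel_p}, {spec.n_perm} permutations)")
print(f"{'id':>3} {'size':>5} {'peak t':>7} {'MNI (mm)':>18} {'p_FWE':>7}")
for c in clusters:
    x, y, z = c.peak_mni
    print(f"{c.cluster_id:>3} {c.size:>5} {c.peak_t:>7.2f} "
          f"({x:5.0f},{y:5.0f},{z:5.0f}) {c.p_fwe:>7.4f}")
print("\nThe dominant negative-t cluster (hundreds of voxels, p_FWE at the "
      "estimator floor) is the planted burnout amplitude deficit.  Smaller "
      "clusters are noise; with a strong true effect present the max-size "
      "null only controls false positives under the global null, so an "
      "occasional small cluster can cross 0.05.")
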