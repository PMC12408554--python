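# Methods

This note documents the statistical models implemented in `falffmap`, the
conventions chosen where the field leaves room, and what the synthetic-data
generators do and do not emulate.

## fALFF and seed-based FC

A voxel series is demeaned and transformed with a real FFT; the one-sided
square-root power spectrum is scaled so the sum of squared amplitudes equals
the total signal power (Parseval). fALFF is the ratio of summed sqrt-power
in the low-frequency band (default 0.01–0.1 Hz) to that over the analysed
range (default 0.01–0.25 Hz):

- **Ratio of sums, not of means.** With the band nested in the total range
  this bounds fALFF in [0, 1] and matches the original fALFF definition;
  "mean over band / mean over range" would not be bounded by 1.
- **Band edges are closed** (`low ≤ f ≤ high`, with a 1e-12 Hz guard for
  float rounding of bin frequencies); edge bins are vanishingly influential
  at T ≥ 240.
- **Detrending.** The default removes only the mean (the DC bin never lies
  in a band, so a band-limited signal keeps fALFF = 1 to ~1e-14). A linear
  detrend option exists but the fitted line of a finite oscillation is not
  exactly zero, and removing it leaks broadband power below 0.01 Hz
  (measured: a pure in-band cosine drops to fALFF ≈ 0.991). Full acquisition
  preprocessing (slice timing, realignment, smoothing) is out of scope.
- **Degenerate voxels** (zero total-band power) return 0.
- Fisher z is applied as `atanh` directly to fALFF values (valid on [0, 1));
  magnitudes ≥ 1 − 1e-7 are clipped first, which also keeps seed-FC maps
  finite for voxels identical to the seed mean. A mean/SD z-scoring
  alternative is available behind `method="zscore"`.

## Group inference

Per voxel, OLS on [intercept, group (burnout = 1), age, education, TIV, BAI,
BDI]; t = contrast / SE with df = n − rank(X). Voxels whose residual
variance is at floating-point-noise level are treated as degenerate: t = 0
if the contrast estimate is also (relatively) zero, NaN otherwise.

Cluster-level inference is nonparametric: Freedman–Lane permutation (maps
are residualised on the nuisance covariates, residual rows permuted, the
reduced fit added back, and the full-model t-map recomputed), with the
per-permutation **maximum cluster size** as the null statistic. Conventions:

- Cluster-forming threshold: two-sided voxel p < 0.001 (configurable);
  clusters formed per tail; connectivity default 18 (faces + edges),
  configurable to 6 or 26.
- **The FWE family spans both tails jointly**: the null maximum is taken
  over positive and negative clusters together. With two separate per-tail
  nulls each at α the realised family-wise error approaches 2α; the joint
  maximum keeps it at α (verified by simulation: 200 null cohorts fall
  inside the 95% binomial band around 0.05). `tail_family="separate"`
  restores the per-tail reading.
- p_FWE = (1 + #{null ≥ size})/(B + 1), so the smallest attainable value is
  1/(B + 1); peak ties break to the lowest linear voxel index.
- The maximum-cluster-size null controls the family-wise error under the
  global null (weak control); when a strong true effect is present,
  secondary noise clusters can occasionally cross α.

## Clinical association

Plain Pearson within the burnout group, p two-sided from the Student-t
transform on n − 2 df — no covariate partialling (the published p-values at
n = 51 are consistent with df = 49, confirming none was used) and no
multiplicity correction by default (Benjamini–Hochberg behind a flag).

## Expression processing

The probe-to-matrix pipeline follows the standard donor-microarray workflow:

1. **Intensity filter**: probe kept iff above background in ≥ 50% of all
   samples, donors pooled (boundary inclusive).
2. **Representative probes**: genes absent from the RNA-seq reference are
   dropped; per probe, Pearson r against the gene's RNA-seq profile over
   shared samples; r < 0.2 eliminated; per gene the max-r probe is kept,
   ties broken by lexicographically smaller probe id.
3. **Sample restriction**: left hemisphere and exact nearest-voxel
   membership in a nonzero atlas label (no search radius; a tolerance option
   exists behind config).
4. **Scaled robust sigmoid**: s = 1/(1 + exp(−(x − median)/(IQR/1.35))),
   min-max rescaled; constant input maps to 0.5; IQR uses
   linear-interpolation (type-7) quantiles. Applied within sample across
   genes, then within gene across samples; **donor-wise by default**
   (`srs_scope="pooled"` available) — the donor-wise default both normalises
   and absorbs additive donor offsets before concatenation.
5. **Differential stability**: per gene, the mean over donor pairs of the
   Spearman correlation between the donors' region-mean expression vectors
   over shared regions (rank correlation because donors differ in sampled
   regions and monotone donor-specific scalings should not count as
   instability); genes in < 2 donors are excluded with a warning; the top
   50% by DS is retained.

## Surrogate maps and ensemble GCEA

Gene scores are Pearson correlations between each gene's profile and the
statistic map averaged in 3 mm spheres (Euclidean mm, boundary inclusive) at
the sample coordinates. Category significance uses surrogate maps rather
than gene shuffles, so spatial autocorrelation shared by map and expression
does not masquerade as enrichment.

Two generators, both ending in a **rank-remap** that gives every surrogate
exactly the original value multiset:

- **Spatial lag** (default): y = (I − ρW)⁻¹ z with W_ij = exp(−d_ij/d0),
  zero diagonal, row-normalised, ρ ∈ [0, 0.99]; ρ = 0 reduces to value
  permutations.
- **Variogram match**: value permutations smoothed with a Gaussian kernel of
  length d0 (row-normalised, self included), optionally mixed with white
  noise by weight α. This family tracks strongly smooth maps better than
  the lag model, whose neighbour correlation saturates on scattered points.

Parameters are fitted by grid search against the observed empirical
variogram (mean semivariance in 10 log-spaced distance bins between the 5th
and 95th percentile of pairwise distances). The objective is the Gaussian
negative log-likelihood of the observed variogram under each candidate's
pilot ensemble (per-bin mean and spread over 100 pilots): the log-variance
term stops overdispersed candidates from "fitting" noise. For the lag model
an AIC-style rule then prefers the weakest autocorrelation among candidates
within 2 NLL units, so white noise identifies ρ ≈ 0 while genuinely smooth
fields keep large ρ. The variogram-match fit adds a local refinement of
(d0, α) around the grid optimum.

GCEA: categories restricted to 10–200 annotated genes among finitely scored
genes; observed score = mean member gene score; for every surrogate all gene
scores are recomputed as one matrix product of column-standardised
expression with column-standardised surrogate maps (this same code path
produces the observed scores, so they equal the standalone gene scores bit
for bit); p = 2·min(add-one-smoothed tail fractions), capped at 1 — never
exactly zero, floor 2/(S + 1). GO hierarchy propagation is out of scope:
annotations are taken as given (direct gene-to-category).

## Neurotransmitter-map association

Region means over a 90-region atlas; the association is the Pearson
correlation of the residuals of both vectors after regression on region-mean
gray-matter probability (symmetric partial correlation — partialling only
one side would leave GM-driven variance in the other). The null draws
surrogate region vectors of the statistic map at region-centroid geometry
(reusing the surrogate machinery above); p two-sided on |r|,
(1 + #{|null| ≥ |obs|})/(B + 1). A vector fully explained by GM is assigned
partial correlation 0; both degenerate is an error. Calibration is
approximate — the surrogate family cannot represent every map exactly — and
measured slightly anti-conservative (9% rejections at nominal 5% over 100
independent receptor maps), within the binomial band of the nominal level.

## Synthetic data

`gen_bold_cohort` emulates a two-group resting-state cohort: per voxel,
AR(1) Gaussian noise (unit stationary variance, ρ = 0.4) plus a band-limited
oscillation — five sinusoids with random phases at frequencies uniform in
[0.02, 0.08] Hz, safely interior to the 0.01–0.1 Hz band at TR = 2 s —
shared within each atlas region (which also gives seed-FC its structure).
Controls' oscillation amplitude in the effect region is multiplied by
`amplitude_ratio` (default 2), planting lower low-frequency amplitude in the
burnout group. A lognormal per-subject amplitude factor is linked to the
clinical scores through a Gaussian copula (EE, DP negatively; PA positively;
default |r| = 0.3, the size of the published clinical correlations);
covariates are drawn group-balanced and the score distributions mirror the
screening cuts of the two arms (51 per group by default). Defaults use a
12³ voxel grid at 3 mm — the statistical structure, not the anatomy, is what
is emulated; there is no hemodynamic response, physiological noise, motion,
or spatial smoothing of the noise field.

`gen_expression_bundle` draws sample locations at distinct in-mask voxel
centers, plus a few right-hemisphere decoys for the hemisphere filter. Gene
profiles are Gaussian random fields (distance-kernel-smoothed white noise,
kernel scale 6 mm); observation noise (SD 0.6 of the unit field) and
additive donor offsets (SD 0.3, 3 donors) put the background differential
stability in a realistic mid-range. Planted genes are mixed with the
reference map to an **exact** empirical spatial correlation before noise,
and represent the high-stability end of the spectrum: their residual
component is smoother (2× kernel length) and their noise smaller (0.4×), so
they rank above the DS median and survive the top-50% cut by construction
design, not by luck. Decoy probes are constructed to fail specific filters
(below background in 60% of samples; pure noise vs. RNA-seq). One
annotation category is exactly the planted set. The reference map a caller
plants against should be at least as smooth as the gene fields (true of real
smoothed statistic maps); planting against a spatially rough map gives the
planted genes rough profiles and correspondingly low DS.

**Spatial scales.** Correlation lengths default to 6 mm (genes, the
`gen_reference_map` stand-in statistic map) inside the 36 mm default grid —
the same smoothness-to-extent ratio as an ~8–12 mm-smooth statistic map in a
~150 mm brain. This ratio matters: when a map's correlation length is an
appreciable fraction of the sampled volume it carries only a handful of
independent spatial patches, and no conditional surrogate method can
calibrate per realization in that regime. Note also that at planted_r = 0
the planted genes are *exactly orthogonal* to the reference (pinned scores,
not null draws); calibration experiments should therefore generate with
`planted_genes=0`.

`gen_receptor_maps` paints region-level values into voxels with slight
noise. The mix with the reference is by **independent** noise
(E[r] = target, sampling SD √((1−r²)/n)), not exact orthogonalisation: a
target-0 map must be independent of the reference, with genuine sampling
variability, for permutation-p calibration checks to be meaningful.

## Problem sizes used in tests

The test and acceptance suites run the study's analyses at reduced scale
chosen once: 12³ grids (3 mm), 120–240 timepoints, 10–20 subjects per group,
500 permutations, 200 expression samples, 400 genes, 1,000 surrogates,
200 null cohorts for FWER calibration, 500 null categories spread over 10
independent expression/map realizations for GCEA calibration, and 20 seeds
for each power check.
Study-scale counts (10,000 surrogates, 5,000 spatial permutations, 51 per
group) remain the package defaults.

## Known limitations

- The published voxelwise group maps, GO term lists and receptor
  correlations require the raw fMRI, donor expression, GO and PET data,
  which are not redistributable inputs here; the pipeline's operating
  characteristics are validated on synthetic data instead.
- Cluster FWE is permutation-based, not random-field theory; published
  cluster statistics serve as reporting-contract fixtures rather than
  recomputation targets.
- The spatial-lag surrogate family saturates on very smooth maps; the
  variogram-match generator is provided for fidelity-critical uses, and
  which of the two a given study actually used is treated as open — both
  satisfy the same ensemble invariants.
- Spatial-null p-values (GCEA, receptor maps) are approximate by nature:
  the ensemble conditions on one observed map, so per-realization p-value
  uniformity holds only on average over the generating distribution, with a
  mild residual conservatism (measured null medians ~0.52–0.54) because the
  surrogate family cannot represent every realization exactly. Null
  rejection rates at α = 0.05 are nominal throughout.
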