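"""AHBA-style expression processing.

The pipeline mirrors the standard microarray workflow for donor brain
expression: probes must beat background noise in at least half of all samples
pooled across donors; genes absent from the RNA-seq reference are dropped and
each remaining gene keeps its probe best correlated with RNA-seq (probes with
r < 0.2 eliminated); samples are restricted to left-hemisphere locations that
fall inside the parcellation; expression is scaled-robust-sigmoid (SRS)
normalised within sample across genes and then within gene across samples
(donor-wise by default); finally genes are ranked by differential stability
(DS) — the mean inter-donor Spearman correlation of region-mean expression —
and the top fraction (default 50%) retained.
"""

from __future__ import annotations

import dataclasses
import warnings
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from falffmap.io import Parcellation, world_to_voxel

__all__ = [
    "ExpressionBundle",
    "GeneExpressionMatrix",
    "intensity_filter",
    "select_representative_probes",
    "filter_samples",
    "srs_normalize",
    "differential_stability",
    "top_ds",
    "process_expression",
]


@dataclasses.dataclass
class ExpressionBundle:
    """Raw probe-level expression with everything the filters need.

    probe_expr: probe x sample values (DataFrame, index = probe ids)
    probe_gene: probe id -> gene symbol
    above_background: probe x sample booleans, aligned with probe_expr
    rnaseq_expr: gene x sample reference values (subset of genes/samples)
    sample_mni: sample id -> (x, y, z) mm  (DataFrame, columns x/y/z)
    sample_donor: sample id -> donor id
    sample_hemisphere: sample id -> 'left' | 'right'
    """

    probe_expr: pd.DataFrame
    probe_gene: pd.Series
    above_background: pd.DataFrame
    rnaseq_expr: pd.DataFrame
    sample_mni: pd.DataFrame
    sample_donor: pd.Series
    sample_hemisphere: pd.Series

    def __post_init__(self) -> None:
        if not self.probe_expr.index.equals(self.above_background.index):
            raise ValueError("probe_expr and above_background probe ids differ")
        if list(self.probe_expr.columns) != list(self.above_background.columns):
            raise ValueError("probe_expr and above_background samples differ")
        missing = set(self.probe_expr.index) - set(self.probe_gene.index)
        if missing:
            raise ValueError(f"{len(missing)} probes lack a gene symbol")


@dataclasses.dataclass
class GeneExpressionMatrix:
    """Processed sample x gene matrix, values normalised to [0, 1]."""

    values: pd.DataFrame  # samples x genes
    sample_mni: pd.DataFrame
    sample_region: pd.Series
    sample_donor: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list:
        return list(self.values.index)


def intensity_filter(bundle: ExpressionBundle) -> list:
    """Probes that beat background noise in >= 50% of all samples (donors pooled)."""
    frac = bundle.above_background.mean(axis=1)
    return list(bundle.probe_expr.index[frac >= 0.5])


def select_representative_probes(
    bundle: ExpressionBundle, retained: Sequence
) -> dict[str, object]:
    """One representative probe per gene, guided by the RNA-seq reference.

    Genes absent from the RNA-seq data are dropped.  Per probe, Pearson r
    against the gene's RNA-seq profile over shared samples is computed;
    probes with r < 0.2 are eliminated and the max-r probe wins (ties go to
    the lexicographically smaller probe id).  Genes with no surviving probe
    are dropped.
    """
    retained = [p for p in retained if p in bundle.probe_expr.index]
    shared = [s for s in bundle.probe_expr.columns if s in bundle.rnaseq_expr.columns]
    if len(shared) < 3:
        raise ValueError("fewer than 3 samples shared with the RNA-seq reference")
    best: dict[str, tuple[float, object]] = {}
    for probe in retained:
        gene = bundle.probe_gene[probe]
        if gene not in bundle.rnaseq_expr.index:
            continue
        x = bundle.probe_expr.loc[probe, shared].to_numpy(dtype=float)
        y = bundle.rnaseq_expr.loc[gene, shared].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r < 0.2:
            continue
        prev = best.get(gene)
        if prev is None or r > prev[0] or (r == prev[0] and str(probe) < str(prev[1])):
            best[gene] = (r, probe)
    return {gene: probe for gene, (_, probe) in best.items()}


def filter_samples(bundle: ExpressionBundle, parcellation: Parcellation) -> pd.Series:
    """Samples kept for analysis: left hemisphere and inside the atlas.

    A sample's MNI coordinate is mapped to its nearest voxel (no search
    radius); it is kept iff that voxel carries a nonzero label.  Returns a
    Series sample id -> region id for the retained samples.
    """
    ids, regions = [], []
    vox = world_to_voxel(parcellation.affine, bundle.sample_mni[["x", "y", "z"]].to_numpy())
    vox = np.rint(vox).astype(int)
    shape = parcellation.labels.shape
    for sid, ijk in zip(bundle.sample_mni.index, vox):
        if bundle.sample_hemisphere[sid] != "left":
            continue
        if np.any(ijk < 0) or np.any(ijk >= shape):
            continue
        label = int(parcellation.labels[tuple(ijk)])
        if label == 0:
            continue
        ids.append(sid)
        regions.append(label)
    return pd.Series(regions, index=ids, name="region")


def srs_normalize(values: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid: sigmoid of (x - median)/(IQR/1.35), min-max
    rescaled to [0, 1].  Constant input returns all 0.5."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])  # linear-interpolation quantiles
    iqr = q75 - q25
    if iqr == 0:
        if np.all(x == x[0]):
            return np.full_like(x, 0.5)
        # zero IQR but non-constant: sigmoid saturates to {0, 1/2, 1} by sign
        s = np.where(x > med, 1.0, np.where(x < med, 0.0, 0.5))
    else:
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    rng = s.max() - s.min()
    if rng == 0:
        return np.full_like(x, 0.5)
    return (s - s.min()) / rng


def differential_stability(
    donor_region_means: Mapping[object, pd.DataFrame]
) -> pd.Series:
    """DS per gene: mean Spearman correlation over donor pairs of the two
    donors' region-mean expression vectors, over their shared regions.

    ``donor_region_means`` maps donor id -> region x gene DataFrame.  Genes
    present in fewer than 2 donors are excluded (with a warning); donor pairs
    sharing fewer than 3 regions do not contribute.
    """
    donors = list(donor_region_means)
    if len(donors) < 2:
        raise ValueError("DS requires at least 2 donors")
    all_genes: list[str] = []
    for df in donor_region_means.values():
        for g in df.columns:
            if g not in all_genes:
                all_genes.append(g)
    ds: dict[str, float] = {}
    skipped = 0
    for gene in all_genes:
        having = [d for d in donors if gene in donor_region_means[d].columns]
        if len(having) < 2:
            skipped += 1
            continue
        rhos = []
        for d1, d2 in combinations(having, 2):
            a = donor_region_means[d1][gene].dropna()
            b = donor_region_means[d2][gene].dropna()
            common = a.index.intersection(b.index)
            if len(common) < 3:
                continue
            rho = stats.spearmanr(a[common], b[common]).statistic
            if np.isfinite(rho):
                rhos.append(rho)
        if rhos:
            ds[gene] = float(np.mean(rhos))
    if skipped:
        warnings.warn(f"{skipped} gene(s) present in < 2 donors excluded from DS", stacklevel=2)
    return pd.Series(ds, name="ds")


def top_ds(ds: pd.Series, fraction: float = 0.5) -> list[str]:
    """The ceil(fraction * G) genes with the highest DS."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.ceil(fraction * len(ds)))
    return list(ds.sort_values(ascending=False, kind="stable").index[:k])


def process_expression(
    bundle: ExpressionBundle,
    parcellation: Parcellation,
    ds_fraction: float = 0.5,
    srs_scope: str = "donor",
) -> GeneExpressionMatrix:
    """Run the full probe-to-matrix pipeline.

    Steps: intensity filter -> RNA-seq-guided representative probes -> sample
    restriction (left hemisphere, inside atlas) -> SRS normalisation (within
    sample across genes, then within gene across samples; applied donor-wise
    when ``srs_scope='donor'``, pooled when ``'pooled'``) -> DS top-fraction
    gene selection.
    """
    if srs_scope not in ("donor", "pooled"):
        raise ValueError("srs_scope must be 'donor' or 'pooled'")
    retained = intensity_filter(bundle)
    gene_probe = select_representative_probes(bundle, retained)
    if not gene_probe:
        raise ValueError("no gene survived probe selection")
    sample_region = filter_samples(bundle, parcellation)
    if len(sample_region) == 0:
        raise ValueError("no sample survived hemisphere/atlas restriction")
    genes = sorted(gene_probe)
    probes = [gene_probe[g] for g in genes]
    mat = bundle.probe_expr.loc[probes, sample_region.index].T.astype(float)
    mat.columns = genes  # samples x genes

    donors = bundle.sample_donor[sample_region.index]
    blocks = [mat.index] if srs_scope == "pooled" else [
        donors.index[donors == d] for d in donors.unique()
    ]
    norm = mat.copy()
    for block in blocks:
        sub = norm.loc[block].to_numpy()
        # within-sample across genes, then within-gene across samples
        sub = np.apply_along_axis(srs_normalize, 1, sub)
        sub = np.apply_along_axis(srs_normalize, 0, sub)
        norm.loc[block] = sub

    region_means = {
        d: norm.loc[donors.index[donors == d]].groupby(
            sample_region[donors.index[donors == d]]
        ).mean()
        for d in donors.unique()
    }
    if len(region_means) >= 2:
        ds = differential_stability(region_means)
        keep = [g for g in genes if g in set(top_ds(ds, ds_fraction))]
    else:
        warnings.warn("single donor: DS selection skipped", stacklevel=2)
        keep = genes
    return GeneExpressionMatrix(
        values=norm[keep],
        sample_mni=bundle.sample_mni.loc[sample_region.index],
        sample_region=sample_region,
        sample_donor=donors,
    )
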