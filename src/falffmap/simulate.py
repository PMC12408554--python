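"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators make every downstream stage testable without any download:

- :func:`gen_bold_cohort` — a two-group resting-state cohort.  Each voxel's
  series is AR(1) Gaussian noise plus a band-limited oscillation (sum of five
  random-phase sinusoids at frequencies uniform in 0.02-0.08 Hz, shared
  within a region).  Controls' oscillation amplitude inside the effect region
  is multiplied by ``amplitude_ratio`` (> 1 plants lower low-frequency
  amplitude in the burnout group).  A per-subject amplitude factor is coupled
  to the clinical scores through a Gaussian copula so that
  corr(amplitude, EE) ~ -|clinical_coupling| and corr(amplitude, PA) ~
  +|clinical_coupling|.
- :func:`gen_expression_bundle` — spatially autocorrelated gene expression
  (distance-kernel-smoothed white noise) over sample locations inside a mask,
  with donor-consistent profiles, decoy probes constructed to fail the
  intensity and RNA-seq filters, and a planted gene set mixed with a
  reference map to an exact target spatial correlation; the annotation table
  contains one category that is exactly the planted set.
- :func:`gen_receptor_maps` — density-like maps whose region-level
  correlation with a reference map hits a requested target.

Every generator is bitwise deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from falffmap.expression import ExpressionBundle
from falffmap.io import (
    BrainMask,
    Parcellation,
    StatMap,
    SubjectRecord,
    Volume4D,
    voxel_to_world,
)

__all__ = [
    "SimulationConfig",
    "ExpressionSimConfig",
    "gen_bold_cohort",
    "gen_expression_bundle",
    "gen_receptor_maps",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings; defaults mirror the study conditions
    (51 subjects per group, TR 2 s, 240 timepoints) at desk-scale grid size."""

    grid_dims: tuple[int, int, int] = (12, 12, 12)
    n_timepoints: int = 240
    tr: float = 2.0
    n_per_group: int = 51
    n_regions: int = 6
    effect_region: int = 3
    amplitude_ratio: float = 2.0
    ar1_rho: float = 0.4
    clinical_coupling: float = 0.3
    osc_amplitude: float = 0.5
    subject_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude_ratio must be > 0")
        if not abs(self.clinical_coupling) < 1:
            raise ValueError("|clinical_coupling| must be < 1")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.n_timepoints < 8:
            raise ValueError("need at least 8 timepoints")


@dataclasses.dataclass(frozen=True)
class ExpressionSimConfig:
    n_samples: int = 200
    n_genes: int = 500
    autocorr_length: float = 6.0
    planted_genes: int = 15
    planted_r: float = 0.8
    n_categories: int = 20
    category_size_range: tuple[int, int] = (10, 40)
    n_donors: int = 3
    noise_sd: float = 0.6
    donor_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_genes > self.n_genes:
            raise ValueError("planted_genes must not exceed n_genes")
        if not abs(self.planted_r) < 1:
            raise ValueError("|planted_r| must be < 1")
        if not 2 <= self.n_donors <= 6:
            raise ValueError("n_donors must be between 2 and 6")
        lo, hi = self.category_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid category_size_range")


def _grid_affine(dims: Sequence[int], voxel_mm: float = 3.0) -> np.ndarray:
    """Isotropic affine centring the grid on MNI (0, 0, 0)."""
    A = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    A[:3, 3] = -voxel_mm * (np.asarray(dims) - 1) / 2.0
    return A


def _slab_parcellation(dims: Sequence[int], n_regions: int, affine: np.ndarray) -> Parcellation:
    """Contiguous slabs along x, labelled 1..n_regions."""
    labels = np.zeros(tuple(dims), dtype=int)
    edges = np.linspace(0, dims[0], n_regions + 1).astype(int)
    for r in range(n_regions):
        labels[edges[r] : edges[r + 1]] = r + 1
    return Parcellation(labels=labels, affine=affine)


def gen_parcellation(
    dims: Sequence[int], blocks: tuple[int, int, int] = (5, 6, 3), affine: np.ndarray | None = None
) -> Parcellation:
    """A 90-region-style block atlas: the grid split into blocks[0] x
    blocks[1] x blocks[2] rectangular regions labelled 1..prod(blocks)."""
    dims = tuple(dims)
    if affine is None:
        affine = _grid_affine(dims)
    labels = np.zeros(dims, dtype=int)
    xs = np.array_split(np.arange(dims[0]), blocks[0])
    ys = np.array_split(np.arange(dims[1]), blocks[1])
    zs = np.array_split(np.arange(dims[2]), blocks[2])
    lab = 1
    for x in xs:
        for y in ys:
            for z in zs:
                labels[np.ix_(x, y, z)] = lab
                lab += 1
    return Parcellation(labels=labels, affine=affine)


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size)
    return np.clip(out, low, high)


def _coupled_scores(rng, g_amp: np.ndarray, coupling: float, mean, sd, sign):
    """Score with a Gaussian-copula link to the latent amplitude factor."""
    c = sign * abs(coupling)
    latent = c * g_amp + np.sqrt(1 - c * c) * rng.standard_normal(g_amp.shape)
    return np.clip(mean + sd * latent, 0, None)


def gen_bold_cohort(
    cfg: SimulationConfig = SimulationConfig(),
) -> tuple[list[Volume4D], BrainMask, Parcellation, list[SubjectRecord]]:
    """Synthetic two-group BOLD cohort with a planted low-frequency
    amplitude effect and clinically coupled scores.

    Burnout subjects come first in all returned lists.
    """
    dims = tuple(cfg.grid_dims)
    affine = _grid_affine(dims)
    mask = BrainMask(data=np.ones(dims, dtype=bool), affine=affine)
    parc = _slab_parcellation(dims, cfg.n_regions, affine)
    if cfg.effect_region not in parc.region_ids:
        raise ValueError(
            f"effect_region {cfg.effect_region} absent from parcellation {parc.region_ids}"
        )
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_timepoints
    t = np.arange(T) * cfg.tr
    n_total = 2 * cfg.n_per_group
    groups = ["burnout"] * cfg.n_per_group + ["control"] * cfg.n_per_group

    # latent per-subject amplitude factor (lognormal around 1)
    g_amp = rng.standard_normal(n_total)
    f_subj = np.exp(cfg.subject_sd * g_amp)

    innov_sd = np.sqrt(1.0 - cfg.ar1_rho**2)  # unit stationary variance
    region_vox = {r: parc.labels == r for r in parc.region_ids}

    volumes: list[Volume4D] = []
    for s in range(n_total):
        data = np.empty(dims + (T,), dtype=np.float32)
        # AR(1) noise, vectorised over voxels
        noise = np.empty((np.prod(dims), T))
        noise[:, 0] = rng.standard_normal(np.prod(dims))
        eps = rng.standard_normal((np.prod(dims), T - 1)) * innov_sd
        for k in range(1, T):
            noise[:, k] = cfg.ar1_rho * noise[:, k - 1] + eps[:, k - 1]
        data[:] = noise.reshape(dims + (T,))
        # region-shared band-limited oscillations
        for r in parc.region_ids:
            freqs = rng.uniform(0.02, 0.08, 5)
            phases = rng.uniform(0, 2 * np.pi, 5)
            osc = np.sum(
                np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0
            )
            amp = cfg.osc_amplitude * f_subj[s]
            if r == cfg.effect_region and groups[s] == "control":
                amp *= cfg.amplitude_ratio
            data[region_vox[r]] += (amp * osc).astype(np.float32)
        volumes.append(Volume4D(data=data, affine=affine, tr=cfg.tr))

    # covariates group-balanced; burnout scores shifted per the screening cuts
    age = _truncated_normal(rng, 33, 5, 20, 40, n_total)
    education = _truncated_normal(rng, 16, 1, 12, 22, n_total)
    tiv = rng.normal(1420, 130, n_total)
    is_b = np.array([g == "burnout" for g in groups])
    bai = np.clip(rng.normal(np.where(is_b, 29, 24), np.where(is_b, 6, 3)), 0, None)
    bdi = np.clip(rng.normal(np.where(is_b, 9, 3.5), np.where(is_b, 7, 4)), 0, None)
    ee = _coupled_scores(rng, g_amp, cfg.clinical_coupling, np.where(is_b, 30, 13),
                         np.where(is_b, 8, 6), sign=-1)
    dp = _coupled_scores(rng, g_amp, cfg.clinical_coupling, np.where(is_b, 12, 3),
                         np.where(is_b, 5, 3), sign=-1)
    pa = _coupled_scores(rng, g_amp, cfg.clinical_coupling, np.where(is_b, 22, 39),
                         np.where(is_b, 8, 7), sign=+1)

    records = [
        SubjectRecord(
            subject_id=f"sub-{s:03d}",
            group=groups[s],
            age=float(age[s]),
            education=float(education[s]),
            tiv=float(tiv[s]),
            bai=float(bai[s]),
            bdi=float(bdi[s]),
            ee=float(ee[s]),
            dp=float(dp[s]),
            pa=float(pa[s]),
        )
        for s in range(n_total)
    ]
    return volumes, mask, parc, records


# ---------------------------------------------------------------------------
# expression bundle

def gen_reference_map(
    mask: BrainMask, smoothing_mm: float = 6.0, seed: int = 0, kind: str = "tmap"
) -> StatMap:
    """A smooth standardized random field on the mask's grid — a stand-in
    for a (spatially smoothed) group statistic map when planting expression
    or receptor effects.  NaN outside the mask."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    voxel_mm = float(np.cbrt(abs(np.linalg.det(mask.affine[:3, :3]))))
    field = gaussian_filter(rng.standard_normal(mask.data.shape), smoothing_mm / voxel_mm)
    vals = field[mask.data]
    field = (field - vals.mean()) / vals.std()
    data = np.where(mask.data, field, np.nan)
    return StatMap(data=data, affine=mask.affine, kind=kind)

def _grf_profiles(rng, coords: np.ndarray, n_fields: int, length: float) -> np.ndarray:
    """Gaussian random fields at given locations: distance-kernel smoothing of
    white noise with kernel scale = length (mm); columns standardised."""
    diff = coords[:, None, :] - coords[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    K = np.exp(-0.5 * (D / length) ** 2)
    fields = K @ rng.standard_normal((coords.shape[0], n_fields))
    fields -= fields.mean(axis=0)
    sd = fields.std(axis=0)
    sd[sd == 0] = 1.0
    return fields / sd


def _exact_mix(z_ref: np.ndarray, raw: np.ndarray, r: float) -> np.ndarray:
    """Field with empirical corr(z_ref, field) exactly r (unit variance)."""
    resid = raw - (raw @ z_ref) / (z_ref @ z_ref) * z_ref
    sd = resid.std()
    if sd == 0:
        raise ValueError("degenerate residual field")
    zres = (resid - resid.mean()) / sd
    return r * z_ref + np.sqrt(1 - r * r) * zres


def gen_expression_bundle(
    cfg: ExpressionSimConfig, reference: StatMap, mask: BrainMask
) -> tuple[ExpressionBundle, dict[str, tuple[str, list[str]]], list[str]]:
    """Synthetic expression bundle, annotation table, and planted gene list.

    Sample locations are distinct in-mask voxel centers (plus a few
    right-hemisphere decoy samples that the hemisphere filter must drop).
    Each gene's spatial profile is a Gaussian random field; the planted genes
    are mixed with the reference map's values to an exact target spatial
    correlation before observation noise.  Probes include decoys failing the
    intensity filter (below background in 60% of samples) and the RNA-seq
    correlation filter (pure noise).  One annotation category is exactly the
    planted set.
    """
    rng = np.random.default_rng(cfg.seed)
    in_mask = np.argwhere(mask.data)
    if in_mask.shape[0] < cfg.n_samples:
        raise ValueError(
            f"mask has {in_mask.shape[0]} voxels; cannot place {cfg.n_samples} distinct samples"
        )
    pick = rng.choice(in_mask.shape[0], size=cfg.n_samples, replace=False)
    vox = in_mask[pick]
    coords = voxel_to_world(mask.affine, vox)
    ref_at = np.asarray(reference.data, dtype=float)[vox[:, 0], vox[:, 1], vox[:, 2]]
    if not np.all(np.isfinite(ref_at)):
        raise ValueError("reference map must be finite inside the mask")
    z_ref = (ref_at - ref_at.mean()) / (ref_at.std() if ref_at.std() > 0 else 1.0)

    n, G = cfg.n_samples, cfg.n_genes
    genes = [f"G{g:04d}" for g in range(G)]
    planted = genes[: cfg.planted_genes]
    fields = _grf_profiles(rng, coords, G, cfg.autocorr_length)
    # planted genes model the high-stability, map-patterned genes: their
    # residual component is smoother than the background genes'
    planted_resid = _grf_profiles(rng, coords, cfg.planted_genes, 2 * cfg.autocorr_length)
    for j in range(cfg.planted_genes):
        fields[:, j] = _exact_mix(z_ref, planted_resid[:, j], cfg.planted_r)

    donors = np.array([f"D{1 + i % cfg.n_donors}" for i in range(n)])
    donor_offsets = {
        d: rng.normal(0, cfg.donor_sd, G) for d in sorted(set(donors))
    }

    sample_ids = [f"S{i:04d}" for i in range(n)]
    # observed microarray intensities: baseline + field + donor offset + noise.
    # Planted genes get less noise so they rank above the median differential
    # stability and reliably survive the top-fraction DS cut.
    noise_scale = np.ones(G)
    noise_scale[: cfg.planted_genes] = 0.4
    expr = 7.0 + fields + rng.normal(0, cfg.noise_sd, (n, G)) * noise_scale
    for d, off in donor_offsets.items():
        expr[donors == d] += off * noise_scale

    # RNA-seq reference tracks the true field for a subset of genes
    rnaseq_genes = genes[: int(0.9 * G)] if G >= 10 else genes
    rnaseq = pd.DataFrame(
        (fields[:, : len(rnaseq_genes)] + rng.normal(0, 0.2, (n, len(rnaseq_genes)))).T,
        index=rnaseq_genes,
        columns=sample_ids,
    )

    probe_rows, probe_genes, bg_rows = [], [], []
    probe_ids = []
    for j, g in enumerate(genes):
        probe_ids.append(f"p{j:04d}_a")
        probe_genes.append(g)
        probe_rows.append(expr[:, j])
        bg_rows.append(rng.random(n) < 0.95)
        if j % 7 == 0:
            # intensity-filter decoy: below background in 60% of samples
            probe_ids.append(f"p{j:04d}_bg")
            probe_genes.append(g)
            probe_rows.append(expr[:, j] * 0.5 + rng.normal(0, 0.5, n))
            bg_rows.append(rng.random(n) >= 0.6)
        elif j % 7 == 1:
            # RNA-seq-filter decoy: noise uncorrelated with the gene field
            probe_ids.append(f"p{j:04d}_nz")
            probe_genes.append(g)
            probe_rows.append(7.0 + rng.normal(0, 1.0, n))
            bg_rows.append(np.ones(n, dtype=bool))
        elif j % 7 == 2:
            # weaker secondary probe: representative selection must prefer _a
            probe_ids.append(f"p{j:04d}_w")
            probe_genes.append(g)
            probe_rows.append(7.0 + 0.6 * fields[:, j] + rng.normal(0, 0.8, n))
            bg_rows.append(np.ones(n, dtype=bool))

    # right-hemisphere decoy samples appended after the in-mask ones
    n_right = max(2, n // 20)
    right_ids = [f"S{n + i:04d}R" for i in range(n_right)]
    right_coords = coords[:n_right].copy()
    right_coords[:, 0] = np.abs(right_coords[:, 0]) + 50.0  # far right of any label
    all_ids = sample_ids + right_ids
    probe_expr = pd.DataFrame(
        np.column_stack(
            [np.array(probe_rows), rng.normal(7.0, 1.0, (len(probe_rows), n_right))]
        ),
        index=probe_ids,
        columns=all_ids,
    )
    above = pd.DataFrame(
        np.column_stack(
            [np.array(bg_rows), np.ones((len(bg_rows), n_right), dtype=bool)]
        ).astype(bool),
        index=probe_ids,
        columns=all_ids,
    )
    mni = pd.DataFrame(
        np.vstack([coords, right_coords]), index=all_ids, columns=["x", "y", "z"]
    )
    donor_s = pd.Series(
        list(donors) + [f"D{1 + i % cfg.n_donors}" for i in range(n_right)], index=all_ids
    )
    hemi = pd.Series(["left"] * n + ["right"] * n_right, index=all_ids)

    bundle = ExpressionBundle(
        probe_expr=probe_expr,
        probe_gene=pd.Series(probe_genes, index=probe_ids),
        above_background=above,
        rnaseq_expr=rnaseq,
        sample_mni=mni,
        sample_donor=donor_s,
        sample_hemisphere=hemi,
    )

    aspects = ("BP", "CC", "MF")
    annotations: dict[str, tuple[str, list[str]]] = {
        "CAT_PLANTED": ("BP", list(planted))
    }
    lo, hi = cfg.category_size_range
    for c in range(cfg.n_categories - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes[cfg.planted_genes :], size=min(size, G - cfg.planted_genes),
                             replace=False)
        annotations[f"CAT_{c:03d}"] = (aspects[c % 3], sorted(members))
    return bundle, annotations, list(planted)


# ---------------------------------------------------------------------------
# receptor maps

def gen_receptor_maps(
    reference: StatMap,
    target_rs: Sequence[float],
    mask: BrainMask,
    seed: int,
    parcellation: Parcellation,
    names: Sequence[str] | None = None,
) -> list[StatMap]:
    """Density-like maps whose region-mean correlation with the reference
    (over the parcellation) is within about +-0.1 of each target."""
    if len(target_rs) == 0:
        raise ValueError("target_rs must not be empty")
    for r in target_rs:
        if not abs(r) < 1:
            raise ValueError(f"|target r| must be < 1, got {r}")
    from falffmap.neuromap import parcellate  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    ref_regions = parcellate(reference, parcellation)
    rids = ref_regions.region_ids
    ref_vec = ref_regions.aligned(rids)
    sd = ref_vec.std()
    z_ref = (ref_vec - ref_vec.mean()) / (sd if sd > 0 else 1.0)

    out = []
    for i, r in enumerate(target_rs):
        # independent-noise mix: E[corr] = r with sampling sd sqrt((1-r^2)/n).
        # (An exactly-orthogonalised mix would pin corr to r but make
        # null-calibration checks at r=0 degenerate.)
        raw = rng.standard_normal(len(rids))
        y = r * z_ref + np.sqrt(1 - r * r) * (raw - raw.mean()) / raw.std()
        data = np.full(parcellation.labels.shape, np.nan)
        for rid, val in zip(rids, y):
            sel = (parcellation.labels == rid) & mask.data
            data[sel] = 10.0 + 2.0 * val + rng.normal(0, 0.05, int(sel.sum()))
        out.append(StatMap(data=data, affine=parcellation.affine, kind="receptor"))
    return out
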