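"""Parcel-level spatial correlation with neurotransmitter density maps.

The group t-map and each receptor/transporter map are reduced to region means
over the parcellation (90-region AAL-style).  Their association is the
partial Pearson correlation after regressing both vectors on region-mean
gray-matter probability (partial-volume adjustment); significance comes from
spatial-autocorrelation-preserving surrogate region vectors of the t-map
(region centroids as the geometry), so the null respects the map's spatial
structure.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from falffmap.io import Parcellation, StatMap, voxel_to_world
from falffmap.gcea import SurrogateEnsemble

__all__ = [
    "RegionVector",
    "NeuromapResult",
    "parcellate",
    "region_centroids",
    "partial_spatial_corr",
    "neuromap_permutation_p",
]


@dataclasses.dataclass
class RegionVector:
    """region_id -> mean map value; regions with no finite voxel are absent."""

    values: dict[int, float]

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.values)

    def aligned(self, region_ids) -> np.ndarray:
        return np.array([self.values[r] for r in region_ids])


@dataclasses.dataclass
class NeuromapResult:
    map_name: str
    r_partial: float
    p_perm: float
    n_perm: int
    n_regions: int


def parcellate(statmap: StatMap, parcellation: Parcellation) -> RegionVector:
    """Unweighted mean of finite map voxels per region; empty regions are
    flagged (warned) and omitted, to be excluded pairwise downstream."""
    if statmap.data.shape != parcellation.labels.shape:
        raise ValueError("map and parcellation grids differ")
    data = np.asarray(statmap.data, dtype=float)
    out: dict[int, float] = {}
    empty = []
    for rid in parcellation.region_ids:
        vals = data[parcellation.labels == rid]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            empty.append(rid)
            continue
        out[rid] = float(vals.mean())
    if not out:
        raise ValueError("no region overlaps any finite voxel")
    if empty:
        warnings.warn(f"region(s) {empty} contain no finite voxel", stacklevel=2)
    return RegionVector(values=out)


def region_centroids(parcellation: Parcellation, region_ids=None) -> np.ndarray:
    """Region centroids in MNI mm (mean of member voxel centers)."""
    ids = parcellation.region_ids if region_ids is None else list(region_ids)
    cents = []
    for rid in ids:
        ijk = np.argwhere(parcellation.labels == rid)
        if ijk.size == 0:
            raise ValueError(f"region {rid} has no voxels")
        cents.append(voxel_to_world(parcellation.affine, ijk).mean(axis=0))
    return np.array(cents)


def _residualize(v: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Residuals of v after OLS on [1, g]."""
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_spatial_corr(x: np.ndarray, y: np.ndarray, gm: np.ndarray) -> float:
    """Pearson correlation of x and y after each is regressed on the
    gray-matter vector (with intercept).  Equals plain Pearson when gm is
    constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gm = np.asarray(gm, dtype=float)
    if not (x.shape == y.shape == gm.shape) or x.ndim != 1:
        raise ValueError("x, y, gm must be 1D vectors of equal length")
    if x.size < 10:
        raise ValueError("need at least 10 shared regions")
    rx = _residualize(x, gm)
    ry = _residualize(y, gm)
    nx = float(rx @ rx)
    ny = float(ry @ ry)
    # a vector fully explained by gm (e.g. y == gm) has a correlation of 0
    # with anything in the residual space; both degenerate is an error
    tol_x = 1e-24 * float((x - x.mean()) @ (x - x.mean()) + np.finfo(float).tiny)
    tol_y = 1e-24 * float((y - y.mean()) @ (y - y.mean()) + np.finfo(float).tiny)
    if nx <= tol_x and ny <= tol_y:
        raise ValueError("zero residual variance after gray-matter adjustment")
    if nx <= tol_x or ny <= tol_y:
        return 0.0
    return float(np.clip((rx @ ry) / np.sqrt(nx * ny), -1.0, 1.0))


def neuromap_permutation_p(
    x_tmap_regions: np.ndarray,
    y_receptor_regions: np.ndarray,
    gm: np.ndarray,
    ensemble: SurrogateEnsemble,
    map_name: str = "receptor",
    n_perm: int | None = None,
) -> NeuromapResult:
    """Two-sided permutation p for the GM-adjusted regional correlation.

    The ensemble must hold surrogate region vectors of the t-map built at the
    region-centroid geometry.  p = (1 + #{|null r| >= |observed r|}) /
    (n_perm + 1); deterministic given the ensemble's seed.
    """
    n_perm = ensemble.n_surrogate if n_perm is None else min(n_perm, ensemble.n_surrogate)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values are coarse", stacklevel=2)
    if ensemble.maps.shape[1] != len(x_tmap_regions):
        raise ValueError("ensemble geometry does not match the region vectors")
    r_obs = partial_spatial_corr(x_tmap_regions, y_receptor_regions, gm)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = partial_spatial_corr(ensemble.maps[k], y_receptor_regions, gm)
    p = float((1 + np.sum(np.abs(null) >= abs(r_obs))) / (n_perm + 1))
    return NeuromapResult(
        map_name=map_name, r_partial=r_obs, p_perm=p, n_perm=n_perm,
        n_regions=len(x_tmap_regions),
    )
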