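"""Cluster-level imaging summaries correlated with burnout subscale scores.

Associations are plain Pearson correlations with analytic two-sided p-values
from the Student-t transform t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of
freedom — no covariate partialling, no multiple-testing correction by default
(a Benjamini-Hochberg option is available).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from falffmap.io import BrainMask, StatMap, SubjectRecord

__all__ = [
    "AssociationResult",
    "cluster_mean",
    "pearson_r",
    "pearson_p",
    "associate",
]

SCORES = ("ee", "dp", "pa")


@dataclasses.dataclass
class AssociationResult:
    imaging_measure: str
    score: str
    r: float
    n: int
    p: float
    p_adjusted: float | None = None


def cluster_mean(statmap: StatMap, cluster_mask: BrainMask) -> float:
    """Unweighted mean of a map's finite values inside a cluster mask."""
    if statmap.data.shape != cluster_mask.data.shape:
        raise ValueError("cluster mask grid does not match map grid")
    vals = np.asarray(statmap.data, dtype=float)[cluster_mask.data]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("cluster mask overlaps no finite voxels")
    return float(vals.mean())


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in x or y")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson coefficient at sample size n.

    Uses t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df; |r| = 1 returns 0 as the
    limiting convention.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        return 0.0
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df))


def associate(
    measures: dict[str, Sequence[float]],
    records: Sequence[SubjectRecord],
    group: str = "burnout",
    adjust: bool = False,
) -> list[AssociationResult]:
    """Correlate each imaging measure with the EE/DP/PA subscales.

    ``measures`` maps a measure name to one value per record (same order as
    ``records``); only subjects of ``group`` enter the correlations, matching
    the within-group analysis convention.  With ``adjust=True``
    Benjamini-Hochberg adjusted p-values are filled in across all tests.
    """
    keep = [i for i, r in enumerate(records) if r.group == group]
    if len(keep) < 3:
        raise ValueError(f"fewer than 3 subjects in group {group!r}")
    out: list[AssociationResult] = []
    for name, values in measures.items():
        values = np.asarray(values, dtype=float)
        if values.shape[0] != len(records):
            raise ValueError(f"measure {name!r} length does not match records")
        v = values[keep]
        for score in SCORES:
            s = np.array([getattr(records[i], score) for i in keep])
            r = pearson_r(v, s)
            out.append(
                AssociationResult(
                    imaging_measure=name, score=score.upper(), r=r, n=len(keep),
                    p=pearson_p(r, len(keep)),
                )
            )
    if adjust and out:
        _, p_adj, _, _ = multipletests([a.p for a in out], method="fdr_bh")
        for a, q in zip(out, p_adj):
            a.p_adjusted = float(q)
    return out
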