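"""Spontaneous-activity metrics: ALFF/fALFF, Fisher z, and seed-based FC.

fALFF is the fraction of a voxel's square-root spectral power falling in the
low-frequency band (default 0.01-0.1 Hz) relative to the whole analysed range
(default 0.01-0.25 Hz).  With the band nested in the total range and a
ratio-of-sums convention the value lies in [0, 1].  Series are demeaned
before the FFT (a linear-detrend option exists); no other filtering is
applied (fALFF is itself frequency-selective).

Seed-based FC correlates each voxel's series with the unweighted mean series
of a seed region; correlation maps are Fisher z-transformed.  Correlations of
magnitude >= 1 - 1e-7 are clipped before atanh so degenerate inputs stay
finite.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from falffmap.io import BrainMask, StatMap, Volume4D

__all__ = [
    "BandSpec",
    "SeedRegion",
    "sqrt_power_spectrum",
    "compute_falff",
    "falff_map",
    "fisher_z_standardize",
    "seed_fc_map",
]

CLIP = 1.0 - 1e-7


@dataclasses.dataclass(frozen=True)
class BandSpec:
    """Low-frequency band nested inside the total analysed range (Hz)."""

    low: float = 0.01
    high: float = 0.1
    total_low: float = 0.01
    total_high: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high <= self.total_high):
            raise ValueError("need 0 < low < high <= total_high")
        if self.total_low > self.low:
            raise ValueError("total_low must not exceed low")

    def validate_for_tr(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if max(self.high, self.total_high) > nyquist + 1e-12:
            raise ValueError(
                f"band edge {max(self.high, self.total_high)} Hz exceeds "
                f"Nyquist {nyquist} Hz for tr={tr}"
            )


@dataclasses.dataclass
class SeedRegion:
    """A cluster of voxels used as FC seed."""

    mask: BrainMask
    label: str = "seed"


def sqrt_power_spectrum(ts: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided square-root power spectrum of a time series.

    Amplitudes are scaled so that the sum of their squares equals the total
    signal power sum(x^2) (Parseval).  Frequency bin k maps to k/(T*tr) Hz;
    the DC bin is reported but never falls inside an analysis band.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 1:
        raise ValueError("expected a 1D time series")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    T = ts.shape[-1]
    spec = np.fft.rfft(ts)
    freqs = np.fft.rfftfreq(T, d=tr)
    # one-sided weights: DC (and Nyquist for even T) counted once, rest twice
    w = np.full(freqs.shape, 2.0)
    w[0] = 1.0
    if T % 2 == 0:
        w[-1] = 1.0
    amps = np.abs(spec) * np.sqrt(w / T)
    return freqs, amps


def _band_mask(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    # closed interval; tiny epsilon guards float rounding of k/(T*tr)
    eps = 1e-12
    return (freqs >= low - eps) & (freqs <= high + eps)


def _detrend(x: np.ndarray, mode: str | None, axis: int = -1) -> np.ndarray:
    if mode is None:
        return np.asarray(x, dtype=float)
    if mode == "mean":
        x = np.asarray(x, dtype=float)
        return x - x.mean(axis=axis, keepdims=True)
    if mode == "linear":
        return signal.detrend(np.asarray(x, dtype=float), axis=axis, type="linear")
    raise ValueError(f"unknown detrend mode {mode!r}")


def compute_falff(
    ts: np.ndarray, tr: float, band: BandSpec = BandSpec(), detrend: str | None = "mean"
) -> float:
    """fALFF of one series: in-band sqrt-power over total-range sqrt-power.

    The series is demeaned first (``detrend='mean'``, the default — removes
    only the DC component, which never falls in a band, so a band-limited
    signal keeps fALFF = 1); ``'linear'`` additionally removes a fitted line,
    which spreads a little power across all bins.  A voxel with zero
    total-band power is degenerate and returns 0.
    """
    band.validate_for_tr(tr)
    ts = _detrend(ts, detrend)
    freqs, amps = sqrt_power_spectrum(ts, tr)
    num = amps[_band_mask(freqs, band.low, band.high)].sum()
    den = amps[_band_mask(freqs, band.total_low, band.total_high)].sum()
    if den == 0:
        return 0.0
    return float(num / den)


def falff_map(
    vol: Volume4D,
    mask: BrainMask,
    band: BandSpec = BandSpec(),
    detrend: str | None = "mean",
) -> StatMap:
    """Voxelwise fALFF inside the mask; NaN outside."""
    if vol.shape3d != mask.data.shape:
        raise ValueError(f"grid mismatch: volume {vol.shape3d} vs mask {mask.data.shape}")
    band.validate_for_tr(vol.tr)
    T = vol.n_timepoints
    series = np.asarray(vol.data, dtype=float)[mask.data]  # V x T
    series = _detrend(series, detrend, axis=1)
    spec = np.abs(np.fft.rfft(series, axis=1))
    freqs = np.fft.rfftfreq(T, d=vol.tr)
    w = np.full(freqs.shape, 2.0)
    w[0] = 1.0
    if T % 2 == 0:
        w[-1] = 1.0
    amps = spec * np.sqrt(w / T)
    num = amps[:, _band_mask(freqs, band.low, band.high)].sum(axis=1)
    den = amps[:, _band_mask(freqs, band.total_low, band.total_high)].sum(axis=1)
    vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out = np.full(mask.data.shape, np.nan)
    out[mask.data] = vals
    return StatMap(data=out, affine=vol.affine, kind="falff_z")


def fisher_z_standardize(statmap: StatMap, method: str = "fisher") -> StatMap:
    """Standardise a map for group statistics.

    ``fisher`` (default) applies z = atanh(v) voxelwise — valid for fALFF
    (in [0, 1)) and correlation maps; values with magnitude >= 1 - 1e-7 are
    clipped first.  ``zscore`` subtracts the in-map mean and divides by the
    SD over finite voxels.  NaNs are preserved either way.
    """
    data = np.asarray(statmap.data, dtype=float)
    if method == "fisher":
        out = np.arctanh(np.clip(data, -CLIP, CLIP))
    elif method == "zscore":
        finite = np.isfinite(data)
        mu = data[finite].mean()
        sd = data[finite].std()
        out = (data - mu) / (sd if sd > 0 else 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    out[~np.isfinite(data)] = np.nan
    return StatMap(data=out, affine=statmap.affine, kind=statmap.kind)


def seed_fc_map(vol: Volume4D, seed: SeedRegion, mask: BrainMask) -> StatMap:
    """Fisher z map of Pearson correlation with the seed's mean time series.

    The seed must lie inside the analysis mask.  Voxels with constant series
    get NaN; a constant seed mean series is an error.
    """
    if vol.shape3d != mask.data.shape:
        raise ValueError(f"grid mismatch: volume {vol.shape3d} vs mask {mask.data.shape}")
    if seed.mask.data.shape != mask.data.shape:
        raise ValueError("seed grid does not match analysis mask grid")
    if np.any(seed.mask.data & ~mask.data):
        raise ValueError("seed region extends outside the analysis mask")
    data = np.asarray(vol.data, dtype=float)
    seed_series = data[seed.mask.data].mean(axis=0)
    seed_c = seed_series - seed_series.mean()
    seed_ss = float(seed_c @ seed_c)
    if seed_ss <= 0:
        raise ValueError(f"seed {seed.label!r} mean series has zero variance")
    vox = data[mask.data]  # V x T
    vox_c = vox - vox.mean(axis=1, keepdims=True)
    vox_ss = np.einsum("ij,ij->i", vox_c, vox_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vox_c @ seed_c) / np.sqrt(vox_ss * seed_ss)
    r[vox_ss <= 0] = np.nan
    z = np.arctanh(np.clip(r, -CLIP, CLIP))
    z[~np.isfinite(r)] = np.nan
    out = np.full(mask.data.shape, np.nan)
    out[mask.data] = z
    return StatMap(data=out, affine=vol.affine, kind="fc_z")
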