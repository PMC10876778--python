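"""Voxel-wise local spontaneous-activity metrics.

Regional homogeneity (ReHo) is Kendall's coefficient of concordance (W)
between a voxel's time series and its 26 nearest neighbours:

    W = 12 S / (K^2 (n^3 - n)),   S = sum_i (R_i - Rbar)^2

where K is the number of series in the neighbourhood, n the number of time
points, and R_i the sum over series of the within-series rank at time i.
Ties receive average ranks; no tie-correction term is applied to the
denominator (ties have measure zero in floating-point data).  A
neighbourhood containing a constant series gets W = 0 with a logged flag.

ALFF is the mean spectral amplitude in the 0.01–0.1 Hz band; fALFF is the
ratio of the in-band amplitude sum to the amplitude sum over the whole
non-DC spectrum.  The amplitude convention used throughout (implementation
and test oracles alike) is ``a_k = 2 |X_k| / n`` for the one-sided rFFT, so
a pure tone of amplitude A at an exact bin contributes a_k = A.  The band is
inclusive at both edges, matching the bandpass filter, so a band-limited
signal has fALFF = 1.

Standardization divides each metric by its in-mask global mean (mReHo /
mALFF / mfALFF), and spatial smoothing (6 mm FWHM Gaussian) is applied last.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .images import ActivityMap, TimeSeriesVolume, voxel_sizes

logger = logging.getLogger(__name__)

__all__ = [
    "kendalls_w",
    "reho_map",
    "alff_map",
    "falff_map",
    "normalize_by_global_mean",
    "gaussian_smooth",
]

_CUBE27 = np.ones((3, 3, 3))


def kendalls_w(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K series over n time points.

    Parameters
    ----------
    series_set : ndarray, shape (K, n)
        K >= 2 series of n >= 2 observations each.

    Returns
    -------
    float in [0, 1]; 1 means identical rank orderings.  If any series is
    constant the statistic is undefined and 0 is returned with a logged
    flag.
    """
    series_set = np.asarray(series_set, float)
    if series_set.ndim != 2:
        raise ValueError("series_set must be 2D (K, n)")
    K, n = series_set.shape
    if K < 2 or n < 2:
        raise ValueError(f"need K >= 2 and n >= 2, got K={K}, n={n}")
    if np.any(series_set.std(axis=1) == 0):
        logger.debug("constant series in concordance computation; returning 0")
        return 0.0
    ranks = rankdata(series_set, axis=1)
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    return float(12.0 * S / (K**2 * (n**3 - n)))


def _neighbor_sum(field: np.ndarray) -> np.ndarray:
    """Sum over the 3x3x3 cube (self included), zero padding outside."""
    return ndimage.correlate(field, _CUBE27, mode="constant", cval=0.0)


def reho_map(vol: TimeSeriesVolume, mask: np.ndarray, neighborhood: int = 27) -> ActivityMap:
    """Voxel-wise Kendall's W over each voxel and its in-mask cube neighbours.

    Voxels whose 3x3x3 cube is clipped by the mask or volume edge use only
    the available neighbours (K < 27).  Expects band-limited, preprocessed
    input.  Voxels with K < 2 or any constant neighbourhood series are set
    to 0.
    """
    if neighborhood != 27:
        raise ValueError("only the 27-voxel (3x3x3) neighbourhood is supported")
    mask = np.asarray(mask, bool)
    if mask.shape != vol.shape3d:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("mask is empty")
    n = vol.n_volumes
    maskf = mask.astype(float)

    ranks = np.empty_like(vol.data)
    ranks[mask] = rankdata(vol.data[mask], axis=1)
    ranks[~mask] = 0.0

    K = _neighbor_sum(maskf)
    # R_i per voxel: neighbourhood sum of ranks at each time point
    S = np.zeros(vol.shape3d)
    Rbar = K * (n + 1) / 2.0
    for t in range(n):
        Ri = _neighbor_sum(ranks[..., t] * maskf)
        S += (Ri - Rbar) ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        W = 12.0 * S / (K**2 * (n**3 - n))
    W[~mask] = 0.0
    W[mask & (K < 2)] = 0.0

    # neighbourhoods containing a constant series are undefined -> 0
    const = np.zeros(vol.shape3d)
    const[mask] = (vol.data[mask].std(axis=1) == 0).astype(float)
    bad = mask & (_neighbor_sum(const * maskf) > 0)
    if bad.any():
        logger.info("ReHo: %d voxel(s) with constant series in neighbourhood set to 0", int(bad.sum()))
        W[bad] = 0.0
    return ActivityMap(np.clip(W, 0.0, 1.0), vol.affine, "reho", mask)


def _amplitude_spectrum(data: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum ``a_k = 2 |X_k| / n`` and its frequencies."""
    n = data.shape[-1]
    amps = 2.0 * np.abs(np.fft.rfft(data, axis=-1)) / n
    freqs = np.fft.rfftfreq(n, d=tr)
    return amps, freqs


def alff_map(
    vol: TimeSeriesVolume,
    mask: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> ActivityMap:
    """Mean in-band spectral amplitude per voxel (DC excluded).

    Computed on data that is nuisance-regressed and detrended but NOT
    bandpass filtered — filtering first would empty the out-of-band
    spectrum that fALFF compares against.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != vol.shape3d:
        raise ValueError("mask shape does not match volume")
    nyquist = 1.0 / (2.0 * vol.tr)
    if high_hz > nyquist:
        raise ValueError(f"band upper edge {high_hz} Hz exceeds Nyquist {nyquist:.4f} Hz")
    amps, freqs = _amplitude_spectrum(vol.data, vol.tr)
    band = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    if band.sum() < 2:
        raise ValueError(
            f"only {int(band.sum())} frequency bin(s) inside [{low_hz}, {high_hz}] Hz; "
            "a longer time series is needed"
        )
    out = amps[..., band].mean(axis=-1)
    out[vol.data.std(axis=-1) == 0] = 0.0  # constant series: no non-DC power
    out[~mask] = 0.0
    return ActivityMap(out, vol.affine, "alff", mask)


def falff_map(
    vol: TimeSeriesVolume,
    mask: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> ActivityMap:
    """Fractional ALFF: in-band amplitude sum over total non-DC amplitude sum.

    Lies in [0, 1].  Voxels with zero total amplitude (constant series) get
    0 with a logged flag.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != vol.shape3d:
        raise ValueError("mask shape does not match volume")
    nyquist = 1.0 / (2.0 * vol.tr)
    if high_hz > nyquist:
        raise ValueError(f"band upper edge {high_hz} Hz exceeds Nyquist {nyquist:.4f} Hz")
    amps, freqs = _amplitude_spectrum(vol.data, vol.tr)
    band = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    nondc = freqs > 0
    num = amps[..., band].sum(axis=-1)
    den = amps[..., nondc].sum(axis=-1)
    zero = (den == 0) | (vol.data.std(axis=-1) == 0)
    if (zero & mask).any():
        logger.info("fALFF: %d constant voxel(s) set to 0", int((zero & mask).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    out[~mask] = 0.0
    return ActivityMap(np.clip(out, 0.0, 1.0), vol.affine, "falff", mask)


def normalize_by_global_mean(amap: ActivityMap, mask: np.ndarray | None = None) -> ActivityMap:
    """Divide every in-mask voxel by the in-mask mean (m-variant maps)."""
    mask = np.asarray(mask if mask is not None else amap.mask, bool)
    if mask is None:
        raise ValueError("a mask is required")
    g = amap.data[mask].mean()
    if g <= 0:
        raise ValueError(f"in-mask global mean must be positive, got {g}")
    out = np.zeros_like(amap.data)
    out[mask] = amap.data[mask] / g
    label = amap.label if amap.label.startswith("m") else "m" + amap.label
    return ActivityMap(out, amap.affine, label, mask)


def gaussian_smooth(amap: ActivityMap, fwhm_mm: float = 6.0) -> ActivityMap:
    """Gaussian spatial smoothing with the given FWHM in mm.

    sigma per axis is fwhm / (2 sqrt(2 ln 2)) converted to voxels through
    the affine; fwhm 0 is the identity.  Zero boundary, so interior mass is
    conserved.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return amap.with_data(amap.data.copy())
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / voxel_sizes(amap.affine)
    out = ndimage.gaussian_filter(amap.data, sigma=sigma_vox, mode="constant", cval=0.0)
    return amap.with_data(out)
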