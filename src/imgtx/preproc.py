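"""BOLD preprocessing: volume removal, nuisance regression, bandpass, FD.

The steps implemented here are the ones applied between co-registered input
volumes and metric computation:

1. removal of the first volumes (default 10),
2. ordinary-least-squares regression of nuisance covariates — intercept,
   linear drift, the Friston-24 motion expansion, spike indicators for
   volumes with frame-wise displacement (FD) above 0.5 mm, and mean white
   matter / CSF signals,
3. bandpass filtering to 0.01–0.1 Hz.

Linear detrending is the drift column of the nuisance design, so regression
and detrending happen in a single pass and the bandpass cannot reintroduce
drift.  FD uses Power's definition with a 50 mm rotation radius, the
convention the 0.5 mm spike threshold presumes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .images import TimeSeriesVolume

logger = logging.getLogger(__name__)

__all__ = [
    "discard_initial_volumes",
    "compute_fd",
    "build_friston24",
    "build_spike_regressors",
    "build_nuisance_design",
    "regress_nuisance",
    "bandpass",
    "preprocess",
]

FD_ROTATION_RADIUS_MM = 50.0
FD_SPIKE_THRESHOLD_MM = 0.5


def discard_initial_volumes(vol: TimeSeriesVolume, n: int = 10) -> TimeSeriesVolume:
    """Drop the first ``n`` volumes (signal-equilibration scrub)."""
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    if n >= vol.n_volumes:
        raise ValueError(
            f"cannot discard {n} volumes from a series of {vol.n_volumes}"
        )
    return vol.with_data(vol.data[..., n:])


def compute_fd(motion: np.ndarray, rotation_radius_mm: float = FD_ROTATION_RADIUS_MM) -> np.ndarray:
    """Frame-wise displacement (Power) from a (t, 6) motion trace.

    Columns 0–2 are translations in mm, 3–5 rotations in radians; rotations
    are converted to arc length on a sphere of ``rotation_radius_mm``.
    FD of the first volume is 0 by convention.
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must have shape (t, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    delta = np.abs(np.diff(motion, axis=0))
    fd = delta[:, :3].sum(axis=1) + rotation_radius_mm * delta[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def build_friston24(motion: np.ndarray) -> pd.DataFrame:
    """Friston-24 motion expansion.

    24 columns: the 6 parameters, their one-volume-lagged copies (first row
    zero), and the squares of both sets.
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must have shape (t, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    lagged = np.vstack([np.zeros(6), motion[:-1]])
    block = np.hstack([motion, lagged, motion**2, lagged**2])
    names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    cols = (
        [f"mot_{n}" for n in names]
        + [f"mot_{n}_lag" for n in names]
        + [f"mot_{n}_sq" for n in names]
        + [f"mot_{n}_lag_sq" for n in names]
    )
    return pd.DataFrame(block, columns=cols)


def build_spike_regressors(fd: np.ndarray, threshold: float = FD_SPIKE_THRESHOLD_MM) -> pd.DataFrame:
    """One indicator column per volume with FD strictly above ``threshold``."""
    fd = np.asarray(fd, float)
    spikes = np.flatnonzero(fd > threshold)
    cols = {}
    for k in spikes:
        col = np.zeros(fd.size)
        col[k] = 1.0
        cols[f"spike_{k:04d}"] = col
    return pd.DataFrame(cols, index=range(fd.size))


def _mask_mean_series(vol: TimeSeriesVolume, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("tissue mask is empty")
    return vol.data[mask].mean(axis=0)


def build_nuisance_design(
    vol: TimeSeriesVolume,
    motion: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    spike_threshold: float = FD_SPIKE_THRESHOLD_MM,
) -> pd.DataFrame:
    """Assemble the full nuisance design for one subject.

    Columns: intercept, linear drift, Friston-24 block, spike indicators,
    mean white-matter and CSF series (those present among the inputs).
    """
    t = vol.n_volumes
    design = {"intercept": np.ones(t), "linear_drift": np.linspace(-0.5, 0.5, t)}
    frame = pd.DataFrame(design)
    if motion is not None:
        motion = np.asarray(motion, float)
        if motion.shape[0] != t:
            raise ValueError(
                f"motion trace has {motion.shape[0]} rows for {t} volumes"
            )
        frame = pd.concat([frame, build_friston24(motion)], axis=1)
        spikes = build_spike_regressors(compute_fd(motion), spike_threshold)
        if spikes.shape[1]:
            frame = pd.concat([frame, spikes], axis=1)
    if wm_mask is not None:
        frame["wm_mean"] = _mask_mean_series(vol, wm_mask)
    if csf_mask is not None:
        frame["csf_mean"] = _mask_mean_series(vol, csf_mask)
    return frame


def _drop_dependent_columns(design: pd.DataFrame) -> pd.DataFrame:
    """Keep a maximal linearly independent column subset (QR with pivoting)."""
    X = design.to_numpy(float)
    if X.shape[1] == 0:
        return design
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        dropped = [design.columns[i] for i in sorted(set(range(X.shape[1])) - set(keep))]
        logger.warning("dropping %d linearly dependent design column(s): %s", len(dropped), dropped)
    return design.iloc[:, keep]


def regress_nuisance(vol: TimeSeriesVolume, design: pd.DataFrame) -> TimeSeriesVolume:
    """Voxel-wise OLS residuals after projecting out the nuisance design.

    The design must include an intercept (so residuals are demeaned).
    Linearly dependent columns are dropped with a warning.
    """
    if design.shape[0] != vol.n_volumes:
        raise ValueError(
            f"design has {design.shape[0]} rows for {vol.n_volumes} volumes"
        )
    design = _drop_dependent_columns(design)
    X = design.to_numpy(float)
    Y = vol.data.reshape(-1, vol.n_volumes).T  # (t, n_voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return vol.with_data(resid.T.reshape(vol.data.shape))


def bandpass(vol: TimeSeriesVolume, low_hz: float = 0.01, high_hz: float = 0.1) -> TimeSeriesVolume:
    """Hard Fourier-domain bandpass: keep bins with ``low_hz <= f <= high_hz``.

    DC is always removed.  Raises if the band does not fit below Nyquist.
    """
    nyquist = 1.0 / (2.0 * vol.tr)
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"invalid band [{low_hz}, {high_hz}]")
    if high_hz > nyquist:
        raise ValueError(
            f"band upper edge {high_hz} Hz exceeds Nyquist {nyquist:.4f} Hz"
        )
    n = vol.n_volumes
    freqs = np.fft.rfftfreq(n, d=vol.tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    spectrum = np.fft.rfft(vol.data, axis=-1)
    spectrum[..., ~keep] = 0.0
    return vol.with_data(np.fft.irfft(spectrum, n=n, axis=-1))


def preprocess(
    vol: TimeSeriesVolume,
    motion: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    n_discard: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    apply_bandpass: bool = True,
) -> TimeSeriesVolume:
    """Full preprocessing chain: discard -> nuisance regression -> bandpass.

    ``apply_bandpass=False`` stops after regression; the residual (still
    detrended through the drift column) is the input the spectral metrics
    expect, since bandpassing first would fix fALFF at 1.
    """
    vol = discard_initial_volumes(vol, n_discard)
    if motion is not None:
        motion = np.asarray(motion, float)[n_discard:]
    design = build_nuisance_design(vol, motion, wm_mask, csf_mask)
    vol = regress_nuisance(vol, design)
    if apply_bandpass:
        vol = bandpass(vol, low_hz, high_hz)
    return vol
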