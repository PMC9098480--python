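"""BOLD denoising: motion QC, confound regression, filtering, smoothing.

The pipeline mirrors a standard resting-state denoising strategy: framewise
displacement (FD) quality control, regression of a 36-parameter nuisance
model (CSF, WM, global signal, six motion parameters, their temporal
derivatives, and the squares of all of those) plus one spike regressor per
high-motion frame, zero-phase band-pass filtering (0.01-0.1 Hz), and
mask-normalized Gaussian spatial smoothing.  Stage order is regression ->
band-pass -> smoothing; each stage stamps the session's history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter

from .datatypes import BoldSession

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class FDSeries:
    """Per-frame framewise displacement (mm) and its scan-level mean."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values[0] != 0.0:
            raise ValueError("FD of the first frame is 0 by convention")
        if (self.values < 0).any():
            raise ValueError("FD values must be non-negative")

    @property
    def mfd(self) -> float:
        return float(self.values.mean())


def framewise_displacement(motion: pd.DataFrame, head_radius_mm: float = 50.0) -> FDSeries:
    """Power-style L1 framewise displacement.

    FD(t) = sum |d translations| + head_radius_mm * sum |d rotations|, with
    backward differences and FD(0) = 0.  Rotations (radians) are converted
    to arc length on a sphere of ``head_radius_mm``.
    """
    arr = np.asarray(motion, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    bad = np.nonzero(~np.isfinite(arr).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite motion values at frame(s) {bad.tolist()}")
    diff = np.abs(np.diff(arr, axis=0))
    fd = diff[:, :3].sum(axis=1) + head_radius_mm * diff[:, 3:].sum(axis=1)
    return FDSeries(np.concatenate([[0.0], fd]))


def qc_exclude(fd: FDSeries, mfd_threshold_mm: float = 0.3) -> bool:
    """Exclude a scan iff its mean FD strictly exceeds the threshold."""
    return fd.mfd > mfd_threshold_mm


@dataclass
class DesignMatrix:
    """Confound design: t x p matrix with named columns and spike count."""

    matrix: np.ndarray
    column_names: list
    n_spikes: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("one name per column required")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("duplicate column names")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def _backward_diff(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    out[1:] = np.diff(x, axis=0)
    return out


def build_confound_design(
    confounds: pd.DataFrame,
    motion: pd.DataFrame,
    fd: FDSeries,
    spike_threshold_mm: float = 0.5,
) -> DesignMatrix:
    """Assemble the 36-parameter nuisance model plus spike regressors.

    Columns, in order: 9 base signals (csf, white_matter, global_signal,
    six motion parameters), their 9 backward-difference derivatives, and
    the squares of those 18 — 36 in total — followed by one indicator
    column per frame whose FD exceeds ``spike_threshold_mm``.
    """
    t = len(confounds)
    if len(motion) != t or len(fd.values) != t:
        raise ValueError(
            f"row counts differ: confounds {t}, motion {len(motion)}, fd {len(fd.values)}"
        )
    base = np.column_stack([np.asarray(confounds, dtype=float), np.asarray(motion, dtype=float)])
    base_names = list(confounds.columns) + list(motion.columns)
    deriv = _backward_diff(base)
    block = np.column_stack([base, deriv, base**2, deriv**2])
    names = (
        base_names
        + [f"{n}_derivative1" for n in base_names]
        + [f"{n}_power2" for n in base_names]
        + [f"{n}_derivative1_power2" for n in base_names]
    )
    spike_frames = np.nonzero(fd.values > spike_threshold_mm)[0]
    spikes = np.zeros((t, spike_frames.size))
    spikes[spike_frames, np.arange(spike_frames.size)] = 1.0
    matrix = np.column_stack([block, spikes]) if spike_frames.size else block
    names += [f"spike_frame_{f:04d}" for f in spike_frames]
    return DesignMatrix(matrix=matrix, column_names=names, n_spikes=spike_frames.size)


def regress_confounds(session: BoldSession, design: DesignMatrix) -> BoldSession:
    """Project nuisance columns (plus an intercept) out of every voxel.

    Exactly collinear columns are dropped with a warning; residual time
    series are mean-zero and orthogonal to every retained column.
    """
    t = session.n_frames
    if design.matrix.shape[0] != t:
        raise ValueError(f"design has {design.matrix.shape[0]} rows, session has {t} frames")
    if not session.mask.any():
        raise ValueError("empty brain mask")
    X = np.column_stack([np.ones(t), design.matrix])
    # Rank-revealing pass: drop columns whose residual after the previous
    # columns is numerically zero (exact collinearity).
    keep = []
    basis = np.empty((t, 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        if norm > 1e-10 * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.column_stack([basis, resid / norm])
        elif j > 0:
            logger.warning("dropping collinear design column %r", design.column_names[j - 1])
    data = session.data
    flat = data[session.mask]  # voxels x t
    coef = basis.T @ flat.T  # basis is orthonormal
    resid = flat - (basis @ coef).T
    out = np.zeros_like(data)
    out[session.mask] = resid
    return session.with_data(out, "confound_regression")


def bandpass_filter(session: BoldSession, low_hz: float = 0.01, high_hz: float = 0.1,
                    order: int = 4) -> BoldSession:
    """Zero-phase Butterworth band-pass applied per voxel.

    Forward-backward filtering doubles the effective order and cancels
    phase shifts that would otherwise bias inter-voxel correlations.
    """
    nyq = 1.0 / (2.0 * session.tr_s)
    if not 0.0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz {high_hz} Hz is at or above the Nyquist frequency {nyq} Hz for TR {session.tr_s} s"
        )
    sos = signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    flat = session.data[session.mask]
    filtered = signal.sosfiltfilt(sos, flat, axis=1)
    out = np.zeros_like(session.data)
    out[session.mask] = filtered
    return session.with_data(out, f"bandpass_{low_hz}_{high_hz}")


def gaussian_smooth(session: BoldSession, fwhm_mm: float = 6.0) -> BoldSession:
    """Mask-normalized 3-D Gaussian smoothing of every frame.

    sigma per axis is fwhm / (2 sqrt(2 ln 2)) in voxel units.  Values
    outside the mask are excluded from the kernel average (the smoothed
    volume is divided by the smoothed mask), which avoids the edge
    attenuation plain convolution would cause on small grids.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return session.with_data(session.data.copy(), "smooth_0mm")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / session.voxel_size_mm
    mask = session.mask.astype(float)
    sm_mask = gaussian_filter(mask, sigma=sigma_vox, mode="constant")
    data = session.data * session.mask[..., None]
    out = np.zeros_like(session.data)
    for t in range(session.n_frames):
        num = gaussian_filter(data[..., t], sigma=sigma_vox, mode="constant")
        frame = np.zeros(mask.shape)
        frame[session.mask] = num[session.mask] / sm_mask[session.mask]
        out[..., t] = frame
    return session.with_data(out, f"smooth_{fwhm_mm}mm")


def denoise(
    session: BoldSession,
    spike_threshold_mm: float = 0.5,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    fwhm_mm: float = 6.0,
    head_radius_mm: float = 50.0,
) -> tuple:
    """Full denoising chain: confound regression -> band-pass -> smoothing.

    Returns (denoised session, QC dict with mFD, spike count, exclusion
    flag).
    """
    fd = framewise_displacement(session.motion, head_radius_mm=head_radius_mm)
    design = build_confound_design(
        session.confounds, session.motion, fd, spike_threshold_mm=spike_threshold_mm
    )
    out = regress_confounds(session, design)
    out = bandpass_filter(out, low_hz=low_hz, high_hz=high_hz)
    out = gaussian_smooth(out, fwhm_mm=fwhm_mm)
    qc = {
        "subject_id": session.subject_id,
        "condition_id": session.condition_id,
        "mfd_mm": fd.mfd,
        "n_spike_frames": design.n_spikes,
        "excluded": qc_exclude(fd),
    }
    return out, qc
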