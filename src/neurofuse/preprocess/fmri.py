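"""Functional-MRI preprocessing.

Motion estimation against a reference frame, framewise displacement (FD),
frame censoring ("scrubbing"), ideal band-pass filtering of the BOLD series,
per-frame plane projections, ROI time-series extraction and functional
connectivity (Pearson r with Fisher z variance stabilisation).

Processing order: the full series is band-pass filtered first and censored
frames are dropped afterwards — Fourier filtering of a gapped series is
ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..volumes import PLANE_AXES, RoiAtlas, VolumeImage
from .smri import RegistrationOptions, register_rigid

__all__ = [
    "MotionTrace",
    "FDSeries",
    "RoiTimeSeriesMatrix",
    "ConnectivityMatrix",
    "estimate_motion",
    "framewise_displacement",
    "censor_frames",
    "bandpass",
    "frame_mean_images",
    "roi_timeseries",
    "connectivity",
    "fisher_z",
]

DEFAULT_BRAIN_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5


@dataclass
class MotionTrace:
    """Per-frame rigid parameters relative to a reference frame.

    ``translations`` is (T, 3) in mm, ``rotations`` (T, 3) in rad; the
    reference frame's row is all zero.
    """

    translations: np.ndarray
    rotations: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, float)
        self.rotations = np.asarray(self.rotations, float)
        if self.translations.shape != self.rotations.shape or self.translations.ndim != 2:
            raise ValueError("translations and rotations must both be (T, 3)")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


@dataclass
class FDSeries:
    """Framewise displacement per frame (mm) and the brain radius used."""

    fd: np.ndarray
    radius_mm: float = DEFAULT_BRAIN_RADIUS_MM

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, float)
        if (self.fd < 0).any():
            raise ValueError("FD must be non-negative")


@dataclass
class RoiTimeSeriesMatrix:
    """T x R matrix of mean BOLD per ROI over the retained frames."""

    S: np.ndarray
    tr: float
    retained_frames: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, float)
        self.retained_frames = np.asarray(self.retained_frames, int)
        if np.isnan(self.S).any():
            raise ValueError("ROI time series contains NaN")

    @property
    def n_rois(self) -> int:
        return self.S.shape[1]


@dataclass
class ConnectivityMatrix:
    """Pearson r and Fisher z functional-connectivity matrices (R x R)."""

    r_mat: np.ndarray
    z_mat: np.ndarray


def estimate_motion(
    vol4d: VolumeImage,
    reference_frame: int = 0,
    opts: RegistrationOptions | None = None,
    smooth_vox: float = 1.0,
) -> MotionTrace:
    """Register every frame of a 4D series to the reference frame.

    Frames are Gaussian-smoothed by ``smooth_vox`` voxels before the MI
    registration — this evens out the interpolation blur between moved and
    unmoved frames and removes a sub-voxel bias in the recovered shift.
    Returns the six rigid parameters per frame; the reference row is zero.
    """
    if vol4d.data.ndim != 4 or vol4d.n_frames < 2:
        raise ValueError("estimate_motion requires a 4D volume with T >= 2")
    opts = opts or RegistrationOptions(pyramid=(2, 1), step_mm=2.0, step_rad=0.05)

    def prep(frame: VolumeImage) -> VolumeImage:
        if smooth_vox <= 0:
            return frame
        sm = ndimage.gaussian_filter(np.asarray(frame.data, float), smooth_vox)
        return VolumeImage(sm, frame.affine)

    ref = prep(vol4d.frame(reference_frame))
    T = vol4d.n_frames
    trans = np.zeros((T, 3))
    rots = np.zeros((T, 3))
    for t in range(T):
        if t == reference_frame:
            continue
        res = register_rigid(prep(vol4d.frame(t)), ref, opts)
        # the realigning transform maps frame -> reference; head motion is
        # its inverse (reference -> frame)
        motion = res.transform.inverse()
        trans[t] = motion.translation
        rots[t] = motion.rotation
    return MotionTrace(trans, rots, reference_frame=reference_frame)


def framewise_displacement(
    trace: MotionTrace, radius_mm: float = DEFAULT_BRAIN_RADIUS_MM
) -> FDSeries:
    """FD_t = |dx| + |dy| + |dz| + r (|da| + |db| + |dg|) on backward
    first differences of the motion trace; FD at the first frame is 0."""
    dt = np.diff(trace.translations, axis=0, prepend=trace.translations[:1])
    dr = np.diff(trace.rotations, axis=0, prepend=trace.rotations[:1])
    fd = np.abs(dt).sum(axis=1) + radius_mm * np.abs(dr).sum(axis=1)
    return FDSeries(fd=fd, radius_mm=radius_mm)


def censor_frames(fd: FDSeries, threshold_mm: float = DEFAULT_FD_THRESHOLD_MM) -> np.ndarray:
    """Indices of frames whose FD does not exceed the threshold."""
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    retained = np.flatnonzero(fd.fd <= threshold_mm)
    if retained.size == 0:
        raise ValueError("all frames censored; series is empty")
    return retained


def bandpass(
    series: np.ndarray, tr: float, f_low: float = 0.01, f_high: float = 0.1
) -> np.ndarray:
    """Ideal band-pass: mask the DFT spectrum to [f_low, f_high] and invert.

    Operates along the first axis of ``series`` (time).  The DC component is
    always removed.  Idempotent, and exactly energy-preserving in band.
    """
    x = np.asarray(series, float)
    T = x.shape[0]
    if T < 8:
        raise ValueError("need at least 8 time points")
    nyquist = 0.5 / tr
    if not (0 < f_low < f_high <= nyquist):
        raise ValueError(f"band ({f_low}, {f_high}) outside (0, Nyquist={nyquist}]")
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= f_low - 1e-12) & (freqs <= f_high + 1e-12)
    keep[0] = False  # DC removal
    spec = np.fft.rfft(x, axis=0)
    shape = [1] * x.ndim
    shape[0] = keep.size
    spec = spec * keep.reshape(shape)
    return np.fft.irfft(spec, n=T, axis=0)


def frame_mean_images(vol4d: VolumeImage) -> dict[str, np.ndarray]:
    """Mean projection of each frame along each anatomical axis.

    Returns a dict plane -> (T, H, W) array; the temporal dimension is kept.
    A 3D volume is treated as a single frame.
    """
    data = np.asarray(vol4d.data, float)
    if data.ndim == 3:
        data = data[..., None]
    out = {}
    for plane, axis in PLANE_AXES.items():
        # move time first, collapse the plane axis by its mean
        proj = data.mean(axis=axis)  # remaining two spatial axes + time
        out[plane] = np.moveaxis(proj, -1, 0)
    return out


def roi_timeseries(
    vol4d: VolumeImage, atlas: RoiAtlas, retained: np.ndarray | None = None
) -> RoiTimeSeriesMatrix:
    """S[t, r] = mean BOLD over the voxels of ROI r at retained frame t."""
    data = np.asarray(vol4d.data, float)
    if data.ndim != 4:
        raise ValueError("roi_timeseries requires a 4D volume")
    if atlas.labels.shape != data.shape[:3]:
        raise ValueError("atlas grid does not match volume grid")
    if retained is None:
        retained = np.arange(data.shape[3])
    retained = np.asarray(retained, int)
    idx = np.arange(1, atlas.n_rois + 1)
    rows = []
    for t in retained:
        rows.append(ndimage.mean(data[..., t], labels=atlas.labels, index=idx))
    return RoiTimeSeriesMatrix(
        S=np.asarray(rows), tr=vol4d.tr or 1.0, retained_frames=retained
    )


def connectivity(S: np.ndarray, clip: float = 1.0 - 1e-7) -> ConnectivityMatrix:
    """Pearson correlation between ROI columns plus Fisher z transform.

    The z matrix is atanh of r clipped to +-(1 - 1e-7), with a zero diagonal
    by convention.
    """
    S = np.asarray(S, float)
    if S.ndim != 2 or S.shape[0] < 3:
        raise ValueError("S must be T x R with T >= 3")
    sd = S.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant ROI column(s): {bad.tolist()}")
    r = np.corrcoef(S, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -clip, clip))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(r_mat=r, z_mat=z)


def fisher_z(r: float | np.ndarray, clip: float = 1.0 - 1e-7) -> float | np.ndarray:
    """Variance-stabilising Fisher transform z = atanh(r)."""
    return np.arctanh(np.clip(r, -clip, clip))
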