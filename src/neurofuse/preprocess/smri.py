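"""Structural-MRI preprocessing: brain masking, intensity standardisation and
mutual-information rigid registration onto a template grid.

Registration maximises the mutual information of the joint intensity
histogram over the six rigid parameters with a multi-resolution,
multi-start coordinate search; the returned transform is never worse
(in MI) than the identity initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ..volumes import RigidTransform, VolumeImage, resample_rigid

__all__ = [
    "MaskedVolume",
    "RegistrationResult",
    "RegistrationOptions",
    "compute_brain_mask",
    "apply_brain_mask",
    "zscore_normalize",
    "mutual_information",
    "register_rigid",
]


@dataclass
class MaskedVolume:
    """A volume together with a binary brain mask of the same shape."""

    volume: VolumeImage
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.shape != self.volume.data.shape:
            raise ValueError("mask shape must match volume shape")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask must be binary")
        if self.mask.sum() < 1:
            raise ValueError("mask is empty")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    mi_final: float
    mi_identity: float
    n_iterations: int
    converged: bool = True


@dataclass
class RegistrationOptions:
    n_bins: int = 32
    max_iter: int = 500
    tol: float = 1e-5
    # coarse-to-fine downsampling factors applied to both volumes
    pyramid: tuple[int, ...] = (4, 2, 1)
    # initial coordinate-search steps: mm for translations, rad for rotations
    step_mm: float = 4.0
    step_rad: float = 0.1
    # extra starting points (translation offsets in mm) beside identity
    extra_starts: tuple[tuple[float, float, float], ...] = ()


def compute_brain_mask(vol: VolumeImage, smooth_mm: float = 2.0) -> np.ndarray:
    """Binary brain mask: Otsu threshold on a smoothed volume, then the
    largest connected component."""
    sigma_vox = smooth_mm / vol.voxel_size
    sm = ndimage.gaussian_filter(np.asarray(vol.data, float), sigma=sigma_vox)
    thr = threshold_otsu(sm)
    fg = sm > thr
    if not fg.any():
        raise ValueError("Otsu threshold removed every voxel")
    lab, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return (lab == keep).astype(np.uint8)


def apply_brain_mask(vol: VolumeImage, mask: np.ndarray) -> MaskedVolume:
    """Elementwise product of intensities with a binary mask."""
    mask = np.asarray(mask)
    if mask.shape != vol.data.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {vol.data.shape}"
        )
    mv = MaskedVolume(
        volume=VolumeImage(vol.data * mask, vol.affine, tr=vol.tr), mask=mask
    )
    return mv


def zscore_normalize(mv: MaskedVolume) -> VolumeImage:
    """Standardise within-mask intensities to mean 0 and population SD 1.

    Outside-mask voxels are set to zero.  Raises on a constant within-mask
    volume (degenerate scan).
    """
    data = np.asarray(mv.volume.data, float)
    inside = mv.mask.astype(bool)
    vals = data[inside]
    mu = vals.mean()
    sd = vals.std()  # population SD: per-scan statistics
    if sd <= 0:
        raise ValueError("volume is constant within the mask; cannot standardise")
    out = np.zeros_like(data)
    out[inside] = (vals - mu) / sd
    return VolumeImage(out, mv.volume.affine, tr=mv.volume.tr)


def _joint_histogram(a: np.ndarray, b: np.ndarray, n_bins: int) -> np.ndarray:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=n_bins)
    return hist


def mutual_information(
    a: np.ndarray,
    b: np.ndarray,
    n_bins: int = 32,
    mask: np.ndarray | None = None,
) -> float:
    """Mutual information (nats) of the joint intensity histogram.

    ``mask`` restricts the estimate to an overlap region (e.g. where both
    volumes have support).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("shapes must match")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if mask is not None:
        sel = np.asarray(mask, bool)
        if not sel.any():
            raise ValueError("empty overlap between masks")
        a, b = a[sel], b[sel]
    p = _joint_histogram(a, b, n_bins)
    p = p / p.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    outer = (px @ py)[nz]
    mi = float(np.sum(p[nz] * (np.log(p[nz]) - np.log(outer))))
    return max(mi, 0.0)


def _downsample(vol: VolumeImage, factor: int) -> VolumeImage:
    if factor == 1:
        return vol
    data = ndimage.zoom(np.asarray(vol.data, float), 1.0 / factor, order=1)
    aff = vol.affine.copy()
    aff[:3, :3] *= factor
    return VolumeImage(data, aff)


def _mi_objective(
    moving: VolumeImage, fixed: VolumeImage, params: np.ndarray, n_bins: int
) -> float:
    t = RigidTransform.from_params(params)
    res = resample_rigid(moving, t, fixed.data.shape[:3], fixed.affine)
    return mutual_information(res.data, np.asarray(fixed.data, float), n_bins=n_bins)


def register_rigid(
    moving: VolumeImage,
    fixed: VolumeImage,
    opts: RegistrationOptions | None = None,
) -> RegistrationResult:
    """Estimate the rigid transform mapping ``moving`` onto ``fixed`` by
    maximising mutual information.

    Derivative-free coordinate search with step shrinking, run coarse-to-fine
    over a resolution pyramid; the identity transform is always a candidate,
    so the result's MI is never below the identity MI.
    """
    opts = opts or RegistrationOptions()
    n_evals = 0

    def search(params0, moving_r, fixed_r, step_mm, step_rad):
        nonlocal n_evals
        params = params0.copy()
        f = _mi_objective(moving_r, fixed_r, params, opts.n_bins)
        n_evals += 1
        steps = np.array([step_mm] * 3 + [step_rad] * 3)
        min_steps = steps / 64.0
        while n_evals < opts.max_iter * 7:
            improved = False
            for i in range(6):
                for sgn in (+1.0, -1.0):
                    cand = params.copy()
                    cand[i] += sgn * steps[i]
                    fc = _mi_objective(moving_r, fixed_r, cand, opts.n_bins)
                    n_evals += 1
                    if fc > f + opts.tol:
                        params, f = cand, fc
                        improved = True
                        break
            if not improved:
                steps /= 2.0
                if np.all(steps < min_steps):
                    break
        return params, f

    starts = [np.zeros(6)] + [
        np.array(list(t) + [0.0, 0.0, 0.0]) for t in opts.extra_starts
    ]
    best_params, best_f = None, -np.inf
    pyramids = [(_downsample(moving, fa), _downsample(fixed, fa), fa)
                for fa in opts.pyramid]
    # coarse translation grid search seeds the basin for every start
    mv_c, fx_c, fa_c = pyramids[0]
    grid_step = opts.step_mm * fa_c
    for p0 in starts:
        f0 = _mi_objective(mv_c, fx_c, p0, opts.n_bins)
        n_evals += 1
        for dx in (-2, -1, 0, 1, 2):
            for dy in (-2, -1, 0, 1, 2):
                for dz in (-2, -1, 0, 1, 2):
                    if dx == dy == dz == 0:
                        continue
                    cand = p0.copy()
                    cand[:3] += grid_step * np.array([dx, dy, dz])
                    fc = _mi_objective(mv_c, fx_c, cand, opts.n_bins)
                    n_evals += 1
                    if fc > f0:
                        p0, f0 = cand, fc
        params = p0.copy()
        for mv_r, fx_r, factor in pyramids:
            for _round in range(2):  # one step-shrink pass + one restart
                params, f = search(
                    params, mv_r, fx_r,
                    opts.step_mm * factor / (1 + _round),
                    opts.step_rad * factor / (1 + _round),
                )
        if f > best_f:
            best_params, best_f = params, f

    mi_id = _mi_objective(moving, fixed, np.zeros(6), opts.n_bins)
    mi_best = _mi_objective(moving, fixed, best_params, opts.n_bins)
    if mi_best < mi_id:
        best_params, mi_best = np.zeros(6), mi_id
    converged = n_evals < opts.max_iter * 7
    return RegistrationResult(
        transform=RigidTransform.from_params(best_params),
        mi_final=mi_best,
        mi_identity=mi_id,
        n_iterations=n_evals,
        converged=converged,
    )
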