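"""Synthetic dual-modal brain phantoms with known ground truth.

The generator emulates the structure of a single-site case/control resting
state study (default roster: 79 cases / 105 controls).  Structural phantoms
are ellipsoidal "brains" with a cortical shell whose thickness carries the
class effect; functional phantoms are ROI-structured band-limited BOLD
signals in which a designated ROI pair carries a class-dependent planted
correlation, with optional injected rigid motion, slow drift and noise.

Randomness is counter-based (Philox) and keyed by (seed, subject_id, stream),
so adding subjects never perturbs existing ones and every output is
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess.fmri import MotionTrace
from .volumes import RigidTransform, RoiAtlas, VolumeImage, resample_rigid, save_nifti

__all__ = [
    "PhantomSpec",
    "SmriPhantom",
    "FmriPhantom",
    "make_smri_phantom",
    "make_fmri_phantom",
    "make_atlas",
    "make_roster",
    "write_dataset",
]

ASD, CONTROL = "ASD", "NC"
DRIFT_FREQ_HZ = 0.002
BASE_SHELL_VOX = 2.0


@dataclass
class PhantomSpec:
    """Study conditions for the synthetic cohort.

    ``effect_size`` sets the between-class cortical-shell thickness
    difference in voxels for sMRI, and (capped at 0.9) the planted
    correlation of the designated ROI pair for fMRI.
    """

    n_asd: int = 79
    n_control: int = 105
    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 3.0  # mm
    effect_size: float = 2.0
    tr: float = 2.0  # s
    n_frames: int = 176
    n_rois: int = 8
    motion_spikes: tuple[tuple[int, float], ...] = ()  # (frame, translation mm)
    noise_sd: float = 0.1
    morph_jitter: float = 0.02  # per-subject relative ellipsoid-axis jitter
    band: tuple[float, float] = (0.01, 0.1)  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asd < 1 or self.n_control < 1:
            raise ValueError("subject counts must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi < 0.5 / self.tr):
            raise ValueError("band must satisfy 0 < f_low < f_high < Nyquist")

    @property
    def planted_rho(self) -> float:
        return min(0.9, self.effect_size)

    def affine(self) -> np.ndarray:
        """World-centred scaling affine for the phantom grid."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * self.voxel_size
        return aff


@dataclass
class SmriPhantom:
    volume: VolumeImage
    mask: np.ndarray
    shell_mask: np.ndarray
    axes_vox: np.ndarray  # outer ellipsoid semi-axes, voxels
    shell_thickness_vox: float


@dataclass
class FmriPhantom:
    volume: VolumeImage
    motion: MotionTrace
    atlas: RoiAtlas
    true_fc: np.ndarray
    mask: np.ndarray
    roi_signals: np.ndarray  # (T, R) noiseless ROI signals
    designated_pair: tuple[int, int] = (1, 2)


def _rng(seed: int, subject_id: str, stream: str) -> np.random.Generator:
    """Counter-based generator keyed by (seed, subject, stream)."""
    digest = hashlib.sha256(f"{seed}|{subject_id}|{stream}".encode()).digest()
    key = int.from_bytes(digest[:16], "little")
    return np.random.Generator(np.random.Philox(key=key))


def _ellipsoid_sq_radius(shape, axes_vox) -> np.ndarray:
    center = (np.asarray(shape, float) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    f = np.zeros(shape, float)
    for g, c, a in zip(grids, center, axes_vox):
        f += ((g - c) / a) ** 2
    return f


def shell_thickness_for(label: str, spec: PhantomSpec) -> float:
    """Cortical shell thickness (voxels) for a class label."""
    return BASE_SHELL_VOX + (spec.effect_size if label == ASD else 0.0)


def analytic_shell_masks(
    spec: PhantomSpec, axes_vox: np.ndarray, thickness_vox: float
) -> tuple[np.ndarray, np.ndarray]:
    """Outer-ellipsoid brain mask and shell membership for given axes."""
    outer = _ellipsoid_sq_radius(spec.shape, axes_vox) <= 1.0
    inner_axes = np.maximum(np.asarray(axes_vox) - thickness_vox, 1.0)
    inner = _ellipsoid_sq_radius(spec.shape, inner_axes) <= 1.0
    return outer, outer & ~inner


def make_smri_phantom(spec: PhantomSpec, subject_id: str, label: str) -> SmriPhantom:
    """Class-labelled structural phantom: ellipsoid brain + cortical shell.

    Shell thickness is ``BASE_SHELL_VOX`` voxels for controls and
    ``BASE_SHELL_VOX + effect_size`` for cases; per-subject ellipsoid axes are
    jittered by ``morph_jitter`` and Gaussian noise of SD ``noise_sd`` is
    added everywhere.  Deterministic per (seed, subject_id).
    """
    if min(spec.shape) < 16:
        raise ValueError("shape must be >= 16 per axis to contain the shell")
    rng = _rng(spec.seed, subject_id, "smri")
    base_axes = 0.40 * np.asarray(spec.shape, float)
    axes = base_axes * (1.0 + spec.morph_jitter * rng.standard_normal(3))
    thickness = shell_thickness_for(label, spec)
    if np.any(axes - thickness < 2.0):
        raise ValueError("shape too small to contain the cortical shell")
    mask, shell = analytic_shell_masks(spec, axes, thickness)
    data = np.zeros(spec.shape, float)
    data[mask] = 0.6  # interior "white matter"
    data[shell] = 1.0  # cortical shell
    data += spec.noise_sd * rng.standard_normal(spec.shape)
    vol = VolumeImage(data, spec.affine())
    return SmriPhantom(
        volume=vol,
        mask=mask.astype(np.uint8),
        shell_mask=shell.astype(np.uint8),
        axes_vox=axes,
        shell_thickness_vox=thickness,
    )


def make_atlas(
    shape: tuple[int, int, int], n_rois: int, mask: np.ndarray | None = None
) -> RoiAtlas:
    """Contiguous block parcellation of a brain mask into n_rois regions.

    Brain voxels are ordered lexicographically and split into n_rois
    near-equal contiguous slabs.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if mask is None:
        mask = np.ones(shape, bool)
    mask = np.asarray(mask, bool)
    vox = np.argwhere(mask)  # lexicographic order
    if n_rois > len(vox):
        raise ValueError("more ROIs than brain voxels")
    labels = np.zeros(shape, dtype=np.int32)
    for r, chunk in enumerate(np.array_split(vox, n_rois), start=1):
        labels[tuple(chunk.T)] = r
    return RoiAtlas(labels=labels, n_rois=n_rois)


def _unit_bandlimited(rng: np.random.Generator, T: int, tr: float, band) -> np.ndarray:
    """Unit-variance signal with spectral support inside the pass band."""
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    keep[0] = False
    spec = np.zeros(freqs.size, complex)
    n_in = int(keep.sum())
    if n_in == 0:
        raise ValueError("band contains no DFT bin at this T and tr")
    spec[keep] = rng.standard_normal(n_in) + 1j * rng.standard_normal(n_in)
    x = np.fft.irfft(spec, n=T)
    sd = x.std()
    return x / sd if sd > 0 else x


def make_fmri_phantom(spec: PhantomSpec, subject_id: str, label: str) -> FmriPhantom:
    """Class-labelled 4D functional phantom with ground truth.

    Each ROI carries a band-limited unit-variance signal plus a slow drift
    (0.002 Hz, out of band) and white noise.  ROIs 1 and 2 (the designated
    pair) share a latent component giving correlation ``planted_rho`` in ASD
    phantoms and 0 in controls.  Rigid motion is injected at the spec's
    ``motion_spikes`` frames by resampling those frames; the returned
    MotionTrace is the ground truth.
    """
    if spec.n_frames < 32:
        raise ValueError("need n_frames >= 32")
    for frame, _ in spec.motion_spikes:
        if not (0 <= frame < spec.n_frames):
            raise ValueError(f"spike frame {frame} out of range")
    rng = _rng(spec.seed, subject_id, "fmri")
    T, R = spec.n_frames, spec.n_rois

    mask = _ellipsoid_sq_radius(spec.shape, 0.40 * np.asarray(spec.shape)) <= 1.0
    atlas = make_atlas(spec.shape, R, mask)

    f_sq = _ellipsoid_sq_radius(spec.shape, 0.40 * np.asarray(spec.shape))

    rho = spec.planted_rho if label == ASD else 0.0
    shared = _unit_bandlimited(rng, T, spec.tr, spec.band)
    signals = np.empty((T, R))
    for r in range(R):
        own = _unit_bandlimited(rng, T, spec.tr, spec.band)
        if r in (0, 1) and rho > 0:
            signals[:, r] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        else:
            signals[:, r] = own

    true_fc = np.eye(R)
    true_fc[0, 1] = true_fc[1, 0] = rho

    t_sec = np.arange(T) * spec.tr
    drift = 0.5 * np.sin(2 * np.pi * DRIFT_FREQ_HZ * t_sec + rng.uniform(0, 2 * np.pi))

    amplitude = 1.0  # BOLD fluctuation amplitude on a baseline of ~100
    data = np.zeros(spec.shape + (T,), np.float64)
    # radial intensity falloff gives the EPI-like tissue contrast that makes
    # frame-to-reference motion estimation identifiable
    baseline = 100.0 * (1.0 - 0.4 * np.clip(f_sq, 0.0, 1.0)) * mask
    roi_of = atlas.labels  # 0 background
    for t in range(T):
        frame = baseline.copy()
        frame[mask] += amplitude * (signals[t, roi_of[mask] - 1] + drift[t])
        data[..., t] = frame
    data += spec.noise_sd * rng.standard_normal(data.shape)

    affine = spec.affine()
    trans = np.zeros((T, 3))
    rots = np.zeros((T, 3))
    for frame, shift_mm in spec.motion_spikes:
        trans[frame, 0] = shift_mm
        motion = RigidTransform(translation=[shift_mm, 0.0, 0.0])
        moved = resample_rigid(
            VolumeImage(data[..., frame], affine), motion, spec.shape, affine
        )
        data[..., frame] = moved.data
    vol = VolumeImage(data, affine, tr=spec.tr)
    motion_trace = MotionTrace(trans, rots, reference_frame=0)
    return FmriPhantom(
        volume=vol,
        motion=motion_trace,
        atlas=atlas,
        true_fc=true_fc,
        mask=mask.astype(np.uint8),
        roi_signals=signals,
    )


def make_registration_phantom(
    shape: tuple[int, int, int] = (24, 24, 24),
    voxel_size: float = 3.0,
    n_blobs: int = 6,
    seed: int = 0,
) -> VolumeImage:
    """Smooth, rotationally asymmetric phantom for registration tests.

    A sum of anisotropic Gaussian blobs at random interior positions; unlike
    the near-spherical cortical phantom, its orientation is identifiable, so
    planted rigid transforms are recoverable ground truth.
    """
    rng = _rng(seed, "registration", "blobs")
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    data = np.zeros(shape)
    c = (np.asarray(shape, float) - 1) / 2
    for _ in range(n_blobs):
        pos = c + rng.uniform(-0.25, 0.25, 3) * np.asarray(shape)
        sig = rng.uniform(1.5, 3.5, 3)
        amp = rng.uniform(0.5, 1.5)
        e = sum(((g - p) / s) ** 2 for g, p, s in zip(grids, pos, sig))
        data += amp * np.exp(-0.5 * e)
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size
    aff[:3, 3] = -c * voxel_size
    return VolumeImage(data, aff)


def make_roster(spec: PhantomSpec) -> pd.DataFrame:
    """Subject roster: ids and class labels for the whole cohort."""
    rows = [
        {"subject_id": f"asd_{i:03d}", "label": ASD} for i in range(spec.n_asd)
    ] + [
        {"subject_id": f"con_{i:03d}", "label": CONTROL}
        for i in range(spec.n_control)
    ]
    return pd.DataFrame(rows)


def write_dataset(spec: PhantomSpec, out_dir: str | Path, modalities=("smri", "fmri")) -> Path:
    """Generate the full cohort to disk: NIfTI volumes, roster CSV and a
    ground-truth JSON (motion, FC, effect sizes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roster = make_roster(spec)
    truth: dict = {"spec": {**asdict(spec), "shape": list(spec.shape)}, "subjects": {}}
    paths_smri, paths_fmri = [], []
    for _, row in roster.iterrows():
        sid, label = row.subject_id, row.label
        rec: dict = {"label": label}
        if "smri" in modalities:
            ph = make_smri_phantom(spec, sid, label)
            p = out / f"{sid}_smri.nii.gz"
            save_nifti(ph.volume, p)
            paths_smri.append(str(p))
            rec["shell_thickness_vox"] = ph.shell_thickness_vox
            rec["shell_voxels"] = int(ph.shell_mask.sum())
        if "fmri" in modalities:
            ph4 = make_fmri_phantom(spec, sid, label)
            p = out / f"{sid}_fmri.nii.gz"
            save_nifti(ph4.volume, p)
            paths_fmri.append(str(p))
            rec["true_fc_pair"] = float(ph4.true_fc[0, 1])
            rec["motion_translations"] = ph4.motion.translations[
                np.any(ph4.motion.translations != 0, axis=1)
            ].tolist()
        truth["subjects"][sid] = rec
    if "fmri" in modalities:
        mask = _ellipsoid_sq_radius(spec.shape, 0.40 * np.asarray(spec.shape)) <= 1.0
        atlas = make_atlas(spec.shape, spec.n_rois, mask)
        save_nifti(
            VolumeImage(atlas.labels.astype(np.int16), spec.affine()),
            out / "atlas.nii.gz",
        )
    if paths_smri:
        roster["smri_path"] = paths_smri
    if paths_fmri:
        roster["fmri_path"] = paths_fmri
    roster.to_csv(out / "roster.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out
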