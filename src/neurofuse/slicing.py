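"""Multi-view slice extraction, augmentation and subject-level splitting.

A subject's 3D volume yields, per anatomical plane, a centred window of
successive mid-slices resized to a common pixel grid.  Train/test
partitioning happens at the subject level before any augmentation, and the
slice accounting (subjects x slices per plane per split per class) is
reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .volumes import PLANE_AXES, VolumeImage

__all__ = [
    "SliceStack",
    "AugmentParams",
    "mid_slice_indices",
    "extract_plane_slices",
    "exclude_endpoints",
    "subject_split",
    "count_slices",
    "draw_augment_params",
    "apply_augment",
    "augment",
    "assemble_multiview",
]

PLANES = ("axial", "coronal", "sagittal")
DEFAULT_OUT_SIZE = 224


@dataclass
class SliceStack:
    """A stack of same-sized 2D slices from one plane of one subject."""

    plane: str
    indices: np.ndarray
    slices: np.ndarray  # (n, H, W)
    subject_id: str = ""
    split: str | None = None

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        self.indices = np.asarray(self.indices, int)
        self.slices = np.asarray(self.slices, float)
        if self.slices.ndim != 3 or len(self.indices) != self.slices.shape[0]:
            raise ValueError("slices must be (n, H, W) matching indices")
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("slice indices must be strictly increasing")


@dataclass
class AugmentParams:
    """One augmentation draw, shared by every slice of a volume."""

    rotation_deg: float = 0.0
    flip_horizontal: bool = False
    flip_vertical: bool = False
    intensity_scale: float = 1.0


def mid_slice_indices(dim_size: int, n: int) -> np.ndarray:
    """Centred window of ``n`` successive slice indices.

    The window starts at floor((dim_size - n) / 2); the single-slice case
    uses the mid coordinate floor(dim_size / 2).
    """
    if not (1 <= n <= dim_size):
        raise ValueError(f"need 1 <= n <= {dim_size}, got n={n}")
    if n == 1:
        return np.array([dim_size // 2])
    start = (dim_size - n) // 2
    return np.arange(start, start + n)


def extract_plane_slices(
    vol: VolumeImage, plane: str, n: int, out_size: int = DEFAULT_OUT_SIZE,
    subject_id: str = "",
) -> SliceStack:
    """Extract ``n`` centred slices orthogonal to a plane axis, bilinearly
    resized to out_size x out_size."""
    if plane not in PLANE_AXES:
        raise ValueError(f"unknown plane {plane!r}")
    axis = PLANE_AXES[plane]
    data = np.asarray(vol.data, float)
    if data.ndim != 3:
        raise ValueError("extract_plane_slices expects a 3D volume")
    idx = mid_slice_indices(data.shape[axis], n)
    slices = np.moveaxis(np.take(data, idx, axis=axis), axis, 0)
    if slices.shape[1:] != (out_size, out_size):
        slices = np.stack(
            [
                resize(s, (out_size, out_size), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
                for s in slices
            ]
        )
    return SliceStack(plane=plane, indices=idx, slices=slices, subject_id=subject_id)


def exclude_endpoints(T: int, k: int = 10) -> np.ndarray:
    """Frame indices with the first and last ``k`` removed."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > 0 and T <= 2 * k:
        raise ValueError(f"T={T} leaves no frames after excluding 2*{k} endpoints")
    return np.arange(k, T - k)


def subject_split(
    roster: pd.DataFrame, test_frac: float = 0.2, seed: int = 0
) -> pd.DataFrame:
    """Seeded subject-level split: per class, floor(test_frac * n) subjects go
    to the test set, the rest to train.

    Returns the roster with a ``split`` column added.
    """
    if roster.empty:
        raise ValueError("empty roster")
    if not (0 < test_frac < 1):
        raise ValueError("test_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = roster.copy().reset_index(drop=True)
    out["split"] = "train"
    for label, grp in out.groupby("label", sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"class {label!r} has fewer than 2 subjects")
        n_test = int(np.floor(test_frac * n))
        perm = rng.permutation(n)
        test_rows = grp.index.to_numpy()[perm[:n_test]]
        out.loc[test_rows, "split"] = "test"
    return out


def count_slices(manifest: pd.DataFrame, n_slices: int,
                 planes: tuple[str, ...] = PLANES) -> pd.DataFrame:
    """Slice accounting: subjects x n_slices per (plane, split, label)."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    subj_counts = (
        manifest.groupby(["split", "label"])["subject_id"].nunique().reset_index()
    )
    rows = []
    for plane in planes:
        for _, row in subj_counts.iterrows():
            rows.append(
                {
                    "plane": plane,
                    "split": row["split"],
                    "label": row["label"],
                    "n_subjects": int(row["subject_id"]),
                    "n_slices": int(row["subject_id"]) * n_slices,
                }
            )
    return pd.DataFrame(rows)


def draw_augment_params(rng: np.random.Generator) -> AugmentParams:
    """One training-time augmentation draw: rotation within +-10 degrees,
    each flip with probability 0.5, intensity scale in [0.9, 1.1]."""
    return AugmentParams(
        rotation_deg=float(rng.uniform(-10.0, 10.0)),
        flip_horizontal=bool(rng.random() < 0.5),
        flip_vertical=bool(rng.random() < 0.5),
        intensity_scale=float(rng.uniform(0.9, 1.1)),
    )


def apply_augment(stack: SliceStack, params: AugmentParams) -> SliceStack:
    """Apply one parameter draw consistently to every slice of the stack."""
    out = stack.slices.copy()
    if params.rotation_deg != 0.0:
        out = np.stack(
            [
                ndimage.rotate(s, params.rotation_deg, reshape=False, order=1,
                               mode="constant", cval=0.0)
                for s in out
            ]
        )
    if params.flip_horizontal:
        out = out[:, :, ::-1]
    if params.flip_vertical:
        out = out[:, ::-1, :]
    out = out * params.intensity_scale
    return SliceStack(
        plane=stack.plane,
        indices=stack.indices,
        slices=out,
        subject_id=stack.subject_id,
        split=stack.split,
    )


def augment(stack: SliceStack, rng: np.random.Generator) -> SliceStack:
    """Draw augmentation parameters and apply them to a training stack.

    Refuses test-split data: no augmentation during validation or testing.
    """
    if stack.split == "test":
        raise ValueError("augmentation is not applied to test-split data")
    return apply_augment(stack, draw_augment_params(rng))


def assemble_multiview(stacks: dict[str, SliceStack] | list[SliceStack]) -> np.ndarray:
    """Stack the three plane stacks into a (3, n, H, W) tensor in the fixed
    order (axial, coronal, sagittal), regardless of input order."""
    if not isinstance(stacks, dict):
        stacks = {s.plane: s for s in stacks}
    missing = [p for p in PLANES if p not in stacks]
    if missing:
        raise ValueError(f"missing plane(s): {missing}")
    arrs = [np.asarray(stacks[p].slices, float) for p in PLANES]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("plane stacks must share n and H x W")
    return np.stack(arrs, axis=0)
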