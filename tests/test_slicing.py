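"""Mid-slice windows, resizing, endpoint exclusion, subject-level splits,
slice accounting and augmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neurofuse import phantom as ph
from neurofuse.slicing import (
    PLANES,
    AugmentParams,
    apply_augment,
    assemble_multiview,
    augment,
    count_slices,
    draw_augment_params,
    exclude_endpoints,
    extract_plane_slices,
    mid_slice_indices,
    subject_split,
    SliceStack,
)
from neurofuse.volumes import VolumeImage


class TestMidSliceIndices:
    @pytest.mark.parametrize(
        "dim,n,expected",
        [
            (128, 1, [64]),          # single mid-slice at floor(D/2)
            (10, 10, list(range(10))),
            (128, 50, list(range(39, 89))),  # floor((128-50)/2) = 39
        ],
    )
    def test_window_conventions(self, dim, n, expected):
        assert mid_slice_indices(dim, n).tolist() == expected

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            mid_slice_indices(8, 9)

    @given(dim=st.integers(2, 300), n=st.integers(2, 300))
    @settings(max_examples=100, deadline=None)
    def test_window_centred_and_in_range(self, dim, n):
        if n > dim:
            return
        idx = mid_slice_indices(dim, n)
        assert len(idx) == n
        assert idx[0] >= 0 and idx[-1] < dim
        # window centred: margins differ by at most one slice
        assert abs(idx[0] - (dim - 1 - idx[-1])) <= 1


class TestExtractPlaneSlices:
    def test_constant_volume_constant_slices(self):
        vol = VolumeImage(np.full((32, 32, 32), 3.0), np.eye(4))
        stack = extract_plane_slices(vol, "axial", 4, out_size=16)
        assert np.allclose(stack.slices, 3.0)
        assert stack.slices.shape == (4, 16, 16)

    def test_single_mid_slice_resized_to_224(self, rng):
        vol = VolumeImage(rng.random((64, 64, 64)), np.eye(4))
        stack = extract_plane_slices(vol, "coronal", 1)
        assert stack.slices.shape == (1, 224, 224)
        assert stack.indices.tolist() == [32]

    def test_resize_of_matching_size_is_identity(self, rng):
        vol = VolumeImage(rng.random((8, 224, 224)), np.eye(4))
        stack = extract_plane_slices(vol, "sagittal", 2, out_size=224)
        expected = vol.data[mid_slice_indices(8, 2)]
        assert np.abs(stack.slices - expected).max() < 1e-6

    def test_planes_pick_correct_axis(self, rng):
        data = rng.random((6, 7, 8))
        vol = VolumeImage(data, np.eye(4))
        sag = extract_plane_slices(vol, "sagittal", 1, out_size=7)
        assert sag.slices.shape == (1, 7, 8)[0:1] + sag.slices.shape[1:]
        axial = extract_plane_slices(vol, "axial", 1, out_size=6)
        assert axial.indices[0] == 4  # floor(8/2)

    def test_unknown_plane(self, rng):
        vol = VolumeImage(rng.random((8, 8, 8)), np.eye(4))
        with pytest.raises(ValueError, match="plane"):
            extract_plane_slices(vol, "oblique", 1)


class TestExcludeEndpoints:
    def test_default_removes_first_and_last_ten(self):
        idx = exclude_endpoints(100, k=10)
        assert len(idx) == 80
        assert idx[0] == 10 and idx[-1] == 89

    def test_k_zero_keeps_all(self):
        assert exclude_endpoints(7, k=0).tolist() == list(range(7))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            exclude_endpoints(20, k=10)


class TestSubjectSplit:
    def test_study_roster_split_counts(self):
        """79 cases -> 64/15 and 105 controls -> 84/21 at an 80/20 split."""
        roster = ph.make_roster(ph.PhantomSpec())
        manifest = subject_split(roster, test_frac=0.2, seed=17)
        asd = manifest[manifest.label == ph.ASD]
        nc = manifest[manifest.label == ph.CONTROL]
        assert (asd.split == "train").sum() == 64
        assert (asd.split == "test").sum() == 15
        assert (nc.split == "train").sum() == 84
        assert (nc.split == "test").sum() == 21

    def test_small_roster_floor_rounding(self):
        roster = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(5)], "label": ["A"] * 5}
        )
        manifest = subject_split(roster, test_frac=0.2, seed=0)
        assert (manifest.split == "test").sum() == 1

    def test_no_subject_leakage_over_many_seeds(self):
        roster = ph.make_roster(
            ph.PhantomSpec(n_asd=13, n_control=17)
        )
        for seed in range(100):
            manifest = subject_split(roster, seed=seed)
            train = set(manifest[manifest.split == "train"].subject_id)
            test = set(manifest[manifest.split == "test"].subject_id)
            assert not train & test
            assert train | test == set(roster.subject_id)

    def test_tiny_class_rejected(self):
        roster = pd.DataFrame({"subject_id": ["a"], "label": ["A"]})
        with pytest.raises(ValueError):
            subject_split(roster)


class TestCountSlices:
    @pytest.mark.parametrize(
        "n_slices,cells",
        [
            (1, {("train", ph.ASD): 64, ("train", ph.CONTROL): 84,
                 ("test", ph.ASD): 15, ("test", ph.CONTROL): 21}),
            (10, {("train", ph.ASD): 640, ("train", ph.CONTROL): 840,
                  ("test", ph.ASD): 150, ("test", ph.CONTROL): 210}),
            (50, {("train", ph.ASD): 3200, ("train", ph.CONTROL): 4200,
                  ("test", ph.ASD): 750, ("test", ph.CONTROL): 1050}),
        ],
    )
    def test_study_accounting_reproduced(self, n_slices, cells):
        roster = ph.make_roster(ph.PhantomSpec())
        manifest = subject_split(roster, test_frac=0.2, seed=5)
        counts = count_slices(manifest, n_slices)
        for plane in PLANES:
            sub = counts[counts.plane == plane]
            for (split, label), expected in cells.items():
                cell = sub[(sub.split == split) & (sub.label == label)]
                assert int(cell.n_slices.iloc[0]) == expected

    def test_zero_slices_rejected(self):
        roster = ph.make_roster(ph.PhantomSpec(n_asd=2, n_control=2))
        manifest = subject_split(roster, seed=0)
        with pytest.raises(ValueError):
            count_slices(manifest, 0)


class TestAugment:
    def stack_of(self, rng, split=None):
        return SliceStack(
            plane="axial", indices=np.arange(3),
            slices=rng.random((3, 16, 16)), subject_id="s0", split=split,
        )

    def test_identity_draw_is_identity(self, rng):
        stack = self.stack_of(rng)
        out = apply_augment(stack, AugmentParams())
        assert np.array_equal(out.slices, stack.slices)

    def test_intensity_scale_scales_mean(self, rng):
        stack = self.stack_of(rng)
        out = apply_augment(stack, AugmentParams(intensity_scale=1.1))
        assert out.slices.mean() == pytest.approx(1.1 * stack.slices.mean(),
                                                  rel=1e-6)

    def test_seeded_draws_are_reproducible(self, rng):
        stack = self.stack_of(rng)
        a = augment(stack, np.random.default_rng(5))
        b = augment(stack, np.random.default_rng(5))
        assert np.array_equal(a.slices, b.slices)

    def test_draw_ranges(self):
        r = np.random.default_rng(0)
        for _ in range(200):
            p = draw_augment_params(r)
            assert -10 <= p.rotation_deg <= 10
            assert 0.9 <= p.intensity_scale <= 1.1

    def test_refuses_test_split(self, rng):
        stack = self.stack_of(rng, split="test")
        with pytest.raises(ValueError, match="test"):
            augment(stack, np.random.default_rng(0))

    def test_shared_draw_preserves_interslice_structure(self, rng):
        """One draw applied to all slices keeps their correlation pattern."""
        base = rng.random((16, 16))
        slices = np.stack([base, base * 0.5, base * 2.0])
        stack = SliceStack(plane="axial", indices=np.arange(3),
                           slices=slices, subject_id="s")
        out = apply_augment(
            stack, AugmentParams(rotation_deg=7.0, flip_horizontal=True,
                                 intensity_scale=1.05)
        )
        flat = out.slices.reshape(3, -1)
        corr = np.corrcoef(flat)
        assert corr[0, 1] > 0.99 and corr[0, 2] > 0.99


class TestAssembleMultiview:
    def make_stacks(self, rng, n=2, size=8):
        return {
            p: SliceStack(plane=p, indices=np.arange(n),
                          slices=rng.random((n, size, size)))
            for p in PLANES
        }

    def test_shape_and_plane_order_stable(self, rng):
        stacks = self.make_stacks(rng)
        t1 = assemble_multiview(stacks)
        t2 = assemble_multiview([stacks["sagittal"], stacks["axial"],
                                 stacks["coronal"]])
        assert t1.shape == (3, 2, 8, 8)
        assert np.array_equal(t1, t2)
        assert np.array_equal(t1[0], stacks["axial"].slices)
        assert np.array_equal(t1[2], stacks["sagittal"].slices)

    def test_missing_plane_rejected(self, rng):
        stacks = self.make_stacks(rng)
        del stacks["coronal"]
        with pytest.raises(ValueError, match="coronal"):
            assemble_multiview(stacks)

    def test_50_slice_224_layout(self):
        stacks = {
            p: SliceStack(plane=p, indices=np.arange(50),
                          slices=np.zeros((50, 224, 224)))
            for p in PLANES
        }
        assert assemble_multiview(stacks).shape == (3, 50, 224, 224)
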