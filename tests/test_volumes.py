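import numpy as np
import pytest

import voxelbma as vb
from voxelbma.volumes import UNCLASSIFIED, load_volume, save_volume


@pytest.fixture()
def tiny_stack():
    rng = np.random.default_rng(2)
    data = rng.uniform(0.3, 0.6, size=(4, 4, 3, 5))
    return vb.FAStack(data=data, affine=np.eye(4), subject_order=[f"s{i}" for i in range(5)])


class TestLoadFAStack:
    def test_per_file_route_orders_subjects_like_table(self, tmp_path, tiny_stack):
        ids = tiny_stack.subject_order
        paths = []
        for i, sid in enumerate(ids):
            p = tmp_path / f"{sid}.nii.gz"
            save_volume(tiny_stack.data[..., i], np.eye(4), p)
            paths.append(p)
        stack = vb.load_fa_stack(paths, ids)
        assert stack.data.shape == (4, 4, 3, 5)
        assert stack.subject_order == list(ids)
        assert np.allclose(stack.data, tiny_stack.data)

    def test_4d_route_matches_per_file_route(self, tmp_path, tiny_stack):
        ids = tiny_stack.subject_order
        p4d = tmp_path / "stack.nii.gz"
        # write in reversed order; the sidecar must drive reordering
        save_volume(tiny_stack.data[..., ::-1], np.eye(4), p4d)
        stack = vb.load_fa_stack(p4d, ids, subject_order=list(reversed(ids)))
        assert np.allclose(stack.data, tiny_stack.data)
        assert stack.subject_order == list(ids)

    def test_mismatched_grid_names_offending_file(self, tmp_path, tiny_stack):
        ids = tiny_stack.subject_order[:2]
        good = tmp_path / "good.nii.gz"
        bad = tmp_path / "bad.nii.gz"
        save_volume(tiny_stack.data[..., 0], np.eye(4), good)
        save_volume(np.zeros((5, 5, 5)), np.eye(4), bad)
        with pytest.raises(ValueError, match="bad.nii.gz"):
            vb.load_fa_stack([good, bad], ids)

    def test_duplicate_subject_ids_rejected(self, tmp_path, tiny_stack):
        with pytest.raises(ValueError, match="duplicate"):
            vb.load_fa_stack([], ["a", "a"])

    def test_missing_subject_in_sidecar_rejected(self, tmp_path, tiny_stack):
        p4d = tmp_path / "stack.nii.gz"
        save_volume(tiny_stack.data, np.eye(4), p4d)
        wrong = list(tiny_stack.subject_order)
        wrong[0] = "stranger"
        with pytest.raises(ValueError, match="subject_order"):
            vb.load_fa_stack(p4d, tiny_stack.subject_order, subject_order=wrong)


class TestBuildMask:
    def test_mean_threshold_rule(self):
        data = np.full((2, 1, 1, 4), 0.21)
        data[1] = 0.19
        stack = vb.FAStack(data=data, affine=np.eye(4), subject_order=list("abcd"))
        mask, n = vb.build_mask(stack, 0.2)
        assert mask[0, 0, 0] and not mask[1, 0, 0]
        assert n == 1

    def test_single_black_subject_excludes_voxel(self):
        data = np.full((1, 1, 1, 4), 0.5)
        data[0, 0, 0, 2] = 0.0
        stack = vb.FAStack(data=data, affine=np.eye(4), subject_order=list("abcd"))
        mask, n = vb.build_mask(stack, 0.2)
        assert n == 0
        # weaker reading: black only if zero in all subjects
        mask_all, n_all = vb.build_mask(stack, 0.2, black_rule="all")
        assert n_all == 1

    def test_all_above_threshold_keeps_every_voxel(self, tiny_stack):
        mask, n = vb.build_mask(tiny_stack, 0.2)
        assert n == np.prod(tiny_stack.grid_shape)

    def test_mask_invariant_to_subject_order(self, tiny_stack):
        rng = np.random.default_rng(0)
        perm = rng.permutation(tiny_stack.n_subjects)
        shuffled = vb.FAStack(
            data=tiny_stack.data[..., perm], affine=np.eye(4),
            subject_order=[tiny_stack.subject_order[i] for i in perm],
        )
        m1, _ = vb.build_mask(tiny_stack, 0.25)
        m2, _ = vb.build_mask(shuffled, 0.25)
        assert np.array_equal(m1, m2)

    @pytest.mark.parametrize("thr", [0.0, 1.0, -0.5])
    def test_threshold_outside_unit_interval_rejected(self, tiny_stack, thr):
        with pytest.raises(ValueError, match="fa_threshold"):
            vb.build_mask(tiny_stack, thr)


class TestAtlas:
    def test_lookup_and_unclassified_convention(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 5
        atlas = vb.AtlasVolume(labels=labels, lookup={5: "Genu of corpus callosum"})
        names = vb.voxels_to_regions([(1, 1, 1), (0, 0, 0)], atlas)
        assert names == ["Genu of corpus callosum", UNCLASSIFIED]

    def test_nonzero_label_missing_from_lookup_rejected(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        labels[0, 0, 0] = 7
        with pytest.raises(ValueError, match="7"):
            vb.AtlasVolume(labels=labels, lookup={1: "a"})

    def test_out_of_grid_voxel_rejected(self):
        atlas = vb.AtlasVolume(labels=np.zeros((2, 2, 2), dtype=np.int32), lookup={})
        with pytest.raises(IndexError):
            vb.voxels_to_regions([(5, 0, 0)], atlas)

    def test_48_region_lookup_round_trips_unique(self, tmp_path):
        # a full-size white-matter lookup table: 48 uniquely named regions
        lookup = {i: f"white-matter-region-{i:02d}" for i in range(1, 49)}
        path = tmp_path / "jhu_like_synthetic.tsv"
        vb.write_atlas_lookup(lookup, path)
        back = vb.read_atlas_lookup(path)
        assert back == lookup
        assert len(set(back.values())) == 48

    def test_label_zero_reserved_in_lookup_file(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("label\tregion_name\n0\tnope\n")
        with pytest.raises(ValueError, match="reserved"):
            vb.read_atlas_lookup(path)


class TestRoundTrips:
    def test_volume_write_read_bit_exact(self, tmp_path):
        rng = np.random.default_rng(9)
        data = rng.uniform(0, 1, (6, 5, 4))
        path = tmp_path / "map.nii.gz"
        save_volume(data, np.eye(4), path)
        back, affine = load_volume(path)
        assert np.array_equal(back, data)
        assert np.array_equal(affine, np.eye(4))

    def test_boolean_mask_round_trip(self, tmp_path):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        path = tmp_path / "mask.nii.gz"
        save_volume(mask, np.eye(4), path)
        back, _ = load_volume(path)
        assert np.array_equal(back.astype(bool), mask)
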