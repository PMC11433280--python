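"""Curation rules, patch geometry, augmentation and manifest splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodulecascade.datapipe import (AugmentationSpec, NoduleAnnotation,
                                    augment, consensus_mask, crop_patch,
                                    label_nodule, load_image, load_mask,
                                    read_annotations, read_manifest, resample,
                                    save_image, save_mask, split_manifest)


def ann(scores, diameter=8.0, masks=None, legible=True, nid="n1"):
    return NoduleAnnotation(nodule_id=nid, reader_scores=tuple(scores),
                            diameter_mm=diameter,
                            reader_mask_count=len(scores) if masks is None else masks,
                            id_legible=legible)


class TestLabelNodule:
    @pytest.mark.parametrize("scores,expected", [
        ([1, 2, 2, 1], "benign"),
        ([3, 3, 3, 3], "excluded"),
        ([5, 4, 4], "malignant"),
        ([4, 4, 5, 5], "malignant"),
        ([2, 2, 1, 1], "benign"),
        ([2, 3, 4, 5], "excluded"),  # median 3.5: indeterminate band
    ])
    def test_median_score_banding(self, scores, expected):
        assert label_nodule(ann(scores)) == expected

    def test_size_exclusions(self):
        assert label_nodule(ann([5, 4, 4], diameter=2.5)) == "excluded"
        assert label_nodule(ann([5, 4, 4], diameter=26.0)) == "excluded"
        assert label_nodule(ann([5, 4, 4], diameter=3.0)) == "malignant"
        assert label_nodule(ann([5, 4, 4], diameter=25.0)) == "malignant"

    def test_illegible_id_excluded(self):
        assert label_nodule(ann([1, 1, 2], legible=False)) == "excluded"

    def test_reader_consensus_requires_two_thirds(self):
        # 4 readers -> at least ceil(8/3) = 3 delineations
        assert label_nodule(ann([1, 1, 2, 2], masks=2)) == "excluded"
        assert label_nodule(ann([1, 1, 2, 2], masks=3)) == "benign"

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            NoduleAnnotation("x", (), 8.0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 5), min_size=1, max_size=6),
           st.floats(0.5, 40.0), st.integers(0, 6), st.booleans())
    def test_every_annotation_maps_to_one_category(self, scores, diam, masks,
                                                   legible):
        a = NoduleAnnotation("p", tuple(scores), diam,
                             min(masks, len(scores)), legible)
        assert label_nodule(a) in {"benign", "malignant", "excluded"}


class TestConsensusMask:
    def test_unanimous_masks_returned_verbatim(self, rng):
        m = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        assert np.array_equal(consensus_mask([m] * 4), m)

    def test_half_votes_are_foreground(self):
        m1 = np.zeros((2, 2), np.uint8)
        m1[0, 0] = 1
        out = consensus_mask([m1, m1, np.zeros_like(m1), np.zeros_like(m1)])
        assert out[0, 0] == 1  # 2 of 4 readers -> kept

    def test_minority_votes_are_background(self):
        m1 = np.zeros((2, 2), np.uint8)
        m1[0, 0] = 1
        zeros = np.zeros_like(m1)
        assert consensus_mask([m1, zeros, zeros, zeros])[0, 0] == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_mask([np.zeros((2, 2)), np.zeros((3, 3))])


class TestCropPatch:
    def test_interior_crop_is_exact_window(self, rng):
        img = rng.random((512, 512, 3))
        msk = np.zeros((512, 512), np.uint8)
        msk[250:262, 250:262] = 1
        patch, mp = crop_patch(img, msk, (256, 256), size=64)
        assert patch.shape == (64, 64, 3)
        assert np.array_equal(patch, img[224:288, 224:288])
        assert mp.sum() == msk.sum()

    def test_border_crop_zero_pads(self, rng):
        img = rng.random((100, 100))
        msk = np.zeros((100, 100), np.uint8)
        patch, _ = crop_patch(img, msk, (10, 10), size=64)
        assert patch.shape == (64, 64)
        assert np.all(patch[:22, :] == 0) and np.all(patch[:, :22] == 0)

    def test_mask_centroid_lands_at_patch_center(self):
        img = np.zeros((200, 200))
        msk = np.zeros((200, 200), np.uint8)
        msk[90:101, 140:151] = 1  # centroid (95, 145)
        cy, cx = np.argwhere(msk).mean(axis=0)
        _, mp = crop_patch(img, msk, (cy, cx), size=64)
        py, px = np.argwhere(mp).mean(axis=0)
        assert abs(py - 31.5) <= 0.5 and abs(px - 31.5) <= 0.5


class TestAugment:
    def test_copy_count_gives_nine_fold_increase(self, rng):
        patch = rng.random((64, 64, 3)).astype(np.float32)
        mask = (rng.random((64, 64)) < 0.2).astype(np.uint8)
        out = augment(patch, mask, AugmentationSpec(copies=9, seed=3))
        assert len(out) == 9  # + the original = 10 images per source

    def test_flips_are_involutions_and_preserve_area(self, rng):
        patch = rng.random((32, 32)).astype(np.float32)
        mask = (rng.random((32, 32)) < 0.3).astype(np.uint8)
        assert np.array_equal(patch[:, ::-1][:, ::-1], patch)
        spec = AugmentationSpec(copies=20, seed=0)
        for img, msk in augment(patch, mask, spec):
            assert img.shape[:2] == (32, 32)
            if msk.sum() == mask.sum():  # flips preserve area exactly
                continue
            # crop/zoom families may change area but never beyond bounds
            assert 0 <= msk.sum() <= msk.size

    def test_reproducible_under_seed(self, rng):
        patch = rng.random((32, 32, 3)).astype(np.float32)
        mask = (rng.random((32, 32)) < 0.3).astype(np.uint8)
        spec = AugmentationSpec(copies=5, seed=11)
        a = augment(patch, mask, spec)
        b = augment(patch, mask, spec)
        for (ia, ma), (ib, mb) in zip(a, b):
            assert np.array_equal(ia, ib) and np.array_equal(ma, mb)

    def test_same_transform_applied_to_image_and_mask(self):
        # encode coordinates in the image; the mask marks one quadrant
        yy, xx = np.mgrid[0:32, 0:32]
        patch = (xx / 31.0).astype(np.float32)
        mask = (xx >= 16).astype(np.uint8)
        for img, msk in augment(patch, mask, AugmentationSpec(copies=12, seed=5)):
            # wherever the mask says right-half, the intensity must be high
            if msk.sum() and (msk == 0).sum():
                assert img[msk == 1].mean() > img[msk == 0].mean()


class TestResample:
    def test_resamples_to_224(self, rng):
        patch = rng.random((64, 64, 3)).astype(np.float32)
        mask = (rng.random((64, 64)) < 0.3).astype(np.uint8)
        img, msk = resample(patch, mask, 224)
        assert img.shape[:2] == (224, 224) and msk.shape == (224, 224)

    def test_mask_stays_binary_and_constant_image_stays_constant(self):
        img, msk = resample(np.full((64, 64), 0.37, np.float32),
                            (np.arange(64 * 64).reshape(64, 64) % 2).astype(np.uint8),
                            224)
        assert set(np.unique(msk)) <= {0, 1}
        assert np.allclose(img, 0.37, atol=1e-6)


class TestSplitManifest:
    def _manifest(self, n, copies=1):
        rows = []
        for i in range(n):
            label = "benign" if i % 2 == 0 else "malignant"
            for c in range(copies):
                rows.append({"image_path": f"img_{i}_{c}.png",
                             "mask_path": f"msk_{i}_{c}.png",
                             "label": label, "source_id": f"s{i}", "split": ""})
        return pd.DataFrame(rows)

    def test_six_two_two_split_sizes(self):
        man = split_manifest(self._manifest(100), ratios=(6, 2, 2), seed=0)
        counts = man["split"].value_counts()
        assert counts["train"] == 60 and counts["val"] == 20 and counts["test"] == 20

    def test_deterministic_under_seed(self):
        a = split_manifest(self._manifest(50), seed=9)
        b = split_manifest(self._manifest(50), seed=9)
        assert (a["split"] == b["split"]).all()

    def test_stratified_by_class(self):
        man = split_manifest(self._manifest(100), ratios=(6, 2, 2), seed=1)
        for split, expect in (("train", 30), ("val", 10), ("test", 10)):
            sub = man[man["split"] == split]
            assert (sub["label"] == "benign").sum() == expect

    def test_augmented_copies_stay_together(self):
        man = split_manifest(self._manifest(30, copies=10), seed=2)
        per_source = man.groupby("source_id")["split"].nunique()
        assert (per_source == 1).all()

    def test_too_few_sources_rejected(self):
        with pytest.raises(ValueError):
            split_manifest(self._manifest(2), ratios=(6, 2, 2), seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(6, 60), st.integers(1, 5), st.integers(0, 10_000))
    def test_leakage_guard_property(self, n_sources, copies, seed):
        man = split_manifest(self._manifest(n_sources, copies=copies), seed=seed)
        assert (man.groupby("source_id")["split"].nunique() == 1).all()
        assert set(man["split"]) <= {"train", "val", "test"}


class TestPngRoundTrip:
    def test_image_and_mask_io(self, tmp_path, rng):
        img = rng.random((3, 32, 32)).astype(np.float32)
        save_image(tmp_path / "i.png", img)
        back = load_image(tmp_path / "i.png")
        assert back.shape == (3, 32, 32)
        assert np.abs(back - img).max() <= 0.5 / 255 + 1e-6

    def test_mask_io_is_exact(self, tmp_path, rng):
        mask = (rng.random((32, 32)) < 0.3).astype(np.uint8)
        save_mask(tmp_path / "m.png", mask)
        assert np.array_equal(load_mask(tmp_path / "m.png"), mask)

    def test_probability_map_io_quantised(self, tmp_path, rng):
        p = rng.random((16, 16)).astype(np.float32)
        save_mask(tmp_path / "p.png", p)
        back = load_mask(tmp_path / "p.png", binary=False)
        assert np.abs(back - p).max() <= 0.5 / 255 + 1e-6


class TestTables:
    def test_annotation_csv_round_trip(self, tmp_path):
        pd.DataFrame({
            "nodule_id": ["a", "b"],
            "reader_scores": ["1;2;2;1", "5;4;4"],
            "diameter_mm": [8.0, 2.5],
            "reader_mask_count": [4, 3],
            "id_legible": [True, True],
        }).to_csv(tmp_path / "ann.csv", index=False)
        anns = read_annotations(tmp_path / "ann.csv")
        assert anns[0].reader_scores == (1, 2, 2, 1)
        assert label_nodule(anns[0]) == "benign"
        assert label_nodule(anns[1]) == "excluded"  # too small

    def test_manifest_validation(self, tmp_path):
        pd.DataFrame({"image_path": ["x"], "mask_path": ["y"],
                      "label": ["weird"], "source_id": ["s"],
                      "split": ["train"]}).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ValueError):
            read_manifest(tmp_path / "m.csv")
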