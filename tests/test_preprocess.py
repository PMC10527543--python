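"""Tests for normalization, augmentation, balancing and splitting."""

import numpy as np
import pandas as pd
import pytest

from leafara.manifest import read_manifest, validate_manifest, write_manifest
from leafara.preprocess import (
    AUG_OPS,
    augment_one,
    apply_record,
    balance_classes,
    build_augmented_dataset,
    compute_stats,
    inner_split,
    resize,
    split_dataset,
    zscore_apply,
)
from leafara.synth import PLANT_VILLAGE_COUNTS, SyntheticSample, generate_leaf_image, phenotype_specs

SPEC = {s.class_name: s for s in phenotype_specs()}


def make_manifest(counts: dict[str, int]) -> pd.DataFrame:
    rows = []
    for cls, n in counts.items():
        for i in range(n):
            rows.append({
                "path": f"{cls}/{i}.png", "mask_path": f"{cls}/{i}_m.png",
                "class": cls, "split": "unassigned", "provenance": "real",
                "transform": "", "parent": "", "seed": i,
            })
    return pd.DataFrame(rows)


class TestZScore:
    def test_constant_images_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compute_stats([np.full((4, 4, 3), 3.0)])

    def test_two_image_hand_example(self):
        stats = compute_stats([np.zeros((2, 2, 3)), np.full((2, 2, 3), 2.0)])
        assert stats.mean == pytest.approx([1.0, 1.0, 1.0])
        assert stats.std == pytest.approx([1.0, 1.0, 1.0])  # population std

    def test_order_invariant(self):
        a = np.random.default_rng(0).uniform(0, 255, (4, 4, 3))
        b = np.random.default_rng(1).uniform(0, 255, (4, 4, 3))
        s1, s2 = compute_stats([a, b]), compute_stats([b, a])
        assert np.allclose(s1.mean, s2.mean) and np.allclose(s1.std, s2.std)

    def test_normalized_training_set_standardized(self):
        rng = np.random.default_rng(2)
        imgs = [rng.uniform(0, 255, (8, 8, 3)) for _ in range(5)]
        stats = compute_stats(imgs)
        normed = np.concatenate([zscore_apply(im, stats).reshape(-1, 3) for im in imgs])
        assert np.allclose(normed.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(normed.std(axis=0), 1.0, atol=1e-6)

    def test_pointwise_formula(self):
        # pixel 5 with mean 3 and std 2 standardizes to 1.0
        stats = compute_stats([np.full((2, 2, 3), 1.0), np.full((2, 2, 3), 5.0)])
        out = zscore_apply(np.full((1, 1, 3), 5.0), stats)
        assert out == pytest.approx(np.ones((1, 1, 3)))


class TestResize:
    def test_own_size_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (16, 16, 3)).astype(np.uint8)
        assert np.array_equal(resize(img, (16, 16)), img)

    def test_constant_stays_constant(self):
        out = resize(np.full((32, 32, 3), 9, dtype=np.uint8), (224, 224))
        assert np.all(out == 9)

    def test_upsample_shape(self):
        out = resize(np.zeros((64, 64, 3), dtype=np.uint8), (224, 224))
        assert out.shape == (224, 224, 3)

    def test_mask_stays_binary(self):
        m = generate_leaf_image(SPEC["TH"], (64, 64), 0).mask
        out = resize(m, (100, 100), is_mask=True)
        assert set(np.unique(out)) <= {0, 1}


@pytest.fixture(scope="module")
def leaf():
    return generate_leaf_image(SPEC["TEB"], (64, 64), 4)


class TestAugmentOne:
    def test_rotation_angle_within_printed_range(self, leaf):
        for seed in range(10):
            _, rec = augment_one(leaf, "rotate", seed)
            assert 5.0 <= abs(rec.params["angle_deg"]) <= 15.0

    def test_scale_magnification_within_printed_range(self, leaf):
        for seed in range(10):
            _, rec = augment_one(leaf, "scale", seed)
            assert 2.5 <= rec.params["magnification_pct"] <= 10.0

    def test_translation_moves_mask_centroid_as_commanded(self, leaf):
        from scipy import ndimage

        aug, rec = augment_one(leaf, "translate", seed=3)
        dy = rec.params["shift_y_pct"] / 100.0 * 64
        dx = rec.params["shift_x_pct"] / 100.0 * 64
        assert 5.0 <= abs(rec.params["shift_x_pct"]) <= 20.0
        c0 = ndimage.center_of_mass(leaf.mask)
        c1 = ndimage.center_of_mass(aug.mask)
        assert abs((c1[0] - c0[0]) - dy) <= 1.0
        assert abs((c1[1] - c0[1]) - dx) <= 1.0

    def test_noise_std_matches_sigma(self):
        flat = SyntheticSample(np.full((256, 256, 3), 128, np.uint8),
                               np.ones((256, 256), np.uint8), "TH", 0)
        aug, rec = augment_one(flat, "noise", seed=5)
        diff = aug.image.astype(float) - 128.0
        assert abs(diff.std() - rec.params["sigma"]) / rec.params["sigma"] < 0.1

    def test_geometric_mask_image_consistency(self, leaf):
        """IoU(transform(mask), mask-of-transformed-mask-image) >= 0.95."""
        mask_as_img = SyntheticSample(
            np.repeat(leaf.mask[..., None] * 255, 3, axis=2).astype(np.uint8),
            leaf.mask, leaf.label, leaf.seed,
        )
        for op in ("rotate", "translate"):
            aug, rec = augment_one(mask_as_img, op, seed=6, fill=(0, 0, 0))
            via_image = aug.image[..., 0] > 127  # bilinear path, re-thresholded
            via_mask = aug.mask.astype(bool)  # nearest-neighbour path
            iou = (via_image & via_mask).sum() / max((via_image | via_mask).sum(), 1)
            assert iou >= 0.95

    def test_replay_is_exact(self, leaf):
        aug1, rec = augment_one(leaf, "rotate", seed=8)
        aug2 = apply_record(leaf, rec)
        assert np.array_equal(aug1.image, aug2.image)

    def test_unknown_op_rejected(self, leaf):
        with pytest.raises(ValueError):
            augment_one(leaf, "shear", 0)


class TestBalanceAugmentSplit:
    def test_published_counts_balance_to_3000(self):
        man = make_manifest(PLANT_VILLAGE_COUNTS)
        assert len(man) == 18161
        bal = balance_classes(man, per_class=300, seed=0)
        assert len(bal) == 3000
        assert (bal.groupby("class").size() == 300).all()

    def test_balance_single_row_per_class(self):
        bal = balance_classes(make_manifest({"TH": 5, "TBS": 7}), per_class=1, seed=0)
        assert len(bal) == 2

    def test_underfull_class_rejected_by_name(self):
        man = make_manifest({"TH": 299, "TBS": 300})
        with pytest.raises(ValueError, match="TH"):
            balance_classes(man, per_class=300)

    def test_combined_arithmetic_of_study(self):
        bal = balance_classes(make_manifest(PLANT_VILLAGE_COUNTS), 300, seed=1)
        combined = build_augmented_dataset(bal, variants_per_image=4, seed=1)
        aug = combined[combined["provenance"] == "augmented"]
        assert len(aug) == 12000
        assert len(combined) == 15000

    def test_minimal_augmentation(self):
        man = make_manifest({"TH": 1})
        combined = build_augmented_dataset(man, variants_per_image=1, seed=0)
        assert len(combined) == 2

    def test_augmented_rows_reference_parents(self):
        man = make_manifest({"TH": 3, "TBS": 3})
        combined = build_augmented_dataset(man, 4, seed=0)
        aug = combined[combined["provenance"] == "augmented"]
        parents = combined.set_index("path")
        for _, row in aug.iterrows():
            assert row["parent"] in parents.index
            assert parents.loc[row["parent"], "class"] == row["class"]

    def test_split_arithmetic_70_15_15(self):
        bal = balance_classes(make_manifest(PLANT_VILLAGE_COUNTS), 300, seed=2)
        combined = build_augmented_dataset(bal, 4, seed=2)
        out = split_dataset(combined, (70, 15, 15), seed=2)
        counts = out["split"].value_counts()
        assert counts["train"] == 10500
        assert counts["val"] == 2250
        assert counts["test"] == 2250

    def test_all_train_ratio(self):
        man = make_manifest({"TH": 4, "TBS": 4})
        out = split_dataset(man, (100, 0, 0))
        assert (out["split"] == "train").all()

    def test_no_leakage_between_parent_and_children(self):
        man = build_augmented_dataset(make_manifest({"TH": 10, "TBS": 10}), 3, seed=0)
        out = split_dataset(man, (60, 20, 20), seed=5)
        split_of = out.set_index("path")["split"]
        aug = out[out["provenance"] == "augmented"]
        assert (aug["split"].values == split_of[aug["parent"]].values).all()

    def test_stratification_within_one_sample(self):
        man = make_manifest({c: 40 for c in ("TH", "TBS", "TMV")})
        out = split_dataset(man, (70, 15, 15), seed=0)
        for _, grp in out.groupby("class"):
            counts = grp["split"].value_counts()
            assert abs(counts.get("train", 0) - 28) <= 1
            assert abs(counts.get("val", 0) - 6) <= 1
            assert abs(counts.get("test", 0) - 6) <= 1

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(make_manifest({"TH": 4}), (70, 15, 10))

    def test_inner_split_carves_val_from_train(self):
        man = make_manifest({"TH": 100})
        out = split_dataset(man, (100, 0, 0), seed=0)
        out = inner_split(out, val_fraction=0.10, seed=0)
        counts = out["split"].value_counts()
        assert counts["train"] == 90 and counts["val"] == 10


class TestManifestIO:
    def test_round_trip_identity(self, tmp_path):
        man = split_dataset(build_augmented_dataset(make_manifest({"TH": 5, "TBS": 5}), 2, seed=0), seed=0)
        p = tmp_path / "m.csv"
        write_manifest(man, str(p))
        back = read_manifest(str(p))
        pd.testing.assert_frame_equal(back, man)

    def test_duplicate_paths_rejected(self):
        man = make_manifest({"TH": 2})
        man.loc[1, "path"] = man.loc[0, "path"]
        with pytest.raises(ValueError, match="duplicate"):
            validate_manifest(man)

    def test_invalid_split_value_rejected(self):
        man = make_manifest({"TH": 1})
        man.loc[0, "split"] = "holdout"
        with pytest.raises(ValueError, match="split"):
            validate_manifest(man)

    def test_orphan_augmented_row_rejected(self):
        man = build_augmented_dataset(make_manifest({"TH": 2}), 1, seed=0)
        man = man[man["provenance"] == "augmented"].reset_index(drop=True)
        man_full = pd.concat([make_manifest({"TBS": 1}), man], ignore_index=True)
        with pytest.raises(ValueError, match="parent"):
            validate_manifest(man_full)
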