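"""Detective trainset construction, shortcut injection and splitting."""

import numpy as np
import pytest

from shortcutscope import (AdaSpec, DatasetItem, Image8, LabeledDataset,
                           build_detective_trainset, inject_shortcut,
                           load_dataset, save_dataset, split_train_val)


def _mini_pool(rng, n, side=16):
    return [Image8(rng.integers(0, 256, (side, side)), id=f"p{i}")
            for i in range(n)]


def _mini_dataset(rng, n_pos=6, n_neg=6, patients=None):
    items = []
    for i in range(n_pos + n_neg):
        pid = None if patients is None else patients[i]
        items.append(DatasetItem(
            image=Image8(rng.integers(0, 256, (16, 16)), id=f"d{i}"),
            label=1 if i < n_pos else 0,
            patient_id=pid,
        ))
    return LabeledDataset(items=tuple(items), name="mini")


class TestLabeledDataset:
    def test_duplicate_image_ids_rejected(self, rng):
        img = Image8(rng.integers(0, 256, (16, 16)), id="dup")
        with pytest.raises(ValueError, match="duplicate"):
            LabeledDataset(items=(DatasetItem(img, 0), DatasetItem(img, 1)))

    def test_bad_label_rejected(self, rng):
        img = Image8(rng.integers(0, 256, (16, 16)), id="x")
        with pytest.raises(ValueError, match="label"):
            DatasetItem(img, 2)


class TestBuildTrainset:
    def test_even_pool_splits_exactly_in_half(self, rng):
        pool = _mini_pool(rng, 40)
        spec = AdaSpec.default("C", seed=1)
        ds = build_detective_trainset(pool, spec, seed=2)
        assert len(ds) == 40
        assert ds.n_label(1) == 20 and ds.n_label(0) == 20

    def test_odd_pool_drops_one_with_warning(self, rng, caplog):
        pool = _mini_pool(rng, 41)
        spec = AdaSpec.default("C", seed=1)
        with caplog.at_level("WARNING"):
            ds = build_detective_trainset(pool, spec, seed=2)
        assert len(ds) == 40
        assert "dropping" in caplog.text

    def test_pool_too_small_errors(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            build_detective_trainset(_mini_pool(rng, 1), AdaSpec.default("C"), seed=0)

    def test_negative_class_pixels_untouched(self, rng):
        pool = _mini_pool(rng, 20)
        by_id = {img.id: img for img in pool}
        ds = build_detective_trainset(pool, AdaSpec.default("C", seed=3), seed=4)
        for it in ds.items:
            if it.label == 0:
                assert np.array_equal(it.image.pixels, by_id[it.image.id].pixels)

    def test_zero_strength_spec_leaves_both_classes_identical_to_pool(self, rng):
        pool = _mini_pool(rng, 20)
        by_id = {img.id: img for img in pool}
        spec = AdaSpec(kind="S", strength_low=0.0, strength_high=0.0, seed=1)
        ds = build_detective_trainset(pool, spec, seed=5)
        for it in ds.items:
            assert np.array_equal(it.image.pixels, by_id[it.image.id].pixels)

    def test_deterministic_given_pool_spec_seed(self, rng):
        pool = _mini_pool(rng, 30)
        spec = AdaSpec.default("S", seed=6)
        a = build_detective_trainset(pool, spec, seed=7)
        b = build_detective_trainset(pool, spec, seed=7)
        assert [it.label for it in a.items] == [it.label for it in b.items]
        for x, y in zip(a.items, b.items):
            assert np.array_equal(x.image.pixels, y.image.pixels)

    def test_records_spec_provenance(self, rng):
        spec = AdaSpec.default("C", seed=8)
        ds = build_detective_trainset(_mini_pool(rng, 10), spec, seed=9)
        assert ds.provenance["ada_spec"] == spec.to_config()


class TestInjectShortcut:
    @pytest.mark.parametrize("target,untouched_label", [
        ("positive", 0), ("negative", 1),
    ])
    def test_non_target_class_bit_identical(self, rng, target, untouched_label):
        ds = _mini_dataset(rng)
        out = inject_shortcut(ds, target, AdaSpec.default("S", seed=1))
        for before, after in zip(ds.items, out.items):
            assert after.label == before.label
            if before.label == untouched_label:
                assert np.array_equal(after.image.pixels, before.image.pixels)

    def test_order_and_labels_unchanged(self, rng):
        ds = _mini_dataset(rng)
        out = inject_shortcut(ds, "positive", AdaSpec.default("C", seed=2))
        assert [it.image.id for it in out.items] == [it.image.id for it in ds.items]
        assert np.array_equal(out.labels, ds.labels)

    def test_invalid_target_rejected(self, rng):
        with pytest.raises(ValueError, match="target"):
            inject_shortcut(_mini_dataset(rng), "both", AdaSpec.default("C"))


class TestSplitTrainVal:
    def test_stratified_sizes_and_both_labels(self, rng):
        ds = _mini_dataset(rng, n_pos=50, n_neg=50)
        train, val = split_train_val(ds, 0.2, seed=1)
        assert len(train) == 80 and len(val) == 20
        for part in (train, val):
            assert part.n_label(0) > 0 and part.n_label(1) > 0
        # disjoint and exhaustive
        ids = {it.image.id for it in train.items} | {it.image.id for it in val.items}
        assert len(ids) == 100

    def test_patients_never_straddle_the_split(self, rng):
        patients = [f"pt{i // 3}" for i in range(30)]  # 3 images per patient
        ds = _mini_dataset(rng, n_pos=15, n_neg=15, patients=patients)
        train, val = split_train_val(ds, 0.3, seed=2)
        train_p = {it.patient_id for it in train.items}
        val_p = {it.patient_id for it in val.items}
        assert not (train_p & val_p)

    def test_one_patient_holding_all_positives_errors(self, rng):
        patients = ["pos-pt"] * 6 + [f"neg{i}" for i in range(6)]
        ds = _mini_dataset(rng, n_pos=6, n_neg=6, patients=patients)
        with pytest.raises(ValueError, match="impossible|both labels"):
            split_train_val(ds, 0.3, seed=3)

    def test_different_seeds_give_different_partitions(self, rng):
        ds = _mini_dataset(rng, n_pos=50, n_neg=50)
        differing = 0
        for s in range(20):
            _, val_a = split_train_val(ds, 0.2, seed=2 * s)
            _, val_b = split_train_val(ds, 0.2, seed=2 * s + 1)
            ids_a = {it.image.id for it in val_a.items}
            ids_b = {it.image.id for it in val_b.items}
            differing += ids_a != ids_b
        assert differing >= 19  # ~always distinct at n=100

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(ValueError, match="val_fraction"):
            split_train_val(_mini_dataset(rng), 1.5, seed=0)


class TestPersistence:
    def test_save_load_round_trip_with_provenance(self, rng, tmp_path):
        pool = _mini_pool(rng, 10)
        spec = AdaSpec.default("C", seed=4)
        ds = build_detective_trainset(pool, spec, seed=5)
        save_dataset(ds, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert len(back) == len(ds)
        orig = {it.image.id: it for it in ds.items}
        for it in back.items:
            assert np.array_equal(it.image.pixels, orig[it.image.id].image.pixels)
            assert it.label == orig[it.image.id].label
        assert back.provenance["ada_spec"] == spec.to_config()

    def test_missing_manifest_errors(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError, match="manifest"):
            load_dataset(tmp_path / "empty")
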