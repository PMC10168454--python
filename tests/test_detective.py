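"""Detective ensembles: registry, training, scoring, persistence."""

import numpy as np
import pytest

from shortcutscope import (AdaSpec, DetectiveConfig, Image8,
                           build_detective_trainset, compute_auc,
                           generate_labeled_cohorts, load_ensemble,
                           predict_scores, registry_get, registry_names,
                           save_ensemble, train_detective)
from shortcutscope.detective import DetectiveEnsemble, LogisticHead, SmallCnnFeatures
from shortcutscope.synth import PhantomParams


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError, match="ensemble_size"):
            DetectiveConfig(ensemble_size=0)
        with pytest.raises(ValueError, match="epochs"):
            DetectiveConfig(epochs=0)
        with pytest.raises(ValueError, match="val_fraction"):
            DetectiveConfig(val_fraction=0.0)


class TestRegistry:
    def test_default_and_heavyweight_entries_present(self):
        names = registry_names()
        assert "small-cnn" in names
        assert "densenet-121" in names

    def test_unknown_name_lists_registered(self):
        with pytest.raises(KeyError, match="small-cnn"):
            registry_get("no-such-net")

    def test_small_cnn_constructor_builds_extractor(self):
        ctor = registry_get("small-cnn")
        extractor = ctor(seed=1, image_side=64)
        assert extractor.n_features > 0

    def test_heavyweight_constructor_raises_with_backend_message(self):
        with pytest.raises(RuntimeError, match="backend"):
            registry_get("densenet-121")()


def _constant_head(p, n_features):
    """A head that outputs probability p for every image."""
    logit = np.log(p / (1 - p))
    return LogisticHead(w=np.zeros(n_features), b=logit,
                        mean=np.zeros(n_features), std=np.ones(n_features))


def _constant_ensemble(probs, image_side=16):
    extractor = SmallCnnFeatures(seed=0, image_side=image_side)
    cfg = DetectiveConfig(ensemble_size=len(probs), image_side=image_side)
    from shortcutscope.perturb import AdaKind
    return DetectiveEnsemble(
        members=tuple(_constant_head(p, extractor.n_features) for p in probs),
        ada_kind=AdaKind.S, config=cfg, train_fingerprint="synthetic",
        extractor=extractor,
    )


class TestPredictScores:
    def test_score_is_mean_of_member_probabilities(self, random_images):
        ens = _constant_ensemble([0.2, 0.6])
        scores = predict_scores(ens, random_images[:4])
        assert np.allclose(scores, 0.4)

    def test_single_member_passthrough(self, random_images):
        ens = _constant_ensemble([0.3])
        assert np.allclose(predict_scores(ens, random_images[:3]), 0.3)

    def test_empty_input_gives_empty_output(self):
        ens = _constant_ensemble([0.5])
        assert predict_scores(ens, []).shape == (0,)

    def test_permuting_input_permutes_output(self, small_pool):
        cfg = DetectiveConfig(ensemble_size=1, image_side=64, epochs=2, seed=3)
        spec = AdaSpec.default("C", seed=1)
        ds = build_detective_trainset(small_pool[:60], spec, seed=2)
        ens = train_detective(ds, cfg)
        imgs = small_pool[60:80]
        perm = np.random.default_rng(0).permutation(len(imgs))
        base = predict_scores(ens, imgs)
        shuffled = predict_scores(ens, [imgs[i] for i in perm])
        assert np.allclose(shuffled, base[perm])

    def test_invariant_to_batch_partitioning(self, small_pool):
        ens = _constant_ensemble([0.2, 0.9], image_side=64)
        imgs = small_pool[:30]
        whole = predict_scores(ens, imgs)
        parts = np.concatenate([predict_scores(ens, imgs[:7]),
                                predict_scores(ens, imgs[7:])])
        assert np.allclose(whole, parts)


@pytest.fixture(scope="module")
def trainset(small_pool):
    spec = AdaSpec.default("S", seed=21)
    return build_detective_trainset(small_pool, spec, seed=22)


class TestTraining:

    def test_learns_the_planted_sharpness_attribute(self, trainset):
        cfg = DetectiveConfig(ensemble_size=2, image_side=64, epochs=5, seed=23)
        ens = train_detective(trainset, cfg)
        # held-out exam: fresh phantoms, same perturbation recipe on class 1
        spec = AdaSpec.from_config(trainset.provenance["ada_spec"])
        cohort = generate_labeled_cohorts(
            60, 60, PhantomParams(side=64, seed=99), shortcut=(spec, "positive"))
        auc = compute_auc(predict_scores(ens, cohort.images), cohort.labels)
        assert auc >= 0.95

    def test_zero_strength_trainset_yields_chance_auc(self, small_pool):
        spec = AdaSpec(kind="S", strength_low=0.0, strength_high=0.0, seed=31)
        ds = build_detective_trainset(small_pool, spec, seed=32)
        cfg = DetectiveConfig(ensemble_size=2, image_side=64, epochs=5, seed=33)
        ens = train_detective(ds, cfg)
        cohort = generate_labeled_cohorts(100, 100, PhantomParams(side=64, seed=55))
        auc = compute_auc(predict_scores(ens, cohort.images), cohort.labels)
        assert 0.4 <= auc <= 0.6

    def test_training_is_reproducible(self, trainset, small_pool):
        cfg = DetectiveConfig(ensemble_size=2, image_side=64, epochs=3, seed=44)
        a = train_detective(trainset, cfg)
        b = train_detective(trainset, cfg)
        probe = small_pool[:10]
        assert np.array_equal(predict_scores(a, probe), predict_scores(b, probe))
        assert a.train_fingerprint == b.train_fingerprint

    def test_degenerate_dataset_rejected(self, small_pool):
        from shortcutscope import DatasetItem, LabeledDataset
        ds = LabeledDataset(items=tuple(
            DatasetItem(img, 1) for img in small_pool[:10]), name="one-class")
        with pytest.raises(ValueError, match="both labels"):
            train_detective(ds, DetectiveConfig(ensemble_size=1),
                            ada_kind="S")

    def test_missing_ada_kind_without_provenance_rejected(self, small_pool):
        from shortcutscope import DatasetItem, LabeledDataset
        ds = LabeledDataset(items=tuple(
            DatasetItem(img, i % 2) for i, img in enumerate(small_pool[:10])),
            name="anon")
        with pytest.raises(ValueError, match="ada_kind"):
            train_detective(ds, DetectiveConfig(ensemble_size=1))


class TestPersistence:
    def test_save_load_round_trip_preserves_scores(self, small_pool, tmp_path):
        spec = AdaSpec.default("C", seed=61)
        ds = build_detective_trainset(small_pool[:80], spec, seed=62)
        cfg = DetectiveConfig(ensemble_size=2, image_side=64, epochs=2, seed=63)
        ens = train_detective(ds, cfg)
        save_ensemble(ens, tmp_path / "run")
        back = load_ensemble(tmp_path / "run")
        probe = small_pool[80:90]
        assert np.array_equal(predict_scores(ens, probe),
                              predict_scores(back, probe))
        assert back.train_fingerprint == ens.train_fingerprint
        assert back.ada_kind == ens.ada_kind

    def test_tampered_checkpoint_fails_verification(self, small_pool, tmp_path):
        spec = AdaSpec.default("C", seed=71)
        ds = build_detective_trainset(small_pool[:40], spec, seed=72)
        cfg = DetectiveConfig(ensemble_size=1, image_side=64, epochs=1, seed=73)
        save_ensemble(train_detective(ds, cfg), tmp_path / "run")
        ckpt = tmp_path / "run" / "member_0.ckpt"
        ckpt.write_bytes(ckpt.read_bytes() + b"tamper")
        with pytest.raises(ValueError, match="fingerprint"):
            load_ensemble(tmp_path / "run")
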