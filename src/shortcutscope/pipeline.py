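"""End-to-end desk-scale workflow: build → train → certify → detect.

Bundles the module chain into single calls so scripts, tests and the
CLI run the identical computation.  The desk-scale defaults (phantom
pool of 1200 images at 64x64, K=3 small-cnn members, 5 epochs, a
300+300 shortcut-free exam cohort) trade the full-scale study's tens of
thousands of radiographs for a run that completes in about a minute on
one CPU while exercising every stage of the framework.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seeds import derive_seed
from .audit import CertificationReport, Thresholds, certify
from .detective import DetectiveConfig, DetectiveEnsemble, train_detective
from .forge import LabeledDataset, build_detective_trainset
from .perturb import AdaKind, AdaSpec
from .synth import PhantomParams, generate_labeled_cohorts, generate_pool

__all__ = ["DeskRun", "run_desk_certification"]

DESK_POOL_SIZE = 1200
DESK_COHORT_SIZE = 300  # per class
DESK_ENSEMBLE_SIZE = 3
DESK_EPOCHS = 5


@dataclass(frozen=True)
class DeskRun:
    """Everything one desk-scale certification run produced."""

    ensemble: DetectiveEnsemble
    trainset: LabeledDataset
    exam_cohort: LabeledDataset
    report: CertificationReport


def run_desk_certification(kind: AdaKind | str, seed: int, *,
                           pool_size: int = DESK_POOL_SIZE,
                           cohort_size: int = DESK_COHORT_SIZE,
                           image_side: int = 64,
                           ensemble_size: int = DESK_ENSEMBLE_SIZE,
                           epochs: int = DESK_EPOCHS,
                           thresholds: Thresholds = Thresholds(),
                           n_boot: int = 2000) -> DeskRun:
    """Train and certify one detective on synthetic phantoms.

    Builds a finding-free phantom pool, constructs the 50/50 detective
    trainset with the default perturbation recipe for ``kind``, trains a
    small-cnn ensemble, then certifies it against a fresh shortcut-free
    phantom cohort (the two exams inject the same recipe into one class
    at a time).  Fully reproducible from ``seed``.
    """
    kind = AdaKind(kind)
    spec = AdaSpec.default(kind, seed=derive_seed(seed, "ada", kind.value))
    pool = generate_pool(
        pool_size,
        PhantomParams(side=image_side, seed=derive_seed(seed, "pool", kind.value)),
    )
    trainset = build_detective_trainset(
        pool, spec, seed=derive_seed(seed, "trainset", kind.value),
        name=f"phantom-trainset-{kind.value}",
    )
    config = DetectiveConfig(
        arch="small-cnn",
        ensemble_size=ensemble_size,
        image_side=image_side,
        epochs=epochs,
        seed=derive_seed(seed, "detective", kind.value),
    )
    ensemble = train_detective(trainset, config)
    exam_cohort = generate_labeled_cohorts(
        cohort_size, cohort_size,
        PhantomParams(side=image_side, seed=derive_seed(seed, "cohort", kind.value)),
        name=f"phantom-shortcut-free-{kind.value}",
    )
    report = certify(
        ensemble, exam_cohort, spec, thresholds,
        n_boot=n_boot, seed=derive_seed(seed, "certify", kind.value),
    )
    return DeskRun(ensemble=ensemble, trainset=trainset,
                   exam_cohort=exam_cohort, report=report)
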