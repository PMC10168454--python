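"""Certification exams and deployment of shortcut detectives.

A trained detective is only trustworthy after a two-part examination on
a dataset known to be free of the shortcut it hunts:

* **Exam 1** — scored on the shortcut-free dataset as-is, the detective
  must sit at chance (AUC close to 0.5).  This proves its features are
  not entangled with the dataset's genuine labeling task.
* **Exam 2a / 2b** — with its own perturbation injected into the
  positive (2a) or negative (2b) class, it must reach AUC close to 1
  (2a) or, symmetrically, close to 0 (2b).  An AUC of 0 is perfect
  separation with the class assignment inverted.

A certified detective is then deployed on curated datasets: an AUC that
deviates materially from 0.5 — beyond a margin and with the 95%
bootstrap CI excluding 0.5 — flags the corresponding shortcut.  The
default thresholds (chance band ±0.10, perfection band 0.05, detection
margin 0.10) are the simple values consistent with published audit
verdicts: a detective passing Exam 1 at 0.56 is still certified, a
dataset scoring 0.56 is not yet flagged, and one scoring 0.84 or 0.37
is flagged on either side of 0.5.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

from ._seeds import derive_seed
from .aucstats import AucResult, bootstrap_auc_ci
from .detective import DetectiveEnsemble, predict_scores
from .forge import LabeledDataset, inject_shortcut
from .perturb import AdaSpec

__all__ = [
    "Thresholds",
    "CertificationReport",
    "DetectionReport",
    "certify",
    "detect",
    "audit_dataset",
    "decision_rule",
]

logger = logging.getLogger(__name__)

DEFAULT_DELTA_CHANCE = 0.10
DEFAULT_DELTA_PERFECT = 0.05
DEFAULT_MARGIN = 0.10


@dataclass(frozen=True)
class Thresholds:
    """Certification bands: chance tolerance and perfection tolerance."""

    delta_chance: float = DEFAULT_DELTA_CHANCE
    delta_perfect: float = DEFAULT_DELTA_PERFECT

    def __post_init__(self) -> None:
        if not 0 < self.delta_chance < 0.5:
            raise ValueError("delta_chance must be in (0, 0.5)")
        if not 0 < self.delta_perfect < 0.5:
            raise ValueError("delta_perfect must be in (0, 0.5)")


@dataclass(frozen=True)
class CertificationReport:
    ada_kind: str
    exam1: AucResult
    exam2a: AucResult
    exam2b: AucResult
    thresholds: Thresholds
    passed: bool
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "ada_kind": self.ada_kind,
            "exam1": self.exam1.to_json(),
            "exam2a": self.exam2a.to_json(),
            "exam2b": self.exam2b.to_json(),
            "thresholds": {
                "delta_chance": self.thresholds.delta_chance,
                "delta_perfect": self.thresholds.delta_perfect,
            },
            "passed": self.passed,
            "provenance": self.provenance,
        }

    def summary(self) -> str:
        verdict = "CERTIFIED" if self.passed else "NOT certified"
        return (
            f"ADA({self.ada_kind}) detective — {verdict}\n"
            f"  Exam 1 (shortcut-free):      {self.exam1}\n"
            f"  Exam 2a (injected positive): {self.exam2a}\n"
            f"  Exam 2b (injected negative): {self.exam2b}"
        )


@dataclass(frozen=True)
class DetectionReport:
    dataset_name: str
    ada_kind: str
    result: AucResult
    margin: float
    flagged: bool
    certified: bool

    def __post_init__(self) -> None:
        if self.flagged and not self.certified:
            raise ValueError(
                "only certified detectives may flag a shortcut; advisory "
                "reports must have flagged=False"
            )

    def to_json(self) -> dict:
        return {
            "dataset_name": self.dataset_name,
            "ada_kind": self.ada_kind,
            "result": self.result.to_json(),
            "margin": self.margin,
            "flagged": self.flagged,
            "certified": self.certified,
        }

    def summary(self) -> str:
        status = "SHORTCUT FLAGGED" if self.flagged else "no shortcut flagged"
        advisory = "" if self.certified else " [advisory: detective uncertified]"
        return (f"{self.dataset_name}: ADA({self.ada_kind}) {self.result} "
                f"-> {status}{advisory}")


def decision_rule(auc: float, ci_low: float, ci_high: float,
                  margin: float = DEFAULT_MARGIN) -> bool:
    """The deployment flagging rule, as a pure function of printed numbers.

    Flag iff the AUC deviates from 0.5 by at least ``margin`` (either
    side — an AUC of 0.1 is as damning as 0.9) *and* the 95% CI excludes
    0.5.
    """
    deviates = abs(auc - 0.5) >= margin
    ci_excludes = ci_low > 0.5 or ci_high < 0.5
    return bool(deviates and ci_excludes)


def certify(ensemble: DetectiveEnsemble, shortcut_free: LabeledDataset,
            spec: AdaSpec, thresholds: Thresholds = Thresholds(), *,
            level: float = 0.95, n_boot: int = 2000, seed: int = 0
            ) -> CertificationReport:
    """Run the two-exam certification protocol.

    Exam 1 scores ``shortcut_free`` as-is; Exams 2a/2b score it with
    ``spec`` injected into the positive / negative class.  The detective
    passes iff Exam 1 sits within ``delta_chance`` of 0.5, Exam 2a
    reaches ``1 - delta_perfect`` and Exam 2b stays below
    ``delta_perfect``.
    """
    shortcut_free.require_both_labels()
    if spec.kind is not ensemble.ada_kind:
        raise ValueError(
            f"spec kind {spec.kind.value!r} does not match detective kind "
            f"{ensemble.ada_kind.value!r}"
        )
    labels = shortcut_free.labels
    exams = {}
    for tag, ds in (
        ("exam1", shortcut_free),
        ("exam2a", inject_shortcut(shortcut_free, "positive", spec)),
        ("exam2b", inject_shortcut(shortcut_free, "negative", spec)),
    ):
        scores = predict_scores(ensemble, ds.images)
        exams[tag] = bootstrap_auc_ci(
            scores, labels, level=level, n_boot=n_boot,
            seed=derive_seed(seed, "certify", tag),
        )
    passed = (
        abs(exams["exam1"].auc - 0.5) <= thresholds.delta_chance
        and exams["exam2a"].auc >= 1.0 - thresholds.delta_perfect
        and exams["exam2b"].auc <= thresholds.delta_perfect
    )
    return CertificationReport(
        ada_kind=ensemble.ada_kind.value,
        exam1=exams["exam1"],
        exam2a=exams["exam2a"],
        exam2b=exams["exam2b"],
        thresholds=thresholds,
        passed=passed,
        provenance={
            "ada_spec": spec.to_config(),
            "train_fingerprint": ensemble.train_fingerprint,
            "detective_config": ensemble.config.to_json(),
            "exam_dataset": shortcut_free.name,
        },
    )


def detect(ensemble: DetectiveEnsemble, dataset: LabeledDataset,
           margin: float = DEFAULT_MARGIN, *, certified: bool = True,
           level: float = 0.95, n_boot: int = 2000, seed: int = 0
           ) -> DetectionReport:
    """Audit one dataset with one detective.

    ``certified=False`` produces an advisory report that never flags.
    """
    dataset.require_both_labels()
    scores = predict_scores(ensemble, dataset.images)
    result = bootstrap_auc_ci(scores, dataset.labels, level=level,
                              n_boot=n_boot,
                              seed=derive_seed(seed, "detect", dataset.name))
    flagged = certified and decision_rule(result.auc, result.ci_low,
                                          result.ci_high, margin)
    return DetectionReport(
        dataset_name=dataset.name,
        ada_kind=ensemble.ada_kind.value,
        result=result,
        margin=margin,
        flagged=flagged,
        certified=certified,
    )


def audit_dataset(dataset: LabeledDataset,
                  detectives: Sequence[tuple[DetectiveEnsemble, bool]],
                  margin: float = DEFAULT_MARGIN, *,
                  level: float = 0.95, n_boot: int = 2000, seed: int = 0
                  ) -> list[DetectionReport]:
    """One detection report per certified detective.

    ``detectives`` pairs each ensemble with its certification verdict;
    uncertified entries are excluded with a warning.  Raises if none
    remain.
    """
    usable = []
    for ens, cert in detectives:
        if cert:
            usable.append(ens)
        else:
            logger.warning(
                "excluding uncertified ADA(%s) detective from audit of %r; "
                "certify it first", ens.ada_kind.value, dataset.name)
    if not usable:
        raise ValueError(
            "no certified detectives available; run certification before "
            "auditing"
        )
    return [
        detect(ens, dataset, margin, certified=True, level=level,
               n_boot=n_boot, seed=seed)
        for ens in usable
    ]
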