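"""AUC and bootstrap confidence intervals — the framework's readout.

The area under the ROC curve is computed in its Mann–Whitney form: the
probability that a randomly chosen positive scores above a randomly
chosen negative, with ties counted half,

    AUC = (1 / (n_pos * n_neg)) * sum over (pos, neg) pairs of
          [ 1 if s_pos > s_neg ; 1/2 if equal ; 0 otherwise ].

Confidence intervals use the stratified percentile bootstrap: positives
and negatives are resampled separately (preserving class counts, so no
replicate degenerates to a single class), the AUC is recomputed for each
replicate, and the interval is read off the empirical quantiles.  The
defaults — 95% level, 2000 replicates, stratified — match the behavior
of pROC's ci.auc.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["AucResult", "compute_auc", "bootstrap_auc_ci", "auc_flip"]

DEFAULT_LEVEL = 0.95
DEFAULT_N_BOOT = 2000


@dataclass(frozen=True)
class AucResult:
    """Point AUC with a bootstrap percentile confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    level: float = DEFAULT_LEVEL
    n_boot: int = DEFAULT_N_BOOT
    n_pos: int = 0
    n_neg: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must be <= ci_high")

    def to_json(self) -> dict:
        return {
            "auc": self.auc,
            "ci": [self.ci_low, self.ci_high],
            "level": self.level,
            "n_boot": self.n_boot,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "seed": self.seed,
        }

    def __str__(self) -> str:  # presentation: 2 decimals, pROC-table style
        return f"{self.auc:.2f} [{self.ci_low:.2f}, {self.ci_high:.2f}]"


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError(
            f"scores and labels must be equal-length 1-D sequences, got "
            f"{scores.shape} vs {labels.shape}"
        )
    uniq = set(np.unique(labels).tolist())
    if not uniq.issubset({0, 1}):
        raise ValueError(f"labels must be 0/1, got values {sorted(uniq)}")
    if uniq != {0, 1}:
        raise ValueError("AUC needs both classes present in labels")
    return scores, labels.astype(np.int64)


def compute_auc(scores, labels) -> float:
    """Mann–Whitney AUC with half-credit ties.

    Equivalent to the trapezoidal area under the empirical ROC curve.
    """
    scores, labels = _validate(scores, labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # average ranks give the half-credit tie rule
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_rows(pos_scores: np.ndarray, neg_scores: np.ndarray) -> np.ndarray:
    """Row-wise AUC for stacked resamples (rows = bootstrap replicates)."""
    n_pos = pos_scores.shape[1]
    n_neg = neg_scores.shape[1]
    both = np.concatenate([pos_scores, neg_scores], axis=1)
    ranks = rankdata(both, axis=1)
    u = ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def bootstrap_auc_ci(scores, labels, *, level: float = DEFAULT_LEVEL,
                     n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> AucResult:
    """Stratified percentile bootstrap CI for the AUC.

    Positives and negatives are resampled with replacement separately,
    preserving ``n_pos`` and ``n_neg`` in every replicate; the interval
    is the ``(1-level)/2`` and ``1-(1-level)/2`` empirical quantiles of
    the replicate AUCs.  Deterministic given ``seed``.
    """
    scores, labels = _validate(scores, labels)
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    rng = np.random.default_rng(seed)
    pos_idx = rng.integers(0, n_pos, size=(n_boot, n_pos))
    neg_idx = rng.integers(0, n_neg, size=(n_boot, n_neg))
    boots = _auc_rows(pos_scores[pos_idx], neg_scores[neg_idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return AucResult(
        auc=compute_auc(scores, labels),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        n_boot=n_boot,
        n_pos=n_pos,
        n_neg=n_neg,
        seed=seed,
    )


def auc_flip(result):
    """Complement an AUC under label inversion: a -> 1 - a.

    Accepts a float or an :class:`AucResult`; CI bounds swap and flip.
    The identity behind reading an AUC of 0.0 as perfect separation with
    inverted class assignment.
    """
    if isinstance(result, AucResult):
        return AucResult(
            auc=1.0 - result.auc,
            ci_low=1.0 - result.ci_high,
            ci_high=1.0 - result.ci_low,
            level=result.level,
            n_boot=result.n_boot,
            n_pos=result.n_neg,
            n_neg=result.n_pos,
            seed=result.seed,
        )
    value = float(result)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {value}")
    return 1.0 - value
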