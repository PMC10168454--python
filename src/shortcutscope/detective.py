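"""Shortcut-detective ensembles: small CPU-scale binary classifiers.

A detective scores the probability that an image belongs to class 1 of
its training construction — i.e. that it carries the perturbed
acquisition attribute.  Following the framework's ensembling scheme, a
detective is an ensemble of individually trained members that differ by
their train/validation split; the ensemble score is the arithmetic mean
of member probabilities.

The default architecture, ``small-cnn``, is a compact convolutional
network sized for CPUs: three 3x3 convolution blocks with fixed,
seed-drawn filter banks (ReLU, 2x2 average pooling), global mean/std
pooling over channels, and a logistic read-out head trained by minibatch
Adam on binary cross-entropy.  Freezing the convolutional filters at
seeded random values is the random-feature trick: only the head is
fitted, which keeps training deterministic, fast and dependency-light
while the filter bank still exposes the band-pass statistics a contrast
or sharpness perturbation shifts.  The member checkpoint with the best
validation AUC across epochs is kept.

ImageNet-scale architectures (VGG-16, DenseNet-121, EfficientNet, Swin
Transformer, ConvNeXt) are declared in the registry for completeness;
building them requires a deep-learning backend and is outside this
package's CPU scope, so their constructors raise with a clear message.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._seeds import derive_rng, derive_seed
from .aucstats import compute_auc
from .forge import LabeledDataset, split_train_val
from .imagekit import Image8, resize
from .perturb import AdaKind

__all__ = [
    "DetectiveConfig",
    "DetectiveEnsemble",
    "train_detective",
    "predict_scores",
    "registry_get",
    "registry_names",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class DetectiveConfig:
    """Training configuration for one detective ensemble.

    Defaults are desk-scale: 64x64 inputs and the ``small-cnn``
    architecture train an ensemble in seconds to minutes on one CPU.
    ``image_side=224`` with a heavyweight architecture is the
    full-fidelity analog and requires a deep-learning backend.
    """

    arch: str = "small-cnn"
    ensemble_size: int = 5
    image_side: int = 64
    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError(f"ensemble_size must be >= 1, got {self.ensemble_size}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")

    def to_json(self) -> dict:
        return {
            "arch": self.arch, "ensemble_size": self.ensemble_size,
            "image_side": self.image_side, "epochs": self.epochs,
            "batch_size": self.batch_size, "learning_rate": self.learning_rate,
            "val_fraction": self.val_fraction, "seed": self.seed,
        }

    @classmethod
    def from_json(cls, block: dict) -> "DetectiveConfig":
        return cls(**block)


# ---------------------------------------------------------------------------
# small-cnn: fixed random convolutional features + trained logistic head
# ---------------------------------------------------------------------------

def _conv3x3(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Batched 3x3 convolution with reflect padding.

    x: (N, C, H, W); filt: (O, C, 3, 3) -> (N, O, H, W).
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3)
    return np.einsum("nchwij,ocij->nohw", win, filt, optimize=True)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))


class SmallCnnFeatures:
    """Three fixed conv blocks (seeded random filters) + global pooling.

    The filter bank is drawn once from the seed and never trained; the
    image statistics it pools (per-channel spatial mean and standard
    deviation, plus the raw image's own mean/std) are the features the
    logistic head learns on.
    """

    CHANNELS = (8, 16, 32)

    def __init__(self, seed: int, image_side: int) -> None:
        self.seed = int(seed)
        self.image_side = int(image_side)
        rng = np.random.default_rng(derive_seed(seed, "small-cnn-filters"))
        chans = (1,) + self.CHANNELS
        self.filters = []
        for c_in, c_out in zip(chans[:-1], chans[1:]):
            scale = 1.0 / np.sqrt(9 * c_in)
            self.filters.append(
                rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)).astype(np.float32)
            )

    @property
    def n_features(self) -> int:
        return 2 * self.CHANNELS[-1] + 2

    def __call__(self, pixels: np.ndarray, chunk: int = 256) -> np.ndarray:
        """pixels: (N, H, W) uint8 -> features (N, n_features) float64."""
        out = []
        for start in range(0, len(pixels), chunk):
            out.append(self._forward(pixels[start:start + chunk]))
        return np.concatenate(out, axis=0)

    def _forward(self, pixels: np.ndarray) -> np.ndarray:
        x = pixels.astype(np.float32)[:, None, :, :] / 255.0
        raw_mean = x.mean(axis=(1, 2, 3))
        raw_std = x.std(axis=(1, 2, 3))
        for filt in self.filters:
            x = np.maximum(_conv3x3(x, filt), 0.0)
            x = _avgpool2(x)
        feats = np.concatenate(
            [
                x.mean(axis=(2, 3)),
                x.std(axis=(2, 3)),
                raw_mean[:, None],
                raw_std[:, None],
            ],
            axis=1,
        )
        return feats.astype(np.float64)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LogisticHead:
    """Logistic regression head trained by minibatch Adam on BCE.

    Features are standardized with statistics of the member's own train
    split; the epoch checkpoint with the best validation AUC is kept.
    """

    w: np.ndarray
    b: float
    mean: np.ndarray
    std: np.ndarray
    val_auc: float = float("nan")

    def predict_proba(self, feats: np.ndarray) -> np.ndarray:
        z = (feats - self.mean) / self.std
        return _sigmoid(z @ self.w + self.b)

    @classmethod
    def fit(cls, feats: np.ndarray, labels: np.ndarray,
            val_feats: np.ndarray, val_labels: np.ndarray, *,
            epochs: int, batch_size: int, learning_rate: float,
            seed: int) -> "LogisticHead":
        mean = feats.mean(axis=0)
        std = feats.std(axis=0)
        std[std == 0] = 1.0
        x = (feats - mean) / std
        y = labels.astype(np.float64)
        rng = np.random.default_rng(seed)
        d = x.shape[1]
        w = rng.normal(0.0, 0.01, size=d)
        b = 0.0
        # Adam state
        mw = np.zeros(d); vw = np.zeros(d); mb = 0.0; vb = 0.0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best = (w.copy(), b, -np.inf)
        xv = (val_feats - mean) / std
        for _ in range(epochs):
            order = rng.permutation(len(x))
            for start in range(0, len(x), batch_size):
                idx = order[start:start + batch_size]
                xb, yb = x[idx], y[idx]
                p = _sigmoid(xb @ w + b)
                err = p - yb
                gw = xb.T @ err / len(idx)
                gb = err.mean()
                t += 1
                mw = beta1 * mw + (1 - beta1) * gw
                vw = beta2 * vw + (1 - beta2) * gw ** 2
                mb = beta1 * mb + (1 - beta1) * gb
                vb = beta2 * vb + (1 - beta2) * gb ** 2
                w -= learning_rate * (mw / (1 - beta1 ** t)) / (
                    np.sqrt(vw / (1 - beta2 ** t)) + eps)
                b -= learning_rate * (mb / (1 - beta1 ** t)) / (
                    np.sqrt(vb / (1 - beta2 ** t)) + eps)
            val_auc = compute_auc(_sigmoid(xv @ w + b), val_labels)
            if val_auc > best[2]:
                best = (w.copy(), b, val_auc)
        w, b, val_auc = best
        return cls(w=w, b=b, mean=mean, std=std, val_auc=val_auc)


# ---------------------------------------------------------------------------
# architecture registry
# ---------------------------------------------------------------------------

def _heavyweight(name: str) -> Callable:
    def ctor(*_args, **_kwargs):
        raise RuntimeError(
            f"architecture {name!r} is registered for completeness but needs "
            "a deep-learning backend and GPU-scale training; use 'small-cnn' "
            "for CPU-scale runs"
        )
    ctor.__name__ = name.replace("-", "_")
    ctor.heavyweight = True
    return ctor


_REGISTRY: dict[str, Callable] = {
    "small-cnn": SmallCnnFeatures,
    "vgg-16": _heavyweight("vgg-16"),
    "densenet-121": _heavyweight("densenet-121"),
    "efficientnet": _heavyweight("efficientnet"),
    "swin-transformer": _heavyweight("swin-transformer"),
    "convnext": _heavyweight("convnext"),
}


def registry_names() -> list[str]:
    return sorted(_REGISTRY)


def registry_get(arch_name: str) -> Callable:
    """Constructor for a registered architecture.

    Unknown names raise a ``KeyError`` listing what is registered.
    """
    try:
        return _REGISTRY[arch_name]
    except KeyError:
        raise KeyError(
            f"unknown architecture {arch_name!r}; registered: "
            f"{', '.join(registry_names())}"
        ) from None


# ---------------------------------------------------------------------------
# ensemble training and scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectiveEnsemble:
    """K trained members sharing one feature extractor.

    ``train_fingerprint`` hashes the training pixels, labels and config,
    so a loaded ensemble can prove which data built it.
    """

    members: tuple[LogisticHead, ...]
    ada_kind: AdaKind
    config: DetectiveConfig
    train_fingerprint: str
    extractor: SmallCnnFeatures

    def __post_init__(self) -> None:
        if len(self.members) != self.config.ensemble_size:
            raise ValueError("member count must equal config.ensemble_size")

    @property
    def val_aucs(self) -> list[float]:
        return [m.val_auc for m in self.members]


def _fingerprint(dataset: LabeledDataset, config: DetectiveConfig) -> str:
    h = hashlib.blake2b(digest_size=16)
    for it in dataset.items:
        h.update(it.image.id.encode())
        h.update(bytes([it.label]))
        h.update(it.image.pixels.tobytes())
    h.update(json.dumps(config.to_json(), sort_keys=True).encode())
    if dataset.provenance:
        h.update(json.dumps(dataset.provenance, sort_keys=True).encode())
    return h.hexdigest()


def _resized_pixels(images: Sequence[Image8], side: int) -> np.ndarray:
    return np.stack([resize(img, side).pixels for img in images])


def train_detective(dataset: LabeledDataset, config: DetectiveConfig,
                    *, ada_kind: AdaKind | str | None = None) -> DetectiveEnsemble:
    """Train an ensemble of ``config.ensemble_size`` members.

    Each member gets its own stratified train/validation split derived
    from ``config.seed`` and the member index, minimizes binary
    cross-entropy, and keeps its best-validation-AUC epoch.  Images are
    resized to ``config.image_side`` before feature extraction.
    Reproducible bit-for-bit given identical inputs and seed.
    """
    dataset.require_both_labels()
    if ada_kind is None:
        prov = dataset.provenance or {}
        spec = prov.get("ada_spec") or prov.get("injected")
        if spec is None:
            raise ValueError(
                "ada_kind not given and dataset provenance does not record an "
                "AdaSpec; pass ada_kind='S' or 'C' explicitly"
            )
        ada_kind = spec["kind"]
    ada_kind = AdaKind(ada_kind)

    ctor = registry_get(config.arch)
    if getattr(ctor, "heavyweight", False):
        ctor()  # raises with the backend message
    extractor = ctor(seed=config.seed, image_side=config.image_side)

    pixels = _resized_pixels(dataset.images, config.image_side)
    feats = extractor(pixels)
    row_of = {it.image.id: i for i, it in enumerate(dataset.items)}

    members = []
    for k in range(config.ensemble_size):
        split_seed = derive_seed(config.seed, "member-split", k)
        train_ds, val_ds = split_train_val(dataset, config.val_fraction, split_seed)
        tr_idx = np.array([row_of[it.image.id] for it in train_ds.items])
        va_idx = np.array([row_of[it.image.id] for it in val_ds.items])
        head = LogisticHead.fit(
            feats[tr_idx], dataset.labels[tr_idx],
            feats[va_idx], dataset.labels[va_idx],
            epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=derive_seed(config.seed, "member-init", k),
        )
        members.append(head)

    return DetectiveEnsemble(
        members=tuple(members),
        ada_kind=ada_kind,
        config=config,
        train_fingerprint=_fingerprint(dataset, config),
        extractor=extractor,
    )


def predict_scores(ensemble: DetectiveEnsemble, images: Sequence[Image8]
                   ) -> np.ndarray:
    """Ensemble scores in [0, 1]: arithmetic mean of member probabilities.

    Order-preserving; an empty input yields an empty result.  Invariant
    to how the caller batches the list.
    """
    if len(images) == 0:
        return np.zeros(0, dtype=np.float64)
    pixels = _resized_pixels(images, ensemble.config.image_side)
    feats = ensemble.extractor(pixels)
    probs = np.stack([m.predict_proba(feats) for m in ensemble.members])
    return probs.mean(axis=0)


# ---------------------------------------------------------------------------
# persistence: <run>/member_<k>.ckpt + <run>/ensemble.json
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: DetectiveEnsemble, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    checksums = []
    for k, m in enumerate(ensemble.members):
        path = directory / f"member_{k}.ckpt"
        tmp = directory / f"member_{k}.ckpt.npz"
        np.savez(tmp, w=m.w, b=np.float64(m.b),
                 mean=m.mean, std=m.std, val_auc=np.float64(m.val_auc))
        tmp.rename(path)
        checksums.append(hashlib.sha256(path.read_bytes()).hexdigest())
    meta = {
        "arch": ensemble.config.arch,
        "image_side": ensemble.config.image_side,
        "ada_kind": ensemble.ada_kind.value,
        "train_fingerprint": ensemble.train_fingerprint,
        "extractor_seed": ensemble.extractor.seed,
        "config": ensemble.config.to_json(),
        "member_checksums": checksums,
        "val_aucs": ensemble.val_aucs,
    }
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_ensemble(directory: str | Path) -> DetectiveEnsemble:
    """Load a persisted ensemble; member checkpoints are checksum-verified."""
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    config = DetectiveConfig.from_json(meta["config"])
    members = []
    for k, expected in enumerate(meta["member_checksums"]):
        path = directory / f"member_{k}.ckpt"
        actual = hashlib.sha256(path.read_bytes()).hexdigest()
        if actual != expected:
            raise ValueError(
                f"checkpoint {path.name} fails fingerprint verification "
                f"(expected {expected[:12]}..., got {actual[:12]}...)"
            )
        with np.load(path) as z:
            members.append(LogisticHead(
                w=z["w"], b=float(z["b"]), mean=z["mean"], std=z["std"],
                val_auc=float(z["val_auc"]),
            ))
    extractor = SmallCnnFeatures(seed=meta["extractor_seed"],
                                 image_side=meta["image_side"])
    return DetectiveEnsemble(
        members=tuple(members),
        ada_kind=AdaKind(meta["ada_kind"]),
        config=config,
        train_fingerprint=meta["train_fingerprint"],
        extractor=extractor,
    )
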