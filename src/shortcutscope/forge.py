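"""Construct detective training sets and inject known shortcuts.

A shortcut detective must learn an acquisition attribute and nothing
else.  The construction guaranteeing this: take a pool of finding-free
images, split it at random into two equal halves, perturb one half with
the chosen attribute and label it 1, leave the other half untouched as
label 0.  Because the pool contains no disease signal, any classifier
separating the halves can only have learned the perturbed attribute.

The same injection machinery doubles as the exam paper generator for
certification: a known shortcut is planted into the positive (exam 2a)
or negative (exam 2b) class of a shortcut-free labeled dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_rng
from .imagekit import Image8, read_png, write_png
from .perturb import AdaSpec, apply_ada

__all__ = [
    "DatasetItem",
    "LabeledDataset",
    "build_detective_trainset",
    "inject_shortcut",
    "split_train_val",
    "save_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.csv"
SIDECAR_NAME = "ada_spec.json"


@dataclass(frozen=True)
class DatasetItem:
    image: Image8
    label: int
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class LabeledDataset:
    """Images with binary labels (and optional patient ids)."""

    items: tuple[DatasetItem, ...]
    name: str = ""
    provenance: dict | None = None  # e.g. the AdaSpec that built it

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.image.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate image ids in dataset {self.name!r}")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([it.label for it in self.items], dtype=np.int64)

    @property
    def images(self) -> list[Image8]:
        return [it.image for it in self.items]

    @property
    def patient_ids(self) -> list[str | None]:
        return [it.patient_id for it in self.items]

    def n_label(self, label: int) -> int:
        return int((self.labels == label).sum())

    def require_both_labels(self) -> None:
        if self.n_label(0) == 0 or self.n_label(1) == 0:
            raise ValueError(
                f"dataset {self.name!r} must contain both labels "
                f"(n0={self.n_label(0)}, n1={self.n_label(1)})"
            )

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            items=tuple(self.items[int(i)] for i in indices),
            name=self.name if name is None else name,
            provenance=self.provenance,
        )

    def with_flipped_labels(self) -> "LabeledDataset":
        return LabeledDataset(
            items=tuple(replace(it, label=1 - it.label) for it in self.items),
            name=self.name + "/flipped",
            provenance=self.provenance,
        )


def build_detective_trainset(pool: Sequence[Image8], spec: AdaSpec,
                             seed: int, *, name: str = "detective-trainset"
                             ) -> LabeledDataset:
    """Random 50/50 split of a finding-free pool; perturb one half.

    Exactly half the pool receives label 1 and the ADA perturbation of
    ``spec``; the other half keeps its pixels and gets label 0.  Odd
    pools drop one image at random (with a warning) rather than failing.
    Deterministic given ``(pool, spec, seed)``.
    """
    pool = list(pool)
    if len(pool) < 2:
        raise ValueError(f"pool must contain at least 2 images, got {len(pool)}")
    rng = derive_rng(seed, "trainset-split")
    order = rng.permutation(len(pool))
    if len(pool) % 2 == 1:
        dropped = pool[order[-1]]
        logger.warning("odd pool of %d: dropping image %r", len(pool), dropped.id)
        order = order[:-1]
    half = len(order) // 2
    pos_idx = set(int(i) for i in order[:half])
    kept = set(int(i) for i in order)
    items = []
    for i, img in enumerate(pool):
        if i not in kept:
            continue  # the dropped image
        if i in pos_idx:
            items.append(DatasetItem(image=apply_ada(img, spec), label=1))
        else:
            items.append(DatasetItem(image=img, label=0))
    return LabeledDataset(items=tuple(items), name=name,
                          provenance={"ada_spec": spec.to_config(), "seed": seed})


def inject_shortcut(dataset: LabeledDataset,
                    target: Literal["positive", "negative"],
                    spec: AdaSpec) -> LabeledDataset:
    """Perturb one class of a labeled dataset with a known shortcut.

    Images of the targeted label pass through :func:`~shortcutscope.perturb.apply_ada`;
    the other class is bit-identical to the input.  Labels and item order
    are unchanged.
    """
    if target not in ("positive", "negative"):
        raise ValueError(f"target must be 'positive' or 'negative', got {target!r}")
    tgt = 1 if target == "positive" else 0
    items = tuple(
        replace(it, image=apply_ada(it.image, spec)) if it.label == tgt else it
        for it in dataset.items
    )
    return LabeledDataset(
        items=items,
        name=f"{dataset.name}/+{spec.kind.value}({'+' if tgt == 1 else '-'})",
        provenance={"base": dataset.name, "injected": spec.to_config(),
                    "target": target},
    )


def _grouped_split(labels: np.ndarray, groups: np.ndarray, val_fraction: float,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Patient-disjoint split with both labels on both sides.

    Tries a number of seeded shuffles of whole patients; raises if no
    attempt satisfies the both-labels contract (e.g. one patient holds
    every positive).
    """
    uniq = np.unique(groups)
    n = len(labels)
    for attempt in range(200):
        rng = derive_rng(seed, "grouped-split", attempt)
        perm = rng.permutation(uniq)
        val_groups: set = set()
        count = 0
        for g in perm:
            if count >= val_fraction * n:
                break
            val_groups.add(g)
            count += int((groups == g).sum())
        val_mask = np.isin(groups, list(val_groups))
        if len(np.unique(labels[val_mask])) == 2 and len(np.unique(labels[~val_mask])) == 2:
            return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)
    raise ValueError(
        "cannot produce a patient-disjoint split with both labels on both "
        "sides; label distribution across patients makes it impossible"
    )


def _stratified_split(labels: np.ndarray, val_fraction: float, seed: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    rng = derive_rng(seed, "stratified-split")
    for lab in (0, 1):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        n_val = min(max(n_val, 1), len(idx) - 1)  # both labels on both sides
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def split_train_val(dataset: LabeledDataset, val_fraction: float, seed: int
                    ) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive train/validation partition.

    Grouped by patient when patient ids are present (no patient straddles
    the split); stratified by label otherwise.  Both parts must contain
    both labels, else an error is raised.
    """
    if not 0 < val_fraction < 1:
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    dataset.require_both_labels()
    labels = dataset.labels
    pids = dataset.patient_ids
    has_groups = any(p not in (None, "") for p in pids)
    if has_groups:
        groups = np.array([p if p not in (None, "") else f"__solo_{i}"
                           for i, p in enumerate(pids)])
        train_idx, val_idx = _grouped_split(labels, groups, val_fraction, seed)
    else:
        train_idx, val_idx = _stratified_split(labels, val_fraction, seed)
    train = dataset.subset(train_idx, name=dataset.name + "/train")
    val = dataset.subset(val_idx, name=dataset.name + "/val")
    for part in (train, val):
        part.require_both_labels()
    return train, val


def save_dataset(dataset: LabeledDataset, directory: str | Path) -> Path:
    """Persist as a directory of PNGs plus a ``path,label,patient_id`` manifest.

    The provenance block (e.g. the AdaSpec that built the dataset) is
    written alongside as a JSON sidecar.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for it in dataset.items:
        fname = f"{it.image.id}.png"
        write_png(it.image, directory / fname)
        rows.append({"path": fname, "label": it.label,
                     "patient_id": it.patient_id or ""})
    pd.DataFrame(rows, columns=["path", "label", "patient_id"]).to_csv(
        directory / MANIFEST_NAME, index=False)
    if dataset.provenance is not None:
        (directory / SIDECAR_NAME).write_text(
            json.dumps(dataset.provenance, indent=2))
    return directory


def load_dataset(directory: str | Path, *, name: str | None = None) -> LabeledDataset:
    """Load a directory persisted by :func:`save_dataset` (or hand-built)."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {directory}")
    df = pd.read_csv(manifest, dtype={"path": str, "patient_id": str},
                     keep_default_na=False)
    required = {"path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"malformed manifest {manifest}: needs columns {sorted(required)}")
    items = []
    for _, row in df.iterrows():
        label = int(row["label"])
        if label not in (0, 1):
            raise ValueError(f"manifest label must be 0/1, got {row['label']!r}")
        img = read_png(directory / row["path"])
        pid = str(row.get("patient_id", "") or "") or None
        items.append(DatasetItem(image=img, label=label, patient_id=pid))
    prov = None
    sidecar = directory / SIDECAR_NAME
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())
    return LabeledDataset(items=tuple(items),
                          name=directory.name if name is None else name,
                          provenance=prov)
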