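"""Chest-radiograph-like phantoms for fully self-contained experiments.

Real detective training uses tens of thousands of finding-free chest
radiographs; those archives are restricted and enormous.  For testing
and desk-scale certification this module renders geometric phantoms
that reproduce the *statistics* the framework cares about — a bright
mediastinal band, two darker elliptical lung fields, periodic rib
bands, mild blur and sensor noise, with per-image jitter of geometry
and exposure — without pretending to anatomical realism.  Because every
phantom is drawn from the same seeded generator, a cohort labeled at
random carries no image signal at all: the ideal shortcut-free baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from ._seeds import derive_rng, derive_seed
from .forge import DatasetItem, LabeledDataset, inject_shortcut
from .imagekit import Image8
from .perturb import AdaSpec

__all__ = [
    "PhantomParams",
    "generate_phantom",
    "generate_pool",
    "generate_labeled_cohorts",
]

MIN_PHANTOM_SIDE = 32


@dataclass(frozen=True)
class PhantomParams:
    """Rendering parameters for one phantom family.

    side
        Square image size in pixels (64 for tests, 224 for fidelity runs).
    lung_contrast
        Intensity drop of the lung fields below soft tissue, in 8-bit units.
    rib_count
        Number of horizontal sinusoidal rib bands across a lung field.
    noise_sigma
        Std of additive Gaussian sensor noise, 8-bit units.
    blur_sigma
        Gaussian system blur, pixels.
    seed
        Master seed; per-image geometry jitter fans out from it.
    """

    side: int = 64
    lung_contrast: float = 80.0
    rib_count: int = 5
    noise_sigma: float = 6.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < MIN_PHANTOM_SIDE:
            raise ValueError(f"side must be >= {MIN_PHANTOM_SIDE}, got {self.side}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.rib_count < 0:
            raise ValueError("rib_count must be >= 0")


# base intensities, 8-bit units (bright = dense)
_AIR = 25.0
_SOFT_TISSUE = 170.0
_MEDIASTINUM = 215.0
_RIB_AMPLITUDE = 22.0


def generate_phantom(params: PhantomParams, *, id: str | None = None) -> Image8:
    """Render one phantom, deterministic given ``params.seed``.

    Geometry (ellipse centers and axes, exposure) is jittered per image
    from the seed; with ``noise_sigma = blur_sigma = 0`` and
    ``rib_count = 0`` the output is piecewise-constant geometry.
    """
    rng = derive_rng(params.seed, "phantom")
    s = params.side
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    u = (xx + 0.5) / s  # normalized coords in (0, 1)
    v = (yy + 0.5) / s

    exposure = rng.normal(0.0, 5.0)  # per-image global exposure jitter
    canvas = np.full((s, s), _AIR, dtype=np.float64)

    # torso: broad bright ellipse filling most of the frame
    torso_w = 0.44 * (1 + rng.normal(0, 0.03))
    torso_h = 0.52 * (1 + rng.normal(0, 0.03))
    torso = ((u - 0.5) / torso_w) ** 2 + ((v - 0.52) / torso_h) ** 2 <= 1.0
    canvas[torso] = _SOFT_TISSUE

    # mediastinum: bright central vertical band inside the torso
    med_w = 0.09 * (1 + rng.normal(0, 0.05))
    med = torso & (np.abs(u - 0.5 + rng.normal(0, 0.01)) <= med_w)
    canvas[med] = _MEDIASTINUM

    # two darker lung fields
    lung_mask = np.zeros((s, s), dtype=bool)
    for sign in (-1.0, 1.0):
        cx = 0.5 + sign * (0.235 + rng.normal(0, 0.012))
        cy = 0.47 + rng.normal(0, 0.015)
        ax = 0.155 * (1 + rng.normal(0, 0.06))
        ay = 0.27 * (1 + rng.normal(0, 0.06))
        ellipse = ((u - cx) / ax) ** 2 + ((v - cy) / ay) ** 2 <= 1.0
        lung_mask |= ellipse & torso & ~med
    canvas[lung_mask] -= params.lung_contrast

    # rib bands: horizontal sinusoid restricted to the lung fields
    if params.rib_count > 0:
        phase = rng.uniform(0, 2 * np.pi)
        ribs = _RIB_AMPLITUDE * np.sin(
            2 * np.pi * params.rib_count * (v / 0.6) + phase)
        canvas[lung_mask] += ribs[lung_mask]

    canvas += exposure
    if params.blur_sigma > 0:
        canvas = gaussian_filter(canvas, params.blur_sigma, mode="reflect")
    if params.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, params.noise_sigma, size=(s, s))
    canvas = np.clip(np.floor(canvas + 0.5), 0, 255)
    return Image8(canvas, id=f"phantom-{params.seed:010d}" if id is None else id)


def generate_pool(n: int, params: PhantomParams) -> list[Image8]:
    """n phantoms with per-image seeds fanned out from ``params.seed``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    pool = []
    for i in range(n):
        child = replace(params, seed=derive_seed(params.seed, "pool", i))
        pool.append(generate_phantom(child, id=f"ph-{params.seed}-{i:06d}"))
    return pool


def generate_labeled_cohorts(n_pos: int, n_neg: int, params: PhantomParams,
                             shortcut: tuple[AdaSpec, str] | None = None,
                             *, name: str = "synthetic-cohort") -> LabeledDataset:
    """A binary-labeled phantom cohort, optionally with a planted shortcut.

    Without a shortcut, both cohorts come from the identical generator,
    so the labels carry no image signal whatsoever.  With
    ``shortcut=(spec, target)`` the stated class is perturbed via
    :func:`~shortcutscope.forge.inject_shortcut`.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError(f"need n_pos >= 1 and n_neg >= 1, got {n_pos}/{n_neg}")
    pool = generate_pool(n_pos + n_neg, params)
    items = tuple(
        DatasetItem(image=img, label=1 if i < n_pos else 0)
        for i, img in enumerate(pool)
    )
    ds = LabeledDataset(items=items, name=name,
                        provenance={"phantom_seed": params.seed,
                                    "n_pos": n_pos, "n_neg": n_neg})
    if shortcut is not None:
        spec, target = shortcut
        ds = inject_shortcut(ds, target, spec)
    return ds
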