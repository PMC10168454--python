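"""Acquisition-dependent attribute (ADA) perturbation operators.

Chest radiographs carry global characteristics — overall contrast and
edge sharpness — that are set by the imaging hardware, vendor
post-processing and protocol rather than by anatomy.  When such an
attribute correlates with the class label of a curated dataset it
becomes an *intrinsic shortcut*.  This module manufactures those
shortcuts on purpose, so a detective model can be trained to recognise
them:

* ADA-C (contrast): a gamma intensity map ``v -> 255 * (v/255)**gamma``,
  monotone and endpoint-preserving; gamma > 1 deepens shadows (more
  contrast in the bright range), gamma < 1 lifts them.
* ADA-S (sharpness): an unsharp mask ``I + amount * (I - G_sigma(I))``;
  positive amounts sharpen, negative amounts soften toward the Gaussian
  blur ``G_sigma``.

An :class:`AdaSpec` bundles the attribute, direction and a per-image
strength range; strengths are drawn independently per image (keyed by
the spec seed and the image id) so the perturbation mimics natural
acquisition variation instead of one fixed lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import gaussian_filter

from ._seeds import derive_rng
from .imagekit import Image8, round_half_away

__all__ = [
    "AdaKind",
    "AdaDirection",
    "AdaSpec",
    "apply_contrast",
    "apply_sharpness",
    "apply_ada",
    "DEFAULT_SHARPNESS_SIGMA",
]

DEFAULT_SHARPNESS_SIGMA = 1.5  # pixels; detail band of the unsharp mask


class AdaKind(str, Enum):
    S = "S"  # sharpness
    C = "C"  # contrast


class AdaDirection(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"


@dataclass(frozen=True)
class AdaSpec:
    """Recipe for one acquisition-dependent perturbation.

    ``strength`` is unitless and maps to the operator parameter through
    the dispatch table of :func:`apply_ada`:

    ========  ==========  ======================================
    kind      direction   operator parameter for drawn strength s
    ========  ==========  ======================================
    C         increase    gamma = 1 + s
    C         decrease    gamma = 1 / (1 + s)
    S         increase    amount = +s   (sigma fixed)
    S         decrease    amount = -s   (sigma fixed)
    ========  ==========  ======================================

    Defaults for the two attributes (visually subtle yet learnable):
    contrast s in [0.15, 0.5] (gamma in [1.15, 1.5] increasing);
    sharpness s in [0.5, 1.5] increasing or [0.3, 0.7] decreasing,
    sigma = 1.5 px.
    """

    kind: AdaKind
    direction: AdaDirection = AdaDirection.INCREASE
    strength_low: float = 0.0
    strength_high: float = 0.0
    sigma: float = DEFAULT_SHARPNESS_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", AdaKind(self.kind))
        object.__setattr__(self, "direction", AdaDirection(self.direction))
        if self.strength_low < 0:
            raise ValueError("strength_low must be >= 0")
        if self.strength_high < self.strength_low:
            raise ValueError("strength_high must be >= strength_low")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @classmethod
    def default(cls, kind: AdaKind | str,
                direction: AdaDirection | str = AdaDirection.INCREASE,
                seed: int = 0) -> "AdaSpec":
        """The package default strength ranges for an attribute."""
        kind = AdaKind(kind)
        direction = AdaDirection(direction)
        if kind is AdaKind.C:
            lo, hi = 0.15, 0.5  # gamma 1.15..1.5 (or reciprocal)
        elif direction is AdaDirection.INCREASE:
            lo, hi = 0.5, 1.5  # unsharp amount
        else:
            lo, hi = 0.3, 0.7  # softening amount (sign applied at dispatch)
        return cls(kind=kind, direction=direction, strength_low=lo,
                   strength_high=hi, seed=seed)

    def to_config(self) -> dict:
        """Flat key=value block for provenance sidecars."""
        return {
            "kind": self.kind.value,
            "direction": self.direction.value,
            "strength_low": self.strength_low,
            "strength_high": self.strength_high,
            "sigma": self.sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_config(cls, block: dict) -> "AdaSpec":
        return cls(
            kind=AdaKind(block["kind"]),
            direction=AdaDirection(block["direction"]),
            strength_low=float(block["strength_low"]),
            strength_high=float(block["strength_high"]),
            sigma=float(block.get("sigma", DEFAULT_SHARPNESS_SIGMA)),
            seed=int(block["seed"]),
        )


def apply_contrast(image: Image8, gamma: float) -> Image8:
    """Gamma intensity mapping ``v -> round(255 * (v/255)**gamma)``.

    A monotone remap of the intensity axis: pixel rank order is
    preserved and 0 and 255 are fixed points.  ``gamma = 1`` is the
    identity.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if gamma == 1.0:
        return image
    v = image.pixels.astype(np.float64) / 255.0
    out = round_half_away(255.0 * np.power(v, gamma))
    return image.with_pixels(np.clip(out, 0, 255))


def apply_sharpness(image: Image8, sigma: float, amount: float) -> Image8:
    """Unsharp mask ``I + amount * (I - G_sigma(I))`` (reflect padding).

    ``amount > 0`` sharpens (amplifies the detail band), ``amount < 0``
    softens toward the blur; ``amount = -1`` reaches the pure blur and
    anything below would invert detail contrast, so it is rejected.
    ``sigma = 0`` or ``amount = 0`` are exact identities.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if amount < -1:
        raise ValueError(
            f"amount must be >= -1 (got {amount}); below -1 the detail band "
            "inverts contrast"
        )
    if sigma == 0 or amount == 0:
        return image
    src = image.pixels.astype(np.float64)
    blurred = gaussian_filter(src, sigma=sigma, mode="reflect")
    out = round_half_away(src + amount * (src - blurred))
    return image.with_pixels(np.clip(out, 0, 255))


def draw_strength(spec: AdaSpec, image_id: str) -> float:
    """The per-image strength: uniform in [low, high], keyed by (seed, id)."""
    if spec.strength_high == spec.strength_low:
        return spec.strength_low
    rng = derive_rng(spec.seed, "ada-strength", image_id)
    return float(rng.uniform(spec.strength_low, spec.strength_high))


def apply_ada(image: Image8, spec: AdaSpec) -> Image8:
    """Apply one ADA perturbation with a per-image random strength.

    Deterministic given ``(spec.seed, image.id)``; dataset order never
    changes the result.  Zero strength is a bit-exact identity for
    either attribute.
    """
    s = draw_strength(spec, image.id)
    if s == 0.0:
        return image
    if spec.kind is AdaKind.C:
        gamma = 1.0 + s if spec.direction is AdaDirection.INCREASE else 1.0 / (1.0 + s)
        return apply_contrast(image, gamma)
    amount = s if spec.direction is AdaDirection.INCREASE else -s
    return apply_sharpness(image, spec.sigma, amount)
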