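"""Image I/O and preprocessing for 8-bit grayscale radiographs.

Every operator in the package consumes and produces :class:`Image8`, a
thin immutable wrapper around a 2-D ``uint8`` array.  This module owns
the conversions into that representation: DICOM window/level mapping,
bilinear resizing, and PNG round-tripping.

Conventions (fixed package-wide):

* row-major pixel grids, origin top-left, 0-based indices;
* rounding is half-away-from-zero everywhere so ports agree bit-for-bit;
* persisted images are 8-bit grayscale PNG; DICOM is input-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage

__all__ = [
    "Image8",
    "WindowSpec",
    "round_half_away",
    "window_to_8bit",
    "resize",
    "read_png",
    "write_png",
    "read_dicom",
]

MIN_SIDE = 8


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1).

    numpy's ``round`` is banker's rounding; image pipelines ported across
    languages disagree silently unless the rule is pinned down once.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class Image8:
    """One grayscale 8-bit image.

    Parameters
    ----------
    pixels
        2-D integer array; every value must lie in [0, 255].  Stored as
        ``uint8`` and made read-only.
    id
        Opaque identifier, unique within a dataset.  Drives per-image
        deterministic randomness downstream.
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"Image8 requires a 2-D pixel grid, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValueError(
                f"Image8 requires height and width >= {MIN_SIDE}, got {px.shape}"
            )
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                if not np.all(px == np.floor(px)):
                    raise ValueError("Image8 pixels must be integers")
            if px.min() < 0 or px.max() > 255:
                raise ValueError(
                    f"Image8 pixels must lie in [0, 255], got range "
                    f"[{px.min()}, {px.max()}]"
                )
            px = px.astype(np.uint8)
        px = px.copy()
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def with_pixels(self, pixels: np.ndarray, id: str | None = None) -> "Image8":
        """A copy of this image with new pixels (and optionally a new id)."""
        return Image8(pixels=pixels, id=self.id if id is None else id)


@dataclass(frozen=True)
class WindowSpec:
    """DICOM-style display window: center (level, WL) and span (width, WW)."""

    level: float
    width: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.level) or not np.isfinite(self.width):
            raise ValueError("window level and width must be finite")
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


def window_to_8bit(raw: np.ndarray, window: WindowSpec, *, id: str = "") -> Image8:
    """Map raw detector intensities into [0, 255] through a display window.

    The window spans ``[WL - WW/2, WL + WW/2]``; intensities below map to
    0, above to 255, and in between linearly:

    ``out = round(255 * clamp((x - (WL - WW/2)) / WW, 0, 1))``.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError(f"expected a 2-D raw intensity grid, got shape {raw.shape}")
    bad = ~np.isfinite(raw)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite raw intensity at index {idx}")
    lo = window.level - window.width / 2.0
    frac = np.clip((raw - lo) / window.width, 0.0, 1.0)
    return Image8(round_half_away(255.0 * frac), id=id)


def resize(image: Image8, side: int) -> Image8:
    """Resize to ``side``x``side`` with bilinear interpolation.

    Values are rounded (half away from zero) and clamped back to [0, 255].
    """
    from skimage.transform import resize as _sk_resize

    side = int(side)
    if side < MIN_SIDE:
        raise ValueError(f"target side must be >= {MIN_SIDE}, got {side}")
    if image.height == side and image.width == side:
        return image
    out = _sk_resize(
        image.pixels.astype(np.float64),
        (side, side),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return Image8(np.clip(round_half_away(out), 0, 255), id=image.id)


def write_png(image: Image8, path: str | Path) -> Path:
    """Write an 8-bit grayscale PNG; the write-then-read round-trip is exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _PILImage.fromarray(image.pixels, mode="L").save(path, format="PNG")
    return path


def read_png(path: str | Path, *, id: str | None = None) -> Image8:
    """Read a PNG as 8-bit grayscale.

    Single-channel 8-bit images are read as-is.  RGB/RGBA inputs are
    reduced to grayscale by the channel average (rounded half away from
    zero), which is exact for channel-equal images.  16-bit PNGs are
    rejected rather than silently rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with _PILImage.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "I;16L", "I;16N"):
            raise ValueError(
                f"unsupported bit depth: {path} is a 16-bit PNG; only 8-bit "
                "grayscale (or 8-bit RGB reducible to grayscale) is supported"
            )
        if im.mode == "L":
            px = np.asarray(im, dtype=np.uint8)
        elif im.mode in ("RGB", "RGBA", "LA", "P"):
            arr = np.asarray(im.convert("RGB"), dtype=np.float64)
            px = np.clip(round_half_away(arr.mean(axis=2)), 0, 255)
        else:
            raise ValueError(f"unsupported PNG mode {im.mode!r} in {path}")
    return Image8(px, id=path.stem if id is None else id)


def default_window(ds, raw: np.ndarray | None = None) -> WindowSpec:
    """The window used when converting a DICOM dataset.

    Prefers the dataset's own WindowCenter/WindowWidth (first value if
    multi-valued); falls back to the full dynamic range of the pixel data
    (level = midrange, width = max - min), matching common viewer
    behavior for unwindowed data.
    """
    wl = getattr(ds, "WindowCenter", None)
    ww = getattr(ds, "WindowWidth", None)

    def _first(v):
        try:
            return float(v[0])
        except (TypeError, IndexError):
            return float(v)

    if wl is not None and ww is not None:
        width = _first(ww)
        if width > 0:
            return WindowSpec(level=_first(wl), width=width)
    arr = (ds.pixel_array if raw is None else raw).astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        hi = lo + 1.0  # constant frame: any window renders it flat
    return WindowSpec(level=(lo + hi) / 2.0, width=hi - lo)


def read_dicom(path: str | Path, *, window: WindowSpec | None = None,
               id: str | None = None) -> Image8:
    """Read a single-frame grayscale DICOM and window it to 8 bits.

    MONOCHROME1 data (low values = bright) is inverted before windowing
    so the output keeps the bright-equals-dense convention.  Rescale
    slope/intercept are applied when present.
    """
    import pydicom

    path = Path(path)
    ds = pydicom.dcmread(path)
    raw = ds.pixel_array.astype(np.float64)
    if raw.ndim != 2:
        raise ValueError(f"multi-frame or non-grayscale DICOM not supported: {path}")
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    raw = raw * slope + intercept
    if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1":
        raw = raw.max() + raw.min() - raw
    if window is None:
        window = default_window(ds, raw)
    return window_to_8bit(raw, window, id=path.stem if id is None else id)
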