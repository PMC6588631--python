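"""Patch extraction from tiled slide images and square-symmetry utilities.

Whole slides are represented as per-magnification RGB arrays (a pyramid in
which linear dimensions halve per 2x magnification step).  All coordinates are
0-based, top-left origin, half-open rectangles, expressed in the *base* frame,
i.e. the pixel grid of the highest magnification present.  Patches extracted
at a lower magnification record their footprint in that base frame via a
``scale`` factor (base pixels per level pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon, box

__all__ = [
    "SlideImage",
    "AnnotationRegion",
    "Patch",
    "magnification_value",
    "extract_patches",
    "patches_from_annotations",
    "orient_pixels",
    "dihedral_orientations",
    "inverse_orientation",
    "resize_for_embedding",
    "EMBED_INPUT_SIZE",
]

#: Side length every embedder input is resized to (bilinear).
EMBED_INPUT_SIZE = 224

#: Query patches must fall in this side-length range before resizing.
MIN_QUERY_SIZE = 200
MAX_QUERY_SIZE = 400


def magnification_value(label: str) -> float:
    """Numeric objective power of a magnification label such as ``"40x"``.

    Accepts ``"40x"``, ``"x40"`` and ``"×40"`` spellings.
    """
    text = str(label).strip().lower().strip("x×")
    try:
        value = float(text)
    except ValueError as exc:
        raise ValueError(f"unparseable magnification label: {label!r}") from exc
    if value <= 0:
        raise ValueError(f"magnification must be positive: {label!r}")
    return value


def _check_rgb(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB array, got shape {pixels.shape}")
    return pixels


@dataclass
class SlideImage:
    """A multi-magnification pyramid of RGB images of one scene.

    Parameters
    ----------
    slide_id:
        Unique identifier.
    levels:
        Mapping of magnification label (e.g. ``"40x"``) to an ``(H, W, 3)``
        uint8/float array.  All levels depict the same scene; linear
        dimensions halve per 2x magnification step (within 1 px rounding).
    microns_per_pixel:
        Optional mapping of magnification label to physical resolution.
    """

    slide_id: str
    levels: dict[str, np.ndarray]
    microns_per_pixel: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("slide needs at least one magnification level")
        for label, pixels in self.levels.items():
            self.levels[label] = _check_rgb(pixels)
        base = self.base_magnification
        base_h, base_w = self.levels[base].shape[:2]
        base_mag = magnification_value(base)
        for label, pixels in self.levels.items():
            factor = base_mag / magnification_value(label)
            for got, full in zip(pixels.shape[:2], (base_h, base_w)):
                if abs(got * factor - full) > factor:  # 1 px rounding at level
                    raise ValueError(
                        f"level {label} of slide {self.slide_id} has shape "
                        f"{pixels.shape[:2]}, inconsistent with base {base} "
                        f"shape {(base_h, base_w)}"
                    )

    @property
    def base_magnification(self) -> str:
        """Label of the highest-magnification level (the base frame)."""
        return max(self.levels, key=magnification_value)

    def scale(self, magnification: str) -> float:
        """Base-frame pixels per pixel of ``magnification``'s level."""
        if magnification not in self.levels:
            raise KeyError(
                f"slide {self.slide_id} has no {magnification} level; "
                f"available: {sorted(self.levels)}"
            )
        return magnification_value(self.base_magnification) / magnification_value(
            magnification
        )


@dataclass(frozen=True)
class AnnotationRegion:
    """A labeled region outlined on a slide, in base-frame coordinates.

    ``shape`` is either an ``(x, y, w, h)`` rectangle tuple or a shapely
    polygon.  ``purity`` is the fraction of the region's area truly belonging
    to its label; annotations here are assumed ~70% pure by default.
    """

    slide_id: str
    shape: tuple[float, float, float, float] | Polygon
    label: str
    purity: float = 0.7

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("annotation label must be non-empty")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")
        if self.geometry.area <= 0:
            raise ValueError("annotation region must have positive area")

    @property
    def geometry(self) -> Polygon:
        if isinstance(self.shape, Polygon):
            return self.shape
        x, y, w, h = self.shape
        return box(x, y, x + w, y + h)


@dataclass
class Patch:
    """A square (typically 300x300) RGB tile cut from a slide.

    ``origin`` is the top-left corner in the base frame; ``size`` is
    ``(w, h)`` in pixels *at the patch's own magnification*; ``scale`` maps
    level pixels to base-frame pixels, so the base-frame footprint is
    ``size * scale``.  ``labels`` carries the recorded annotation categories
    (a set: regions may overlap).
    """

    slide_id: str
    origin: tuple[float, float]
    magnification: str
    pixels: np.ndarray
    labels: frozenset[str] = frozenset()
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = _check_rgb(self.pixels)
        self.labels = frozenset(self.labels)

    @property
    def size(self) -> tuple[int, int]:
        """(w, h) in pixels at the patch's magnification."""
        h, w = self.pixels.shape[:2]
        return (w, h)

    @property
    def base_footprint(self) -> tuple[float, float, float, float]:
        """(x, y, w, h) rectangle in base-frame pixels."""
        w, h = self.size
        return (self.origin[0], self.origin[1], w * self.scale, h * self.scale)

    @property
    def center(self) -> tuple[float, float]:
        """Base-frame center, the reference point for spatial diversity."""
        x, y, w, h = self.base_footprint
        return (x + w / 2.0, y + h / 2.0)

    @property
    def ref(self) -> tuple[str, float, float, str]:
        """(slide_id, x, y, magnification) identity key."""
        return (self.slide_id, self.origin[0], self.origin[1], self.magnification)


def extract_patches(
    slide: SlideImage,
    magnification: str,
    size: int = 300,
    stride: int | None = None,
) -> list[Patch]:
    """Tile one magnification level into fixed-size patches.

    Patches are emitted left-to-right, top-to-bottom.  With the default
    ``stride = size`` the footprints are pairwise non-overlapping.  Incomplete
    boundary tiles are dropped, never padded.
    """
    if stride is None:
        stride = size
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    level = slide.levels.get(magnification)
    if level is None:
        raise KeyError(
            f"slide {slide.slide_id} has no {magnification} level; "
            f"available: {sorted(slide.levels)}"
        )
    h, w = level.shape[:2]
    if size > min(h, w):
        raise ValueError(
            f"patch size {size} exceeds {magnification} level dimensions {(w, h)}"
        )
    scale = slide.scale(magnification)
    patches = []
    for y in range(0, h - size + 1, stride):
        for x in range(0, w - size + 1, stride):
            patches.append(
                Patch(
                    slide_id=slide.slide_id,
                    origin=(x * scale, y * scale),
                    magnification=magnification,
                    pixels=level[y : y + size, x : x + size].copy(),
                    scale=scale,
                )
            )
    return patches


def patches_from_annotations(
    slide: SlideImage,
    regions: list[AnnotationRegion],
    magnification: str,
    size: int = 300,
    min_overlap: float = 0.7,
) -> list[Patch]:
    """Extract labeled patches whose footprints lie mostly inside annotations.

    For each region a non-overlapping grid of candidate footprints is anchored
    at the region's bounding-box corner; a candidate is kept when at least
    ``min_overlap`` of its area falls inside the region (default 0.7, chosen
    to mirror the ~70% purity the annotations themselves carry).  A kept patch
    inherits the label of *every* region it overlaps above threshold, so
    overlapping annotations produce multi-label patches.  Regions smaller than
    one footprint simply contribute no patches.
    """
    for region in regions:
        if region.slide_id != slide.slide_id:
            raise ValueError(
                f"region on slide {region.slide_id} does not belong to "
                f"slide {slide.slide_id}"
            )
    level = slide.levels.get(magnification)
    if level is None:
        raise KeyError(
            f"slide {slide.slide_id} has no {magnification} level; "
            f"available: {sorted(slide.levels)}"
        )
    h, w = level.shape[:2]
    scale = slide.scale(magnification)

    candidates: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for region in regions:
        minx, miny, maxx, maxy = region.geometry.bounds
        x0 = int(round(minx / scale))
        y0 = int(round(miny / scale))
        x1 = int(round(maxx / scale))
        y1 = int(round(maxy / scale))
        for y in range(y0, y1 - size + 1, size):
            for x in range(x0, x1 - size + 1, size):
                if x < 0 or y < 0 or x + size > w or y + size > h:
                    continue
                if (x, y) not in seen:
                    seen.add((x, y))
                    candidates.append((x, y))

    patches = []
    for x, y in sorted(candidates, key=lambda c: (c[1], c[0])):
        footprint = box(x * scale, y * scale, (x + size) * scale, (y + size) * scale)
        labels = {
            region.label
            for region in regions
            if region.geometry.intersection(footprint).area / footprint.area
            >= min_overlap
        }
        if labels:
            patches.append(
                Patch(
                    slide_id=slide.slide_id,
                    origin=(x * scale, y * scale),
                    magnification=magnification,
                    pixels=level[y : y + size, x : x + size].copy(),
                    labels=frozenset(labels),
                    scale=scale,
                )
            )
    return patches


# --- dihedral group D4 -----------------------------------------------------
#
# Histology has no preferred orientation, so the database stores one embedding
# per element of the symmetry group of the square: indices 0-3 are
# counter-clockwise rotations by 0/90/180/270 degrees, indices 4-7 are the
# horizontal mirror followed by the same rotations.

#: Group inverse of each orientation index (mirrored elements are involutions).
_INVERSE = (0, 3, 2, 1, 4, 5, 6, 7)


def orient_pixels(pixels: np.ndarray, orientation: int) -> np.ndarray:
    """Apply dihedral transform ``orientation`` (0-7) to a square array."""
    pixels = np.asarray(pixels)
    if pixels.shape[0] != pixels.shape[1]:
        raise ValueError(
            f"dihedral transforms need a square patch, got {pixels.shape[:2]}"
        )
    if not 0 <= orientation <= 7:
        raise ValueError(f"orientation index must be 0-7, got {orientation}")
    if orientation >= 4:
        pixels = pixels[:, ::-1]
    return np.rot90(pixels, orientation % 4)


def dihedral_orientations(patch: "Patch | np.ndarray") -> list[np.ndarray]:
    """The 8 oriented copies of a square patch, indexed 0-7."""
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    return [np.ascontiguousarray(orient_pixels(pixels, i)) for i in range(8)]


def inverse_orientation(orientation: int) -> int:
    """Index of the transform undoing ``orientation``."""
    if not 0 <= orientation <= 7:
        raise ValueError(f"orientation index must be 0-7, got {orientation}")
    return _INVERSE[orientation]


def resize_for_embedding(pixels: np.ndarray, out_size: int = EMBED_INPUT_SIZE) -> np.ndarray:
    """Resize a query/database patch to the embedder's 224x224 input contract.

    Inputs must be between 200 and 400 pixels on each side (the query-size
    rule).  Interpolation is corner-aligned bilinear, so constants and linear
    ramps are reproduced exactly and endpoint values are preserved; outputs
    are clamped to [0, 255].  A 224x224 input is returned unchanged, making
    the operation idempotent.
    """
    pixels = _check_rgb(pixels)
    h, w = pixels.shape[:2]
    for side in (h, w):
        if not MIN_QUERY_SIZE <= side <= MAX_QUERY_SIZE:
            raise ValueError(
                f"patch sides must be within [{MIN_QUERY_SIZE}, {MAX_QUERY_SIZE}] px "
                f"before embedding, got {(w, h)}"
            )
    if (h, w) == (out_size, out_size):
        return pixels
    rows = np.linspace(0.0, h - 1.0, out_size)
    cols = np.linspace(0.0, w - 1.0, out_size)
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty((out_size, out_size, 3), dtype=np.float32)
    for c in range(3):
        out[:, :, c] = map_coordinates(
            pixels[:, :, c].astype(np.float64), [grid_r, grid_c], order=1, mode="nearest"
        )
    return np.clip(out, 0.0, 255.0)
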