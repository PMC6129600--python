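"""Footprint image input, binarization, and boundary-contour extraction.

The analysis pipeline operates on binary rasters of toeless plantar prints
(ink pedograph tracings scanned to PNG/TIFF/PGM). This module reads such
images, thresholds them into a :class:`BinaryFootprint`, and traces the
ordered boundary contour that the perimeter and bending-energy features
consume.

Conventions
-----------
* Pixel coordinates are ``(row, col)``, 0-based, origin at the top-left.
* A *boundary pixel* is a foreground pixel with at least one background
  4-neighbour.
* Contours are traced with the Moore-neighbour (8-connectivity) walk and
  oriented so the signed polygon area (x = col, y = row) is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "GrayImage",
    "BinaryFootprint",
    "Contour",
    "FootprintError",
    "EmptyFootprintError",
    "ConfigurationError",
    "read_image",
    "binarize",
    "boundary_mask",
    "extract_contour",
]

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity
_BOX = ndi.generate_binary_structure(2, 2)  # 8-connectivity

# Moore neighbourhood enumerated clockwise starting from North (row-up).
_NBRS = (
    (-1, 0), (-1, 1), (0, 1), (1, 1),
    (1, 0), (1, -1), (0, -1), (-1, -1),
)
_NBR_INDEX = {d: i for i, d in enumerate(_NBRS)}


class FootprintError(ValueError):
    """Base class for footprint-processing errors."""


class EmptyFootprintError(FootprintError):
    """Raised when an operation would produce or consume an empty mask."""


class ConfigurationError(FootprintError):
    """Raised when required configuration (e.g. spatial resolution) is missing."""


@dataclass
class GrayImage:
    """A 2-D grayscale intensity grid with physical resolution metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D float array of intensities in ``[0, 255]``.
    resolution : float
        Spatial sampling in pixels per millimetre (> 0).
    """

    pixels: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FootprintError("GrayImage requires a non-empty 2-D intensity grid")
        if not np.all(np.isfinite(self.pixels)):
            raise FootprintError("GrayImage intensities must be finite")
        if not (self.resolution > 0):
            raise ConfigurationError("resolution (px per mm) must be positive")


@dataclass
class BinaryFootprint:
    """A binary (True = ink/foreground) raster of a toeless plantar print."""

    mask: np.ndarray
    resolution: float = 2.0
    side: str = "unknown"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FootprintError("mask must be 2-D")
        if not self.mask.any():
            raise EmptyFootprintError("empty footprint: mask has no foreground pixels")
        if not (self.resolution > 0):
            raise ConfigurationError("resolution (px per mm) must be positive")
        if self.side not in ("left", "right", "unknown"):
            raise FootprintError(f"side must be left/right/unknown, got {self.side!r}")

    @property
    def area_px2(self) -> int:
        return int(self.mask.sum())


@dataclass
class Contour:
    """Ordered closed boundary pixel sequences, one per foreground region.

    Each component is an ``(n, 2)`` integer array of ``(row, col)``
    coordinates, cyclically ordered (last pixel 8-adjacent to the first)
    with positive signed polygon area (foreground on the left).
    """

    components: list = field(default_factory=list)

    @property
    def n_pixels(self) -> int:
        return int(sum(len(c) for c in self.components))

    def pixels(self) -> np.ndarray:
        """All contour pixels concatenated across components."""
        return np.concatenate(self.components, axis=0)


def read_image(path, resolution: float | None = None) -> GrayImage:
    """Read a PNG/TIFF/PGM image and convert it to a grayscale grid.

    RGB(A) inputs are converted to luminance (ITU-R 601 weights); grayscale
    inputs pass through unchanged. ``resolution`` (px per mm) must be
    supplied here or by the caller's configuration.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise OSError(f"cannot read image file {path}: empty image")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
        else:
            arr = arr[..., 0]
    elif arr.ndim != 2:
        raise OSError(f"cannot read image file {path}: unsupported dimensionality")
    if resolution is None:
        raise ConfigurationError(
            f"no resolution (px per mm) supplied for {path}; "
            "set resolution_px_per_mm in the config or pass it explicitly"
        )
    return GrayImage(pixels=arr, resolution=resolution)


def binarize(
    img,
    threshold: float = 128.0,
    polarity: str = "light",
    fill_holes: bool = True,
    min_component_frac: float = 0.01,
    resolution: float | None = None,
    side: str = "unknown",
) -> BinaryFootprint:
    """Threshold a grayscale image into a solid binary footprint.

    Parameters
    ----------
    img : GrayImage or ndarray
        Intensity grid. If an ndarray, ``resolution`` must be given.
    threshold : float
        Intensity cut in ``[0, 255]``.
    polarity : {"light", "dark"}
        ``light``: foreground where intensity >= threshold (light ink on a
        dark scan); ``dark``: foreground where intensity <= threshold.
    fill_holes : bool
        Fill interior dropouts so the print is a solid region (the area and
        arch-index definitions assume solid contact regions).
    min_component_frac : float
        Connected components (8-connectivity) smaller than this fraction of
        total foreground are treated as specks and removed. Severe high-arch
        prints legitimately split into heel and forefoot components, so all
        components above the cut are kept and analysed as a union.
    """
    if isinstance(img, GrayImage):
        pixels = img.pixels
        resolution = img.resolution if resolution is None else resolution
    else:
        pixels = np.asarray(img, dtype=float)
    if resolution is None:
        raise ConfigurationError("binarize: resolution (px per mm) not supplied")
    if not (0 <= threshold <= 255):
        raise FootprintError(f"threshold must be in [0, 255], got {threshold}")
    if polarity not in ("light", "dark"):
        raise FootprintError(f"polarity must be 'light' or 'dark', got {polarity!r}")

    mask = pixels >= threshold if polarity == "light" else pixels <= threshold
    if not mask.any():
        raise EmptyFootprintError("empty footprint: no pixels pass the threshold")
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask, structure=_BOX)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(sizes >= min_component_frac * mask.sum()) + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        raise EmptyFootprintError("empty footprint: all components below size cut")
    return BinaryFootprint(mask=mask, resolution=resolution, side=side)


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels: foreground with at least one background 4-neighbour."""
    mask = np.asarray(mask, dtype=bool)
    return mask & ~ndi.binary_erosion(mask, structure=_CROSS, border_value=0)


def _trace_moore(mask: np.ndarray) -> list:
    """Moore-neighbour boundary walk of a single foreground component.

    Returns the ordered closed walk of outer-boundary pixels. The walk may
    touch a pixel twice at one-pixel-wide necks; callers deduplicate.
    """
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # row-major first pixel: on the boundary
    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    walk = [start]
    cur = start
    back = (start[0], start[1] - 1)  # entered scanning from the West
    seen = {(cur, back)}
    for _ in range(8 * mask.size):
        i = _NBR_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            j = (i + k) % 8
            cand = (cur[0] + _NBRS[j][0], cur[1] + _NBRS[j][1])
            if fg(cand):
                prev = (cur[0] + _NBRS[(j - 1) % 8][0], cur[1] + _NBRS[(j - 1) % 8][1])
                nxt = cand
                back = prev
                break
        if nxt is None:  # isolated pixel
            return [start]
        state = (nxt, back)
        if state in seen:
            break
        seen.add(state)
        walk.append(nxt)
        cur = nxt
    return walk


def _signed_area(component: np.ndarray) -> float:
    """Shoelace signed area with x = col, y = row."""
    y = component[:, 0].astype(float)
    x = component[:, 1].astype(float)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_contour(fp: BinaryFootprint) -> Contour:
    """Trace the ordered outer boundary of each foreground region.

    The traced pixel set equals ``{p in foreground : p has a background
    4-neighbour}`` for solid (hole-free) regions; each component is a closed
    cycle with positive signed polygon area.
    """
    mask = fp.mask
    if not mask.any():
        raise EmptyFootprintError("extract_contour: empty footprint")
    labels, n = ndi.label(mask, structure=_BOX)
    bmask = boundary_mask(mask)
    components = []
    for lab in range(1, n + 1):
        comp = labels == lab
        walk = _trace_moore(comp)
        ordered, seen = [], set()
        for p in walk:
            if p not in seen and bmask[p]:
                seen.add(p)
                ordered.append(p)
        arr = np.array(ordered, dtype=int)
        if len(arr) >= 3 and _signed_area(arr) < 0:
            arr = arr[::-1].copy()
        components.append(arr)
    return Contour(components=components)
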