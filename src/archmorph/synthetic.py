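"""Synthetic toeless plantar prints and analytic test shapes.

Real pedograph prints are not distributable with the package, so the test
and calibration machinery runs on generated masks. The footprint template
is a heel disk plus a forefoot ellipse joined by a midfoot band whose
medial edge is indented by a controllable ``arch_depth``:

* ``arch_depth = 0`` — flat foot: full-width midfoot contact, convex-ish
  outline, large arch index.
* ``arch_depth -> 1`` — pes cavus: the medial indentation narrows the band
  below 10% of foot width and finally disconnects heel from forefoot.

Optional boundary jitter (radial Gaussian displacement of the traced
outline, re-rasterized) emulates ink-edge raggedness. All generation is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, measure

from .io import BinaryFootprint, FootprintError

__all__ = ["FootprintParams", "generate_footprint", "generate_disk", "generate_rectangle"]


@dataclass
class FootprintParams:
    """Parameters of the synthetic toeless footprint.

    length_mm is the heel-to-metatarsal-line distance (the print is
    toeless); width_mm the forefoot width. ``resolution`` is the raster
    scale in pixels per millimetre; 2 px/mm is the reference scale at which
    the fitted arch-height model's coefficients are calibrated.
    """

    length_mm: float = 180.0
    width_mm: float = 90.0
    arch_depth: float = 0.35
    side: str = "right"
    resolution: float = 2.0
    boundary_noise_px: float = 0.0
    corner_smooth_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.length_mm > self.width_mm > 0):
            raise FootprintError("require length_mm > width_mm > 0")
        if not (0.0 <= self.arch_depth <= 1.0):
            raise FootprintError("arch_depth must be in [0, 1]")
        if self.side not in ("left", "right"):
            raise FootprintError("side must be 'left' or 'right'")
        if not (self.resolution > 0):
            raise FootprintError("resolution must be positive")
        if self.boundary_noise_px < 0:
            raise FootprintError("boundary_noise_px must be >= 0")
        if self.corner_smooth_mm < 0:
            raise FootprintError("corner_smooth_mm must be >= 0")


# Template proportions (fractions of foot length L / width W). The heel
# disk and forefoot ellipse roughly match adult pedograph prints; the
# bite ellipse carves the medial longitudinal arch out of the convex
# base blob, with penetration depth d_max at arch_depth = 1 chosen to
# fully disconnect the midfoot.
_HEEL_R = 0.30  # of W
_FORE_CY = 0.17  # of L
_FORE_RY = 0.17  # of L
_BITE_RX = 0.50  # of W
_BITE_RY = 0.32  # of L
_BITE_CY = 0.50  # of L
_D_MAX = 0.92  # of the midfoot width at arch_depth = 0


def generate_footprint(p: FootprintParams) -> BinaryFootprint:
    """Rasterize the parametric toeless footprint template.

    The base shape is the convex hull of the heel disk and the forefoot
    ellipse — a smooth, capsule-like blob emulating a flat print. The
    medial arch is a subtracted ellipse ("bite") penetrating the medial
    edge at midfoot by ``arch_depth`` times the maximal depth; at depth
    near 1 the remaining band narrows below 10% of foot width and then
    disconnects. A final Gaussian rounding pass (``corner_smooth_mm``)
    removes the rasterization corners where the bite meets the outline,
    as real ink outlines carry no sharp vertices. Both the bite and the
    rounding are inclusion-monotone in ``arch_depth``.
    """
    from skimage.morphology import convex_hull_image

    L, W, res = p.length_mm, p.width_mm, p.resolution
    margin = 8.0 + 4.0 * (p.boundary_noise_px / res + 1.0)
    h = int(round((L + 2 * margin) * res))
    w = int(round((W + 2 * margin) * res))
    yy = (np.arange(h)[:, None] + 0.5) / res - margin  # mm, 0 at forefoot tip
    xx = (np.arange(w)[None, :] + 0.5) / res - margin

    fore_cx, fore_cy = W / 2, _FORE_CY * L
    fore = ((xx - fore_cx) / (W / 2)) ** 2 + ((yy - fore_cy) / (_FORE_RY * L)) ** 2 <= 1.0
    heel_r = _HEEL_R * W
    heel = (xx - W / 2) ** 2 + (yy - (L - heel_r)) ** 2 <= heel_r**2
    base = convex_hull_image(fore | heel)

    # medial edge of the base blob at the bite's central row
    bite_cy = _BITE_CY * L
    row = int(np.clip(round((bite_cy + margin) * res - 0.5), 0, h - 1))
    cols = np.flatnonzero(base[row])
    x_med = (cols.max() + 0.5) / res - margin  # mm
    x_lat = (cols.min() + 0.5) / res - margin
    d_max = _D_MAX * (x_med - x_lat)

    bx, by = _BITE_RX * W, _BITE_RY * L
    bite_cx = x_med + bx - p.arch_depth * d_max
    bite = ((xx - bite_cx) / bx) ** 2 + ((yy - bite_cy) / by) ** 2 <= 1.0

    mask = base & ~bite
    if p.corner_smooth_mm > 0:
        smoothed = ndi.gaussian_filter(mask.astype(float), p.corner_smooth_mm * res)
        mask = smoothed >= 0.5
    if p.boundary_noise_px > 0:
        mask = _jitter_boundary(mask, p.boundary_noise_px, np.random.default_rng(p.seed))
    if p.side == "left":
        mask = mask[:, ::-1].copy()
    return BinaryFootprint(mask=mask, resolution=res, side=p.side)


def _jitter_boundary(mask: np.ndarray, sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Radially perturb each component outline and re-rasterize.

    Per-vertex Gaussian offsets are smoothed along the contour (circular
    window) so the perturbed polygon stays simple for noise amplitudes
    below the midfoot band width.
    """
    out = np.zeros_like(mask)
    labels, n = ndi.label(mask, structure=ndi.generate_binary_structure(2, 2))
    for lab in range(1, n + 1):
        comp = labels == lab
        contours = measure.find_contours(comp.astype(float), 0.5)
        poly = max(contours, key=len)
        cy, cx = np.argwhere(comp).mean(axis=0)
        dy, dx = poly[:, 0] - cy, poly[:, 1] - cx
        r = np.hypot(dy, dx)
        noise = rng.normal(0.0, sigma_px, size=len(poly))
        kernel = np.ones(7) / 7.0
        noise = np.convolve(np.concatenate([noise[-3:], noise, noise[:3]]), kernel, mode="valid")
        r_new = np.maximum(r + noise, 1.0)
        rows = cy + r_new * dy / np.maximum(r, 1e-9)
        cols = cx + r_new * dx / np.maximum(r, 1e-9)
        rr, cc = draw.polygon(rows, cols, shape=mask.shape)
        out[rr, cc] = True
    return out


def generate_disk(radius_px: float, pad: int = 2, resolution: float = 2.0) -> BinaryFootprint:
    """Filled disk: pixels whose centre is within ``radius_px`` of the centre."""
    if radius_px < 0.5:
        raise FootprintError("radius_px must be >= 0.5 (at least one pixel)")
    half = int(np.ceil(radius_px)) + pad
    coords = np.arange(-half, half + 1)
    mask = coords[:, None] ** 2 + coords[None, :] ** 2 <= radius_px**2
    return BinaryFootprint(mask=mask, resolution=resolution)


def generate_rectangle(w_px: int, h_px: int, pad: int = 2, resolution: float = 2.0) -> BinaryFootprint:
    """Filled ``h_px`` x ``w_px`` block centred in a padded canvas."""
    if w_px < 1 or h_px < 1:
        raise FootprintError("rectangle sides must be >= 1 pixel")
    mask = np.zeros((h_px + 2 * pad, w_px + 2 * pad), dtype=bool)
    mask[pad : pad + h_px, pad : pad + w_px] = True
    return BinaryFootprint(mask=mask, resolution=resolution)
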