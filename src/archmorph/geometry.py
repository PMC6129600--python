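"""Geometric shape descriptors: area, perimeter, circularity.

Circularity C = P^2 / A measures departure from a disk (4*pi for an ideal
circle, 16 for a square, larger for elongated or indented shapes). A flat
foot's straighter medial edge lowers C relative to a high-arch print of the
same area.

Two perimeter estimators are provided:

* ``boundary_count`` (default): boundary-pixel count x pi/4, summed over components
  — the convention used to calibrate the fitted arch-height model, kept as
  the default for score fidelity even though it is not a consistent length
  estimator.
* ``chain_code``: sum of traced step lengths (1 axial, sqrt(2) diagonal) —
  a consistent estimator, used where circularity is compared with its
  continuum closed form.
"""

from __future__ import annotations

import numpy as np

from .io import BinaryFootprint, Contour, EmptyFootprintError, FootprintError

__all__ = ["area", "perimeter", "circularity", "GeometricFeatures"]


def area(fp: BinaryFootprint) -> float:
    """Foreground pixel count (px^2)."""
    a = float(np.asarray(fp.mask, dtype=bool).sum())
    if a == 0:
        raise EmptyFootprintError("area: empty mask")
    return a


def perimeter(c: Contour, estimator: str = "boundary_count") -> float:
    """Contour length in px, summed over components.

    ``boundary_count``: (number of boundary pixels) * pi/4. ``chain_code``: sum of
    Euclidean step lengths along the closed traced cycle.
    """
    if not c.components or c.n_pixels == 0:
        raise EmptyFootprintError("perimeter: empty contour")
    if estimator == "boundary_count":
        return c.n_pixels * np.pi / 4.0
    if estimator == "chain_code":
        total = 0.0
        for comp in c.components:
            if len(comp) < 2:
                continue
            steps = np.diff(np.vstack([comp, comp[:1]]).astype(float), axis=0)
            total += float(np.hypot(steps[:, 0], steps[:, 1]).sum())
        return total
    raise FootprintError(f"unknown perimeter estimator {estimator!r}")


def circularity(P: float, A: float) -> float:
    """C = P^2 / A. Requires positive perimeter and area."""
    if not (P > 0 and A > 0):
        raise FootprintError(f"circularity requires P > 0 and A > 0, got P={P}, A={A}")
    return P * P / A


class GeometricFeatures:
    """Bundle of the three geometric descriptors for one print."""

    __slots__ = ("area_px2", "perimeter_px", "circularity")

    def __init__(self, area_px2: float, perimeter_px: float):
        self.area_px2 = area_px2
        self.perimeter_px = perimeter_px
        self.circularity = circularity(perimeter_px, area_px2)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeometricFeatures(area_px2={self.area_px2:.1f}, "
            f"perimeter_px={self.perimeter_px:.2f}, circularity={self.circularity:.3f})"
        )
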