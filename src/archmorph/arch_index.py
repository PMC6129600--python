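"""Automated Cavanagh & Rodgers Arch Index.

The Arch Index trisects the toeless print along its longitudinal axis into
forefoot (A), midfoot (B) and heel (C) sections of equal axial extent and
reports AI = B / (A + B + C): a flat foot has large midfoot contact (high
AI), a pes cavus print small or none (low AI). Cut-offs: AI >= 0.26 is a
low arch, AI <= 0.21 a high arch, in between normal.

The clinical construction draws the axis from mid-heel to the second toe;
toeless prints make that literal line impossible to automate, so the
longitudinal axis here is the major principal axis of the foreground pixel
distribution — a reproducible surrogate that is rotation-invariant (the
midfoot section, hence AI, does not depend on which end is called the
heel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryFootprint, EmptyFootprintError, FootprintError

__all__ = [
    "FootAxis",
    "Trisection",
    "ArchClassification",
    "NoDominantAxisError",
    "foot_axis",
    "trisect",
    "compute_ai",
    "classify_ai",
    "arch_index",
    "CR_HIGH_MAX",
    "CR_LOW_MIN",
]

CR_HIGH_MAX = 0.21  # AI <= this: high arch
CR_LOW_MIN = 0.26  # AI >= this: low arch


class NoDominantAxisError(FootprintError):
    """Raised when the pixel distribution has no dominant principal axis."""


@dataclass
class FootAxis:
    """Unit longitudinal direction (d_row, d_col), oriented heel -> forefoot."""

    direction: np.ndarray
    centroid: np.ndarray

    @property
    def angle_deg(self) -> float:
        """Angle from the column axis, in degrees, folded to [0, 180)."""
        ang = np.degrees(np.arctan2(self.direction[0], self.direction[1]))
        return float(ang % 180.0)


@dataclass
class Trisection:
    """Axial trisection of the print: section areas (A, B, C) in px^2."""

    axis: FootAxis
    region_areas: tuple  # (forefoot A, midfoot B, heel C)


@dataclass
class ArchClassification:
    scheme: str
    score: float
    label: str  # high / normal / low


def foot_axis(fp: BinaryFootprint) -> FootAxis:
    """Major principal axis of the foreground, oriented heel -> forefoot.

    Raises :class:`NoDominantAxisError` when the covariance eigenvalue
    ratio is below 1.05 (near-isotropic mask, e.g. a disk). The heel is
    taken as the narrower end: mean transverse spread of the pixels in the
    outer 15% of the axial extent at each end is compared.
    """
    coords = np.argwhere(fp.mask).astype(float)
    if len(coords) == 0:
        raise EmptyFootprintError("foot_axis: empty footprint")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or evals[1] / evals[0] < 1.05:
        raise NoDominantAxisError(
            f"no dominant axis: eigenvalue ratio {evals[1] / max(evals[0], 1e-12):.3f} < 1.05"
        )
    direction = evecs[:, 1]  # largest eigenvalue
    t = centered @ direction
    perp = centered @ evecs[:, 0]
    lo, hi = t.min(), t.max()
    cut = 0.15 * (hi - lo)
    width_lo = perp[t <= lo + cut].std()
    width_hi = perp[t >= hi - cut].std()
    if width_hi < width_lo:  # narrow (heel) end sits at +t: flip so heel is at -t
        direction = -direction
    return FootAxis(direction=direction, centroid=centroid)


def trisect(fp: BinaryFootprint, axis: FootAxis) -> Trisection:
    """Split the axial extent of the foreground into three equal intervals.

    Pixels project onto the longitudinal axis; the projected extent (of the
    foreground itself, not a bounding box) is cut at 1/3 and 2/3. A pixel
    exactly on a cut is assigned to the lower-index section (A before B
    before C).
    """
    coords = np.argwhere(fp.mask).astype(float)
    t = (coords - axis.centroid) @ axis.direction
    lo, hi = t.min(), t.max()
    e1 = lo + (hi - lo) / 3.0  # heel/midfoot cut
    e2 = lo + 2.0 * (hi - lo) / 3.0  # midfoot/forefoot cut
    a = float(np.count_nonzero(t >= e2))  # forefoot (heel at -t)
    b = float(np.count_nonzero((t >= e1) & (t < e2)))
    c = float(np.count_nonzero(t < e1))
    return Trisection(axis=axis, region_areas=(a, b, c))


def compute_ai(t: Trisection) -> float:
    """Arch Index AI = B / (A + B + C)."""
    a, b, c = t.region_areas
    total = a + b + c
    if total <= 0:
        raise EmptyFootprintError("compute_ai: zero total area")
    return b / total


def classify_ai(ai: float) -> ArchClassification:
    """Classify an Arch Index with the Cavanagh & Rodgers cut-offs."""
    if not (0.0 <= ai <= 1.0):
        raise FootprintError(f"arch index must be in [0, 1], got {ai}")
    if ai >= CR_LOW_MIN:
        label = "low"
    elif ai <= CR_HIGH_MAX:
        label = "high"
    else:
        label = "normal"
    return ArchClassification(scheme="cavanagh_rodgers", score=ai, label=label)


def arch_index(fp: BinaryFootprint) -> float:
    """Convenience: AI of a print in one call (axis + trisection + ratio)."""
    return compute_ai(trisect(fp, foot_axis(fp)))
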