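"""Arch Height Index (AHI): the fitted perimeter + bending-energy model.

The arch-height score is a linear function of two contour features,

    AHI = -7.351e-05 * P - 1050.964 * MBE + 0.4597,

with P the footprint perimeter (px, boundary-count x pi/4 convention) and
MBE the mean bending energy (px^-2) at the 2 px/mm reference scale. Both
coefficients are negative: longer, more wrinkled outlines (high arches)
score lower. The score is scaled to mimic the Arch Index, so the same
three-way classification applies, with cut-offs 0.23 (high arch at or
below) and 0.27 (low arch at or above) obtained as the first and third
quartiles of the score distribution over a screening sample whose scores
were approximately Normal(0.25, 0.025).

An ordinary-least-squares refit against Arch Index targets is provided as
a calibration utility for data acquired at other scales or tracing
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .arch_index import ArchClassification
from .io import FootprintError

__all__ = [
    "AhiCoefficients",
    "CutoffScheme",
    "DEFAULT_COEFFICIENTS",
    "CR_SCHEME",
    "MBEP_SCHEME",
    "ahi_score",
    "classify_ahi",
    "derive_quartile_cutoffs",
    "fit_ahi_model",
]


@dataclass(frozen=True)
class AhiCoefficients:
    """Linear-model coefficients; defaults are the published fitted values."""

    beta_p: float = -7.351e-05
    beta_mbe: float = -1050.964
    intercept: float = 0.4597

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.beta_p, self.beta_mbe, self.intercept])):
            raise FootprintError("AHI coefficients must be finite")


@dataclass(frozen=True)
class CutoffScheme:
    """Three-way cut-offs: score <= high_max -> high arch, >= low_min -> low."""

    high_max: float
    low_min: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (self.high_max < self.low_min):
            raise FootprintError("cut-offs require high_max < low_min")


DEFAULT_COEFFICIENTS = AhiCoefficients()
CR_SCHEME = CutoffScheme(high_max=0.21, low_min=0.26, name="cavanagh_rodgers")
MBEP_SCHEME = CutoffScheme(high_max=0.23, low_min=0.27, name="mbe_p")


def ahi_score(P: float, mbe: float, coeffs: AhiCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Evaluate the linear arch-height model at perimeter P and MBE."""
    if P < 0 or mbe < 0:
        raise FootprintError("perimeter and MBE must be non-negative")
    return coeffs.beta_p * P + coeffs.beta_mbe * mbe + coeffs.intercept


def classify_ahi(ahi: float, scheme: CutoffScheme = MBEP_SCHEME) -> ArchClassification:
    """Three-way classification of an AHI score; boundaries are inclusive."""
    if not np.isfinite(ahi):
        raise FootprintError("AHI score must be finite")
    if ahi <= scheme.high_max:
        label = "high"
    elif ahi >= scheme.low_min:
        label = "low"
    else:
        label = "normal"
    return ArchClassification(scheme=scheme.name, score=ahi, label=label)


def derive_quartile_cutoffs(scores, name: str = "quartile") -> CutoffScheme:
    """First/third quartiles of a score sample as high/low cut-offs.

    Quantiles use linear interpolation between order statistics. Values are
    kept unrounded; round to 2 decimals for reporting.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise FootprintError("need at least 4 scores to derive quartile cut-offs")
    q1, q3 = np.quantile(scores, [0.25, 0.75], method="linear")
    if q1 == q3:
        raise FootprintError("degenerate score distribution: Q1 == Q3")
    return CutoffScheme(high_max=float(q1), low_min=float(q3), name=name)


def fit_ahi_model(features, targets) -> AhiCoefficients:
    """Ordinary-least-squares calibration of the AHI model.

    Parameters
    ----------
    features : array-like, shape (n, 2)
        Columns (perimeter P, mean bending energy MBE).
    targets : array-like, shape (n,)
        Reference Arch Index values.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise FootprintError("features must be an (n, 2) array of (P, MBE)")
    if X.shape[0] < 3:
        raise FootprintError("need at least 3 observations to fit the model")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FootprintError("design matrix is rank-deficient (collinear features)")
    res = sm.OLS(y, design).fit()
    const, bp, bm = res.params
    return AhiCoefficients(beta_p=float(bp), beta_mbe=float(bm), intercept=float(const))
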