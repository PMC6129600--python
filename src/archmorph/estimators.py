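"""scikit-learn-style estimators wrapping the footprint pipeline.

* :class:`FootprintFeaturizer` — stateless transformer: binary footprints
  in, a feature table (area, perimeter, circularity, wavelet second
  moment, orientation entropy, mean |curvature|, mean bending energy,
  arch index) out.
* :class:`AhiLinearModel` — the arch-height regression on (P, MBE). It is
  pre-parameterized with the published coefficients so ``predict`` works
  without fitting; ``fit`` refits by ordinary least squares against Arch
  Index targets (calibration for other scales).
* :class:`CutoffArchClassifier` / :class:`QuartileCutoffClassifier` —
  three-way high/normal/low labelling of scores by fixed or
  sample-quartile cut-offs.

These compose with sklearn pipelines and model selection; the module
functions in :mod:`archmorph.geometry`, :mod:`archmorph.gabor`,
:mod:`archmorph.curvature`, :mod:`archmorph.arch_index` and
:mod:`archmorph.ahi` are the underlying operations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import ahi as _ahi
from . import curvature as _curv
from . import gabor as _gab
from . import geometry as _geom
from .arch_index import arch_index as _arch_index
from .io import BinaryFootprint, extract_contour

__all__ = [
    "FootprintFeaturizer",
    "AhiLinearModel",
    "CutoffArchClassifier",
    "QuartileCutoffClassifier",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = (
    "area_px2",
    "perimeter_px",
    "circularity",
    "second_moment",
    "entropy",
    "mean_abs_curvature",
    "mbe",
    "arch_index",
)


def _as_footprint(x) -> BinaryFootprint:
    if isinstance(x, BinaryFootprint):
        return x
    return BinaryFootprint(mask=np.asarray(x, dtype=bool))


class FootprintFeaturizer(TransformerMixin, BaseEstimator):
    """Extract the shape-feature vector from each binary footprint.

    Parameters
    ----------
    perimeter_estimator : {"boundary_count", "chain_code"}
        Boundary-length convention; the published arch-height model is
        calibrated with ``boundary_count`` (boundary count x pi/4).
    sigma_px : float
        Gaussian scale of the curvature field, px.
    k0_mag, epsilon, n_orientations, mag_floor :
        Gabor filter-bank settings (see :class:`archmorph.gabor.GaborParams`).
    compute_gabor : bool
        Skip the (relatively costly) wavelet features when False; their
        columns are filled with NaN.
    compute_arch_index : bool
        Skip trisection for shapes without a dominant axis when False.
    """

    def __init__(
        self,
        perimeter_estimator: str = "boundary_count",
        sigma_px: float = 2.5,
        k0_mag: float = np.pi / 4,
        epsilon: float = 4.0,
        n_orientations: int = 18,
        mag_floor: float = 0.1,
        compute_gabor: bool = True,
        compute_arch_index: bool = True,
    ):
        self.perimeter_estimator = perimeter_estimator
        self.sigma_px = sigma_px
        self.k0_mag = k0_mag
        self.epsilon = epsilon
        self.n_orientations = n_orientations
        self.mag_floor = mag_floor
        self.compute_gabor = compute_gabor
        self.compute_arch_index = compute_arch_index

    def fit(self, X, y=None):
        """Stateless; validates parameters and records the input count."""
        _gab.GaborParams(
            k0_mag=self.k0_mag, epsilon=self.epsilon, n_orientations=self.n_orientations
        )
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        """Compute one feature row per footprint (list of masks/footprints)."""
        rows = [self._features_one(_as_footprint(x)) for x in X]
        return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))

    def _features_one(self, fp: BinaryFootprint) -> dict:
        contour = extract_contour(fp)
        A = _geom.area(fp)
        P = _geom.perimeter(contour, estimator=self.perimeter_estimator)
        series = _curv.contour_curvature(fp, contour, sigma_px=self.sigma_px)
        row = {
            "area_px2": A,
            "perimeter_px": P,
            "circularity": _geom.circularity(P, A),
            "mean_abs_curvature": float(np.mean(np.abs(series.k))),
            "mbe": _curv.mean_bending_energy(series),
            "second_moment": np.nan,
            "entropy": np.nan,
            "arch_index": np.nan,
        }
        if self.compute_gabor:
            g = _gab.GaborParams(
                k0_mag=self.k0_mag,
                epsilon=self.epsilon,
                n_orientations=self.n_orientations,
                mag_floor=self.mag_floor,
            )
            w = _gab.wavelet_transform(fp, g)
            row["second_moment"] = _gab.second_moment(w, fp)
            hist = _gab.orientation_histogram(
                w, fp, K=self.n_orientations, mag_floor=self.mag_floor
            )
            row["entropy"] = _gab.entropy(hist)
        if self.compute_arch_index:
            row["arch_index"] = _arch_index(fp)
        return row

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_COLUMNS, dtype=object)


class AhiLinearModel(RegressorMixin, BaseEstimator):
    """Linear arch-height score on (perimeter, mean bending energy).

    Defaults to the published coefficients, so the estimator predicts
    without fitting; calling :meth:`fit` re-estimates them by OLS.
    """

    def __init__(
        self,
        beta_p: float = _ahi.DEFAULT_COEFFICIENTS.beta_p,
        beta_mbe: float = _ahi.DEFAULT_COEFFICIENTS.beta_mbe,
        intercept: float = _ahi.DEFAULT_COEFFICIENTS.intercept,
    ):
        self.beta_p = beta_p
        self.beta_mbe = beta_mbe
        self.intercept = intercept

    def fit(self, X, y):
        coeffs = _ahi.fit_ahi_model(np.asarray(X, dtype=float), y)
        self.coef_ = np.array([coeffs.beta_p, coeffs.beta_mbe])
        self.intercept_ = coeffs.intercept
        self.n_features_in_ = 2
        return self

    def _coefficients(self) -> _ahi.AhiCoefficients:
        if hasattr(self, "coef_"):
            return _ahi.AhiCoefficients(
                beta_p=float(self.coef_[0]),
                beta_mbe=float(self.coef_[1]),
                intercept=float(self.intercept_),
            )
        return _ahi.AhiCoefficients(self.beta_p, self.beta_mbe, self.intercept)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (P, MBE)")
        c = self._coefficients()
        return c.beta_p * X[:, 0] + c.beta_mbe * X[:, 1] + c.intercept


class CutoffArchClassifier(ClassifierMixin, BaseEstimator):
    """Label scores high/normal/low with fixed, boundary-inclusive cut-offs."""

    def __init__(self, high_max: float = 0.23, low_min: float = 0.27, scheme: str = "mbe_p"):
        self.high_max = high_max
        self.low_min = low_min
        self.scheme = scheme

    def fit(self, X, y=None):
        _ahi.CutoffScheme(self.high_max, self.low_min, self.scheme)  # validates ordering
        self.classes_ = np.array(["high", "low", "normal"])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        scores = np.asarray(X, dtype=float).reshape(-1)
        labels = np.where(
            scores <= self.high_max, "high", np.where(scores >= self.low_min, "low", "normal")
        )
        return labels.astype(object)


class QuartileCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Cut-offs from the first/third quartiles of the training scores."""

    def __init__(self, scheme: str = "quartile"):
        self.scheme = scheme

    def fit(self, X, y=None):
        scores = np.asarray(X, dtype=float).reshape(-1)
        cutoffs = _ahi.derive_quartile_cutoffs(scores, name=self.scheme)
        self.high_max_ = cutoffs.high_max
        self.low_min_ = cutoffs.low_min
        self.classes_ = np.array(["high", "low", "normal"])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        scores = np.asarray(X, dtype=float).reshape(-1)
        labels = np.where(
            scores <= self.high_max_, "high", np.where(scores >= self.low_min_, "low", "normal")
        )
        return labels.astype(object)
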