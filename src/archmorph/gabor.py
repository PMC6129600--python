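"""Gabor-wavelet orientation analysis of the footprint raster.

The filter bank consists of K oriented complex Gabor kernels

    psi(x) = exp(j k0 . x_theta) * exp(-1/2 |A x_theta|^2),
    A = diag(eps^{-1/2}, 1),  eps >= 1,

i.e. a complex exponential under an anisotropic Gaussian envelope whose
long axis (std sqrt(eps)) lies along the filter orientation theta and whose
oscillation runs perpendicular to it, so filter theta responds maximally to
stripe-like structure oriented at theta. Each kernel is mean-corrected
(its complex mean subtracted) so constant regions give (near-)zero
response.

Two scalar features are derived from the transform:

* the raw second moment of the response magnitude over the foreground, and
* the Shannon entropy (nats) of the histogram of dominant orientations,
  a measure of orientation disorder of the print.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .io import BinaryFootprint, EmptyFootprintError, FootprintError

__all__ = [
    "GaborParams",
    "WaveletResponse",
    "OrientationHistogram",
    "gabor_kernel",
    "wavelet_transform",
    "second_moment",
    "orientation_histogram",
    "entropy",
]


@dataclass
class GaborParams:
    """Filter-bank parameters.

    k0_mag : spatial frequency of the carrier, rad/px (default pi/4, i.e.
        an 8 px wavelength at the 2 px/mm reference scale — 4 mm stripes).
    epsilon : envelope anisotropy (>= 1); the envelope std is sqrt(epsilon)
        along the orientation and 1 across it.
    n_orientations : number K of evenly spaced orientations on [0, pi).
    kernel_support_px : square kernel side; default covers 6 envelope stds.
    mag_floor : fraction of the peak magnitude below which pixels are
        excluded from the orientation histogram.
    """

    k0_mag: float = np.pi / 4
    epsilon: float = 4.0
    n_orientations: int = 18
    kernel_support_px: int | None = None
    mag_floor: float = 0.1

    def __post_init__(self) -> None:
        if not (self.k0_mag > 0):
            raise FootprintError("k0_mag must be positive")
        if self.epsilon < 1:
            raise FootprintError("epsilon must be >= 1")
        if self.n_orientations < 2:
            raise FootprintError("n_orientations must be >= 2")
        if self.kernel_support_px is None:
            self.kernel_support_px = 2 * int(np.ceil(3.0 * max(np.sqrt(self.epsilon), 1.0))) + 1

    @property
    def thetas(self) -> np.ndarray:
        K = self.n_orientations
        return np.arange(K) * np.pi / K


@dataclass
class WaveletResponse:
    """Per-pixel maximum response magnitude and dominant orientation."""

    magnitude: np.ndarray  # max over orientations of |W_theta|, >= 0
    dominant_theta: np.ndarray  # argmax orientation, in [0, pi)


@dataclass
class OrientationHistogram:
    """Normalized K-bin frequency vector of dominant orientations."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise FootprintError("histogram frequencies must be >= 0 and sum to 1")


def gabor_kernel(g: GaborParams, theta: float, mean_correct: bool = True) -> np.ndarray:
    """Complex Gabor kernel at orientation ``theta`` (radians).

    With x = (col, row) and local frame (u along theta, v across it), the
    kernel is exp(j*k0*v) * exp(-1/2 (u^2/eps + v^2)). ``mean_correct``
    subtracts the complex mean so the kernel sums to zero.
    """
    half = g.kernel_support_px // 2
    if half < np.ceil(3.0 * np.sqrt(g.epsilon)):
        warnings.warn("kernel support smaller than 3 envelope stds; response truncated", stacklevel=2)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    c, s = np.cos(theta), np.sin(theta)
    u = xx * c + yy * s  # along the orientation (envelope long axis)
    v = -xx * s + yy * c  # across it (carrier direction)
    psi = np.exp(1j * g.k0_mag * v) * np.exp(-0.5 * (u * u / g.epsilon + v * v))
    if mean_correct:
        psi = psi - psi.mean()
    return psi


def wavelet_transform(fp: BinaryFootprint, g: GaborParams | None = None) -> WaveletResponse:
    """Convolve the mask with the oriented bank; keep per-pixel max and argmax.

    Convolution is performed in the frequency domain (zero-padded), which
    agrees with direct convolution to floating-point accuracy.
    """
    g = g or GaborParams()
    if not fp.mask.any():
        raise EmptyFootprintError("wavelet_transform: empty footprint")
    img = fp.mask.astype(float)
    # replicate-pad so the canvas border itself produces no spurious edge
    # response (a constant image transforms to ~0 everywhere)
    half = g.kernel_support_px // 2
    padded = np.pad(img, half, mode="edge")
    best_mag = np.zeros_like(img)
    best_idx = np.zeros(img.shape, dtype=np.intp)
    for k, theta in enumerate(g.thetas):
        full = np.abs(fftconvolve(padded, gabor_kernel(g, theta), mode="same"))
        resp = full[half:-half, half:-half] if half else full
        better = resp > best_mag
        best_mag[better] = resp[better]
        best_idx[better] = k
    return WaveletResponse(magnitude=best_mag, dominant_theta=g.thetas[best_idx])


def second_moment(w: WaveletResponse, fp: BinaryFootprint) -> float:
    """Raw second moment of the response magnitude over the foreground."""
    mask = fp.mask
    if not mask.any():
        raise EmptyFootprintError("second_moment: empty footprint")
    return float(np.mean(w.magnitude[mask] ** 2))


def orientation_histogram(
    w: WaveletResponse,
    fp: BinaryFootprint,
    K: int = 18,
    mag_floor: float = 0.1,
) -> OrientationHistogram:
    """K-bin histogram of dominant orientations over strong foreground pixels.

    Pixels with magnitude below ``mag_floor`` x (peak magnitude) carry
    essentially arbitrary orientation and are excluded.
    """
    if K < 2:
        raise FootprintError("K must be >= 2")
    mask = fp.mask
    sel = mask & (w.magnitude >= mag_floor * w.magnitude.max())
    if not sel.any():
        raise FootprintError("orientation_histogram: no pixel passes the magnitude floor")
    # K equal bins on [0, pi), left-closed; the small offset keeps angles
    # that sit exactly on a bin edge (the bank's own orientations) from
    # dropping one bin under floating-point round-off
    idx = np.floor(w.dominant_theta[sel] * K / np.pi + 1e-9).astype(int) % K
    counts = np.bincount(idx, minlength=K)
    return OrientationHistogram(p=counts / counts.sum())


def entropy(h: OrientationHistogram) -> float:
    """Shannon entropy -sum p_i ln p_i in nats; 0*ln 0 taken as 0."""
    p = h.p[h.p > 0]
    return float(-np.sum(p * np.log(p)))
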