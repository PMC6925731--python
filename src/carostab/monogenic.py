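"""Monogenic-signal features: DoG bandpass, Riesz transform, local phase/orientation.

The monogenic signal extends the 1D analytic signal to images: an isotropic
bandpass response f together with its two Riesz components (r_x, r_y) gives a
local amplitude A = sqrt(f^2 + r_x^2 + r_y^2), a local phase
phi = atan2(sqrt(r_x^2 + r_y^2), f) in [0, pi] describing structure type
(ridge vs edge), and a local orientation theta = atan(r_y/r_x) folded to
[0, pi].  Phase and orientation are invariant to image brightness and
contrast, which is what makes them good registration surfaces for ultrasound.

Orientation is unreliable where the phase is near 0 or pi (ridge centre
lines), so a confidence coefficient sin^2(phi) weights the orientation into
the combined image C = sin^2(phi) * theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ArgumentError

_SQRT2 = float(np.sqrt(2.0))

FEATURE_MODES = ("intensity", "phase", "orientation", "combined")


@dataclass
class MonogenicConfig:
    """DoG bandpass parameters.

    sigma1/sigma2 are the standard deviations (px) of the two Gaussians;
    sigma2 defaults to sqrt(2)*sigma1.  The centre mu is kept at 0.  The
    discrete kernels are unit-normalized, so the difference has zero DC gain.
    """

    sigma1: float = 10.0
    sigma2: float | None = None
    mu: float = 0.0
    eps_rel: float = 1e-9  # amplitude floor (relative to max A) for degeneracy
    #: orientation is axial (theta ~ theta + pi), so pointwise estimates are
    #: regularized by smoothing the confidence-weighted double-angle field
    #: (cos 2theta, sin 2theta) before folding back; 0 disables
    orientation_smooth_px: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma2 is None:
            self.sigma2 = _SQRT2 * self.sigma1
        if not 0 < self.sigma1 < self.sigma2:
            raise ArgumentError("need 0 < sigma1 < sigma2")


@dataclass
class LocalVectorImage:
    """Per-pixel monogenic feature planes of one image."""

    f: np.ndarray
    r_x: np.ndarray
    r_y: np.ndarray
    A: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    confidence: np.ndarray


def dog_kernel(sigma1: float, sigma2: float, mu: float = 0.0,
               truncate: float = 4.0) -> np.ndarray:
    """Discrete 1D difference-of-Gaussians kernel (each Gaussian unit-mass)."""
    radius = int(truncate * sigma2 + 0.5 + abs(mu))
    x = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-0.5 * ((x - mu) / sigma1) ** 2)
    g2 = np.exp(-0.5 * ((x - mu) / sigma2) ** 2)
    return g1 / g1.sum() - g2 / g2.sum()


def dog_bandpass(I: np.ndarray, config: MonogenicConfig) -> np.ndarray:
    """Isotropic (separable) DoG bandpass of the image; zero DC response."""
    I = np.asarray(I, dtype=float)
    out = np.empty_like(I)
    for sigma, sign in ((config.sigma1, 1.0), (config.sigma2, -1.0)):
        radius = int(4.0 * sigma + 0.5 + abs(config.mu))
        x = np.arange(-radius, radius + 1, dtype=float)
        g = np.exp(-0.5 * ((x - config.mu) / sigma) ** 2)
        g /= g.sum()
        plane = ndimage.convolve1d(I, g, axis=0, mode="reflect")
        plane = ndimage.convolve1d(plane, g, axis=1, mode="reflect")
        if sign > 0:
            out[:] = plane
        else:
            out -= plane
    return out


def riesz_kernels(shape: tuple) -> tuple:
    """Frequency-domain Riesz multipliers (H_u, H_v) for the given shape.

    u is the longitudinal (column) frequency and v the radial (row)
    frequency; the undefined origin multiplier is set to 0.
    """
    rows, cols = shape
    v = np.fft.fftfreq(rows)[:, None]
    u = np.fft.fftfreq(cols)[None, :]
    mag = np.hypot(u, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        hu = np.where(mag > 0, -1j * u / mag, 0.0)
        hv = np.where(mag > 0, -1j * v / mag, 0.0)
    return hu, hv


def riesz(f: np.ndarray) -> tuple:
    """Riesz transform pair (r_x, r_y) of a real image, via the FFT."""
    f = np.asarray(f, dtype=float)
    hu, hv = riesz_kernels(f.shape)
    F = np.fft.fft2(f)
    r_x = np.fft.ifft2(F * hu).real
    r_y = np.fft.ifft2(F * hv).real
    return r_x, r_y


def local_features(f: np.ndarray, r_x: np.ndarray, r_y: np.ndarray,
                   eps_rel: float = 1e-9) -> LocalVectorImage:
    """Local amplitude, phase, orientation and confidence from (f, r_x, r_y).

    phi = atan2(sqrt(r_x^2 + r_y^2), f) in [0, pi];
    theta = atan(r_y / r_x) folded into [0, pi) (axial orientation);
    confidence = sin^2(phi).  Pixels with amplitude below ``eps_rel * max A``
    get phi = pi/2, theta = 0 and confidence 0 (no reliable structure).
    """
    f = np.asarray(f, dtype=float)
    if f.shape != np.shape(r_x) or f.shape != np.shape(r_y):
        raise ArgumentError("feature planes must share one shape")
    r_mag = np.hypot(r_x, r_y)
    A = np.sqrt(f**2 + r_x**2 + r_y**2)
    phi = np.arctan2(r_mag, f)
    theta = np.mod(np.arctan2(r_y, r_x), np.pi)
    conf = np.sin(phi) ** 2
    degenerate = A < eps_rel * (A.max() if A.size else 0.0)
    phi = np.where(degenerate, np.pi / 2.0, phi)
    theta = np.where(degenerate, 0.0, theta)
    conf = np.where(degenerate, 0.0, conf)
    return LocalVectorImage(f, np.asarray(r_x, float), np.asarray(r_y, float),
                            A, phi, theta, conf)


def combine(lvi: LocalVectorImage, embedding: bool = False):
    """Confidence-weighted orientation image C = sin^2(phi) * theta.

    With ``embedding=True`` returns the two-plane axial embedding
    (sin^2(phi) cos 2theta, sin^2(phi) sin 2theta) instead, which avoids the
    0/pi wrap of the scalar product form.
    """
    if embedding:
        return (lvi.confidence * np.cos(2 * lvi.theta),
                lvi.confidence * np.sin(2 * lvi.theta))
    return lvi.confidence * lvi.theta


def smooth_orientation(theta: np.ndarray, confidence: np.ndarray,
                       sigma_px: float) -> np.ndarray:
    """Regularized axial orientation: smooth the weighted double-angle field.

    Pointwise theta estimates wrap at 0/pi, so plain smoothing is wrong;
    averaging (w cos 2theta, w sin 2theta) and folding back is the standard
    estimator for axial data.
    """
    cw = ndimage.gaussian_filter(confidence * np.cos(2.0 * theta), sigma_px)
    sw = ndimage.gaussian_filter(confidence * np.sin(2.0 * theta), sigma_px)
    return np.mod(0.5 * np.arctan2(sw, cw), np.pi)


def analyze(I: np.ndarray, config: MonogenicConfig | None = None) -> LocalVectorImage:
    """DoG bandpass + Riesz transform + local feature extraction in one call.

    Applies the double-angle orientation regularization configured in
    ``config.orientation_smooth_px`` to the theta plane.
    """
    config = config or MonogenicConfig()
    f = dog_bandpass(I, config)
    r_x, r_y = riesz(f)
    lvi = local_features(f, r_x, r_y, eps_rel=config.eps_rel)
    if config.orientation_smooth_px > 0:
        lvi.theta = smooth_orientation(lvi.theta, lvi.confidence,
                                       config.orientation_smooth_px)
    return lvi


def make_feature_image(I: np.ndarray, config: MonogenicConfig | None = None,
                       mode: str = "combined") -> np.ndarray:
    """Feature surface used for registration: intensity, phase, orientation or combined."""
    if mode not in FEATURE_MODES:
        raise ArgumentError(f"unknown feature mode {mode!r}; "
                            f"expected one of {FEATURE_MODES}")
    I = np.asarray(I, dtype=float)
    if mode == "intensity":
        return I
    lvi = analyze(I, config)
    if mode == "phase":
        return lvi.phi
    if mode == "orientation":
        return lvi.theta
    return combine(lvi)
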