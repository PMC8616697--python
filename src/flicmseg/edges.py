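"""Canny edge detection from separable Gaussian smoothing and 2x2 discrete
gradients, plus filter-quality diagnostics.

The detector chain is: separable Gaussian smoothing -> forward-averaged 2x2
difference gradients

    E_x(i,j) = [I(i,j+1) - I(i,j) + I(i+1,j+1) - I(i+1,j)] / 2
    E_y(i,j) = [I(i,j)   - I(i+1,j) + I(i,j+1) - I(i+1,j+1)] / 2

with magnitude M = sqrt(E_x^2 + E_y^2) and full-quadrant direction
eta = atan2(E_y, E_x) -> non-maximum suppression along the quantized
gradient direction -> double-threshold hysteresis (weak edges kept only
when 8-connected to a strong edge). The gradient grid is (H-1) x (W-1),
with each value assigned to the top-left pixel of its 2x2 block.

The classical filter-design criteria (edge response, noise response,
localization accuracy, zero-crossing spacing) are provided as diagnostics
of a supplied 1-D kernel; they are not optimized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .containers import ImageGrid, as_pixels
from .exceptions import ContractError, InvalidSpecError

__all__ = [
    "GaussianKernel",
    "GradientField",
    "EdgeMap",
    "FilterDiagnostics",
    "gaussian_kernel",
    "gaussian_smooth",
    "image_gradients",
    "canny",
    "filter_diagnostics",
]


@dataclass
class GaussianKernel:
    """Discretized, unit-sum 1-D Gaussian."""

    sigma: float
    radius: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)


@dataclass
class GradientField:
    """Discrete image gradients on the (H-1) x (W-1) grid."""

    ex: np.ndarray
    ey: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray


@dataclass
class EdgeMap:
    """Binary edge raster with the thresholds that produced it.

    ``edges`` lives on the full H x W grid; detections occupy the
    (H-1) x (W-1) gradient region (top-left assignment), the last row and
    column are always False.
    """

    edges: np.ndarray
    low_thresh: float
    high_thresh: float


@dataclass
class FilterDiagnostics:
    """Classical filter-design functionals of a 1-D kernel."""

    edge_response: float          # F_G = int G(-x) H(x) dx
    noise_response: float         # F_Z = sigma * sqrt(int H^2)
    localization: float           # D   = |int G' H'| / (sigma sqrt(int H'^2))
    zero_crossing_spacing: float  # S(f) = pi sqrt(int H'^2 / int H''^2)


def gaussian_kernel(sigma: float, radius: int | None = None) -> GaussianKernel:
    """Sampled 1-D Gaussian normalized to unit sum."""
    if not sigma > 0:
        raise InvalidSpecError("sigma must be positive")
    if radius is None:
        radius = max(1, int(round(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-x * x / (2.0 * sigma * sigma))
    return GaussianKernel(sigma=float(sigma), radius=int(radius), weights=w / w.sum())


def gaussian_smooth(image, sigma: float) -> ImageGrid:
    """Separable Gaussian smoothing (reflective borders).

    The 2-D convolution with the isotropic Gaussian factors into two 1-D
    passes; a unit-sum kernel leaves constant images unchanged.
    """
    x = as_pixels(image)
    k = gaussian_kernel(sigma)
    out = ndi.correlate1d(x, k.weights, axis=0, mode="reflect")
    out = ndi.correlate1d(out, k.weights, axis=1, mode="reflect")
    peak = image.peak if isinstance(image, ImageGrid) else 255.0
    return ImageGrid(out, peak)


def image_gradients(image) -> GradientField:
    """Forward-averaged 2x2 difference gradients with magnitude/direction."""
    x = as_pixels(image)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ContractError("image must be at least 2x2 for gradients")
    ex = 0.5 * (x[:-1, 1:] - x[:-1, :-1] + x[1:, 1:] - x[1:, :-1])
    ey = 0.5 * (x[:-1, :-1] - x[1:, :-1] + x[:-1, 1:] - x[1:, 1:])
    mag = np.hypot(ex, ey)
    direction = np.arctan2(ey, ex)
    return GradientField(ex=ex, ey=ey, magnitude=mag, direction=direction)


def _non_maximum_suppression(mag: np.ndarray, ex: np.ndarray, ey: np.ndarray) -> np.ndarray:
    # Gradient direction in array (row, col) coordinates: E_y is a *negative*
    # row difference, so the array-space angle is atan2(-E_y, E_x).
    ang = np.arctan2(-ey, ex)
    a = np.mod(ang, np.pi)
    sector = np.floor((a + np.pi / 8) / (np.pi / 4)).astype(int) % 4
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    padded = np.pad(mag, 1, mode="constant")
    keep = np.zeros_like(mag, dtype=bool)
    h, w = mag.shape
    for s, (dr, dc) in offsets.items():
        sel = sector == s
        fwd = padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
        bwd = padded[1 - dr:1 - dr + h, 1 - dc:1 - dc + w]
        keep |= sel & (mag >= fwd) & (mag >= bwd)
    return keep & (mag > 0)


def canny(image, sigma: float = 1.4, low: float | None = None,
          high: float | None = None) -> EdgeMap:
    """Full Canny chain: smooth, differentiate, suppress, hysteresis.

    ``low``/``high`` are absolute magnitude thresholds; when omitted they
    default to 0.1 and 0.2 of the maximum gradient magnitude. Weak edges
    (>= low) survive only when 8-connected to a strong edge (>= high).
    """
    smoothed = gaussian_smooth(image, sigma)
    g = image_gradients(smoothed)
    mmax = float(g.magnitude.max())
    if low is None:
        low = 0.1 * mmax
    if high is None:
        high = 0.2 * mmax
    if not (high >= low >= 0):
        raise InvalidSpecError("need high >= low >= 0")
    nms = _non_maximum_suppression(g.magnitude, g.ex, g.ey)
    if mmax == 0.0:
        grid = np.zeros_like(g.magnitude, dtype=bool)
    else:
        weak = nms & (g.magnitude >= low) & (g.magnitude > 0)
        strong = weak & (g.magnitude >= high)
        lab, n = ndi.label(weak, structure=np.ones((3, 3), dtype=int))
        if n:
            keep_ids = np.unique(lab[strong])
            keep_ids = keep_ids[keep_ids > 0]
            grid = np.isin(lab, keep_ids)
        else:
            grid = np.zeros_like(weak)
    h, w = as_pixels(image).shape
    edges = np.zeros((h, w), dtype=bool)
    edges[: h - 1, : w - 1] = grid
    return EdgeMap(edges=edges, low_thresh=float(low), high_thresh=float(high))


def filter_diagnostics(x: np.ndarray, kernel: np.ndarray, *,
                       noise_sigma: float = 1.0,
                       edge_profile: np.ndarray | None = None) -> FilterDiagnostics:
    """Numerically evaluate the four filter-design functionals.

    Parameters
    ----------
    x : 1-D grid (symmetric about 0, finite support [-w, w]) on which the
        impulse response is sampled.
    kernel : samples of the impulse response H(x) on ``x``.
    noise_sigma : standard deviation of the Gaussian noise model.
    edge_profile : samples of the edge function G(x) on ``x``; defaults to
        a unit step at the origin.

    Integrals use the trapezoidal rule on the sampled grid; derivatives are
    second-order finite differences.
    """
    x = np.asarray(x, dtype=np.float64)
    h = np.asarray(kernel, dtype=np.float64)
    if x.shape != h.shape or x.ndim != 1 or x.size < 3:
        raise ContractError("grid and kernel must be matching 1-D arrays (>= 3 samples)")
    if not np.allclose(x, -x[::-1], atol=1e-9):
        raise ContractError("sample grid must be symmetric about 0")
    if edge_profile is None:
        g = (x >= 0).astype(np.float64)
    else:
        g = np.asarray(edge_profile, dtype=np.float64)
        if g.shape != x.shape:
            raise ContractError("edge profile must be sampled on the same grid")
    energy = np.trapezoid(h * h, x)
    if energy <= 0:
        raise ContractError("zero-energy kernel")
    g_neg = g[::-1]  # G(-x) on a symmetric grid
    f_g = float(np.trapezoid(g_neg * h, x))
    f_z = float(noise_sigma * np.sqrt(energy))
    dh = np.gradient(h, x)
    dg_neg = np.gradient(g_neg, x)
    d_num = abs(np.trapezoid(dg_neg * dh, x))
    d_den = noise_sigma * np.sqrt(np.trapezoid(dh * dh, x))
    loc = float(d_num / d_den) if d_den > 0 else float("inf")
    d2h = np.gradient(dh, x)
    num = np.trapezoid(dh * dh, x)
    den = np.trapezoid(d2h * d2h, x)
    spacing = float(np.pi * np.sqrt(num / den)) if den > 0 else float("inf")
    return FilterDiagnostics(edge_response=f_g, noise_response=f_z,
                             localization=loc, zero_crossing_spacing=spacing)
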