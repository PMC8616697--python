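"""Synthetic brain-slice phantoms with ground-truth tissue labels.

The phantom emulates a T1-like axial slice: an elliptical head, a bright
skull ring, a gray-matter cortical band, a white-matter interior, and a
central H-shaped cerebrospinal-fluid region (the lateral-ventricle pattern
targeted by the H-region identification step). Geometry is procedurally
jittered from a seed so that replicate noise-robustness experiments can be
run without any external data. Images are piecewise constant at the class
means; calibrated Gaussian or salt-and-pepper noise is injected separately
by :func:`add_noise`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .containers import ImageGrid, LabelMap
from .exceptions import InvalidSpecError

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "generate_phantom",
    "add_noise",
    "render_h_mask",
    "BACKGROUND",
    "SKULL",
    "WM",
    "GM",
    "CSF",
    "CLASS_NAMES",
    "DEFAULT_CLASS_MEANS",
]

# Tissue class indices in the truth label map.
BACKGROUND, SKULL, WM, GM, CSF = range(5)
CLASS_NAMES = ("background", "skull", "white_matter", "gray_matter", "csf")

# T1-like ordering: white matter bright, gray matter intermediate, CSF dark,
# skull (marrow/scalp composite) brightest, background air ~0. Pairwise gaps
# are >= 30 intensity units so the noiseless phantom is exactly separable by
# intensity thresholding.
DEFAULT_CLASS_MEANS = (0.0, 230.0, 190.0, 125.0, 60.0)


@dataclass
class PhantomSpec:
    """Geometry and intensity specification for one phantom slice."""

    height: int = 128
    width: int = 128
    class_means: tuple[float, ...] = DEFAULT_CLASS_MEANS
    geometry_seed: int = 0
    include_h_region: bool = True
    include_decoy: bool = False
    skull_thickness: int = 3

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise InvalidSpecError("phantom dimensions must be at least 32x32")
        means = tuple(float(v) for v in self.class_means)
        if len(means) != 5:
            raise InvalidSpecError("class_means must list 5 values (bg, skull, WM, GM, CSF)")
        if len(set(means)) != 5:
            raise InvalidSpecError("class_means must be pairwise distinct")
        if min(means) < 0 or max(means) > 255:
            raise InvalidSpecError("class_means must lie in [0, 255]")
        self.class_means = means
        if self.skull_thickness < 1:
            raise InvalidSpecError("skull_thickness must be >= 1 pixel")
        if self.include_decoy and min(self.height, self.width) < 64:
            raise InvalidSpecError("decoy placement requires at least 64x64")


@dataclass
class NoiseSpec:
    """Noise model: additive Gaussian (level = std dev on the intensity
    scale) or salt-and-pepper (level = corruption density in [0, 1])."""

    kind: str = "gaussian"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "salt_pepper"):
            raise InvalidSpecError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise InvalidSpecError("noise level must be nonnegative")
        if self.kind == "salt_pepper" and self.level > 1:
            raise InvalidSpecError("salt-and-pepper density must be <= 1")


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def render_h_mask(height: int, width: int, center: tuple[float, float] | None = None) -> np.ndarray:
    """Render the letter-H region used for the CSF ventricle pattern.

    Two vertical bars joined by a horizontal crossbar, centered in the frame
    (or at ``center``), with dimensions scaling with the frame size. This is
    also the source of the default template descriptor for H-region matching.
    """
    h, w = height, width
    cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    bar_w = max(3, round(0.095 * w))
    bar_h = max(9, round(0.36 * h))
    offset = max(bar_w, round(0.125 * w))  # bar-center distance from midline
    cross_h = max(3, round(0.06 * h))
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for side in (-1.0, 1.0):
        bx = cx + side * offset
        mask |= (np.abs(xx - bx) <= bar_w / 2.0) & (np.abs(yy - cy) <= bar_h / 2.0)
    mask |= (np.abs(xx - cx) <= offset) & (np.abs(yy - cy) <= cross_h / 2.0)
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[ImageGrid, LabelMap]:
    """Generate one phantom slice and its ground-truth label map.

    The image is piecewise constant at ``spec.class_means`` over the truth
    labels. Geometry (head ellipse axes) is jittered ±10% from
    ``spec.geometry_seed``; the call is bit-deterministic for a fixed spec.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.geometry_seed)
    jy, jx = rng.uniform(0.9, 1.1, size=2)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # a head slice is never clipped by the frame: cap the jittered axes
    ry = min(0.46 * h * jy, h / 2.0 - 4.0)
    rx = min(0.42 * w * jx, w / 2.0 - 4.0)

    labels = np.zeros((h, w), dtype=np.int64)
    head = _ellipse(h, w, cy, cx, ry, rx)
    t = spec.skull_thickness
    brain = _ellipse(h, w, cy, cx, ry - t, rx - t)
    gm_band = max(6, round(0.08 * min(h, w)))
    wm = _ellipse(h, w, cy, cx, ry - t - gm_band, rx - t - gm_band)

    labels[head] = SKULL
    labels[brain] = GM
    labels[wm] = WM

    # CSF structures are lined with a 2-px gray-matter band (the deep gray
    # nuclei — caudate, thalamus — that border the lateral ventricles in an
    # axial T1 slice), so within the brain only adjacent-intensity tissue
    # pairs (CSF|GM, GM|WM) ever share a boundary.
    lining = np.ones((5, 5), dtype=bool)

    if spec.include_h_region:
        h_mask = render_h_mask(h, w, center=(cy, cx)) & brain
        labels[ndi.binary_dilation(h_mask, structure=lining) & brain] = GM
        labels[h_mask] = CSF

    if spec.include_decoy:
        # Disk-shaped CSF decoy on the vertical axis inside white matter,
        # clear of the H region (used by shape-matching experiments).
        r = max(3, round(0.04 * min(h, w)))
        dy = round(0.25 * h)
        decoy = _ellipse(h, w, cy - dy, cx, r, r) & wm
        labels[ndi.binary_dilation(decoy, structure=lining) & brain] = GM
        labels[decoy] = CSF

    means = np.asarray(spec.class_means, dtype=np.float64)
    image = means[labels]
    return ImageGrid(image, peak=255.0), LabelMap(labels, class_names=CLASS_NAMES)


def add_noise(image: ImageGrid, noise: NoiseSpec) -> ImageGrid:
    """Inject seeded noise into a copy of ``image``.

    Gaussian: independent additive N(0, level^2) per pixel, clipped to
    [0, peak]. Salt-and-pepper: a fraction ``level`` of pixels replaced by 0
    or ``peak`` with equal probability. Pure function of (image, noise).
    """
    if not isinstance(noise, NoiseSpec):
        noise = NoiseSpec(**noise)
    x = image.pixels
    if noise.level == 0:
        return image.copy()
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "gaussian":
        out = x + rng.normal(0.0, noise.level, size=x.shape)
        out = np.clip(out, 0.0, image.peak)
    else:
        out = x.copy()
        corrupt = rng.random(x.shape) < noise.level
        salt = rng.random(x.shape) < 0.5
        out[corrupt & salt] = image.peak
        out[corrupt & ~salt] = 0.0
    return ImageGrid(out, image.peak)
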