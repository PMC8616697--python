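"""Core in-memory containers shared by every module.

All raster data is carried as plain ``numpy`` arrays wrapped in light
dataclasses that record the minimal metadata the algorithms need (the
representable peak intensity for PSNR, class names for label maps, the
closed/ordered contract for contours).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError, InvalidSpecError

__all__ = ["ImageGrid", "LabelMap", "MembershipField", "Contour", "as_pixels"]


@dataclass
class ImageGrid:
    """A 2-D grayscale raster.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite real intensities.
    peak : float
        Maximum representable intensity M (e.g. 255 for 8-bit data); used as
        the peak signal in PSNR and for the SSIM stabilizing constants.
    """

    pixels: np.ndarray
    peak: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InvalidSpecError(f"ImageGrid requires a 2-D array, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidSpecError("ImageGrid pixels must be finite")
        if not self.peak > 0:
            raise InvalidSpecError("ImageGrid peak must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.pixels.copy(), self.peak)


@dataclass
class LabelMap:
    """Integer per-pixel class assignment.

    Labels are nonnegative class indices; ``-1`` marks pixels outside the
    analysis mask (e.g. outside the stripped brain).
    """

    labels: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidSpecError("LabelMap requires a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.labels == class_id


@dataclass
class MembershipField:
    """Per-pixel fuzzy memberships, shape (H, W, K).

    Each valid pixel's memberships lie in [0, 1] and sum to 1; pixels outside
    the analysis mask carry all-zero rows.
    """

    mu: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        if self.mu.ndim != 3:
            raise InvalidSpecError("MembershipField requires an (H, W, K) array")

    @property
    def n_clusters(self) -> int:
        return self.mu.shape[2]

    def validate(self, atol: float = 1e-10) -> None:
        """Raise if any nonzero row is not normalized or out of range."""
        if self.mu.min() < -atol or self.mu.max() > 1 + atol:
            raise ContractError("memberships outside [0, 1]")
        sums = self.mu.sum(axis=2)
        live = sums > 0.5
        if not np.allclose(sums[live], 1.0, atol=atol):
            raise ContractError("memberships of in-mask pixels must sum to 1")


@dataclass
class Contour:
    """Ordered closed boundary of a pixel region.

    ``points`` holds (x, y) = (column, row) coordinates, one per boundary
    step, without repeating the start point at the end. Consecutive points
    are 8-connected; orientation is counterclockwise in (x, y) coordinates
    (positive shoelace area) whenever the contour encloses area.
    """

    points: np.ndarray
    n_components: int = 1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidSpecError("Contour requires an (N, 2) array of (x, y) points")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def signed_area(self) -> float:
        x = self.points[:, 0]
        y = self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def reversed(self) -> "Contour":
        pts = np.vstack([self.points[:1], self.points[1:][::-1]])
        return Contour(pts, self.n_components)


def as_pixels(image) -> np.ndarray:
    """Return the raw 2-D float array behind an ImageGrid or array-like."""
    if isinstance(image, ImageGrid):
        return image.pixels
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ContractError("expected a 2-D image")
    return arr
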