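"""Segmentation-overlap and image-quality metrics.

Overlap metrics compare a predicted class mask B against the reference mask
A: Jaccard = |A∩B| / |A∪B| and Dice = 2|A∩B| / (|A| + |B|), related by
Dice = 2J / (1 + J). Image quality uses PSNR = 10 log10(M^2 / MSE) with M
the declared peak intensity, and SSIM as the mean over sliding windows of
the luminance/contrast/structure product

    L = (2 mu_a mu_b + c1) / (mu_a^2 + mu_b^2 + c1)
    C = (2 s_a s_b + c2)  / (s_a^2 + s_b^2 + c2)
    S = (cov_ab + c3)     / (s_a s_b + c3)

with the standard constants c1 = (0.01 M)^2, c2 = (0.03 M)^2, c3 = c2/2 and
a 7x7 uniform window (valid-mode aggregation). Pixel accuracy is the
fraction of identically labeled pixels after label matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .containers import ImageGrid, LabelMap, as_pixels
from .exceptions import ContractError

__all__ = ["MetricReport", "jaccard", "dice", "psnr", "ssim", "pixel_accuracy",
           "evaluate_segmentation"]


def _masks(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ContractError("masks must share a shape")
    return a, b


def jaccard(truth_mask, pred_mask) -> float:
    """|A∩B| / |A∪B|; two empty masks agree perfectly (1.0)."""
    a, b = _masks(truth_mask, pred_mask)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def dice(truth_mask, pred_mask) -> float:
    """2|A∩B| / (|A| + |B|); two empty masks agree perfectly (1.0)."""
    a, b = _masks(truth_mask, pred_mask)
    total = np.count_nonzero(a) + np.count_nonzero(b)
    if total == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / total


def psnr(reference: ImageGrid, test: ImageGrid, mask=None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images.

    ``mask`` optionally restricts the mean squared error to a pixel subset.
    """
    a = as_pixels(reference)
    b = as_pixels(test)
    if a.shape != b.shape:
        raise ContractError("images must share a shape")
    peak = reference.peak if isinstance(reference, ImageGrid) else 255.0
    diff = a - b
    if mask is not None:
        diff = diff[np.asarray(mask, dtype=bool)]
    mse = float(np.mean(diff * diff)) if diff.size else 0.0
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / mse))


def ssim(reference: ImageGrid, test: ImageGrid, win_size: int = 7) -> float:
    """Mean structural similarity over sliding uniform windows.

    Images smaller than the window fall back to a single global window.
    Satisfies ssim(A, A) = 1 and symmetry in its arguments.
    """
    a = as_pixels(reference)
    b = as_pixels(test)
    if a.shape != b.shape:
        raise ContractError("images must share a shape")
    peak = reference.peak if isinstance(reference, ImageGrid) else 255.0
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    c3 = c2 / 2.0

    if min(a.shape) < win_size:
        mua, mub = a.mean(), b.mean()
        va = a.var()
        vb = b.var()
        cov = float(np.mean((a - mua) * (b - mub)))
    else:
        f = lambda z: ndi.uniform_filter(z, size=win_size, mode="reflect")
        pad = win_size // 2
        sl = (slice(pad, a.shape[0] - pad), slice(pad, a.shape[1] - pad))
        mua = f(a)[sl]
        mub = f(b)[sl]
        va = np.clip(f(a * a)[sl] - mua * mua, 0.0, None)
        vb = np.clip(f(b * b)[sl] - mub * mub, 0.0, None)
        cov = f(a * b)[sl] - mua * mub
    sa = np.sqrt(va)
    sb = np.sqrt(vb)
    lum = (2 * mua * mub + c1) / (mua ** 2 + mub ** 2 + c1)
    con = (2 * sa * sb + c2) / (sa ** 2 + sb ** 2 + c2)
    struct = (cov + c3) / (sa * sb + c3)
    return float(np.mean(lum * con * struct))


def pixel_accuracy(truth: LabelMap, pred: LabelMap, mask=None) -> float:
    """Fraction of identically labeled pixels (labels already matched)."""
    t = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    p = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    if t.shape != p.shape:
        raise ContractError("label maps must share a shape")
    agree = t == p
    if mask is not None:
        agree = agree[np.asarray(mask, dtype=bool)]
    return float(np.mean(agree)) if agree.size else 1.0


@dataclass
class MetricReport:
    """Per-class overlap plus image-level quality for one prediction."""

    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    psnr: float = float("nan")
    ssim: float = float("nan")
    pixel_accuracy: float = float("nan")
    extras: dict[str, float] = field(default_factory=dict)

    @property
    def mean_jaccard(self) -> float:
        vals = [v["jaccard"] for v in self.per_class.values()]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_dice(self) -> float:
        vals = [v["dice"] for v in self.per_class.values()]
        return float(np.mean(vals)) if vals else float("nan")

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "pixel_accuracy": self.pixel_accuracy,
            "mean_jaccard": self.mean_jaccard,
            "mean_dice": self.mean_dice,
            **({"extras": self.extras} if self.extras else {}),
        }


def evaluate_segmentation(truth: LabelMap, pred: LabelMap,
                          class_ids: dict[str, tuple[int, int]],
                          reference: ImageGrid | None = None,
                          test: ImageGrid | None = None,
                          accuracy_mask=None) -> MetricReport:
    """Assemble a MetricReport.

    ``class_ids`` maps a class name to its (truth_label, pred_label) pair.
    PSNR/SSIM are filled when both images are supplied; pixel accuracy is
    evaluated over ``accuracy_mask`` (or everywhere) after remapping pred
    labels onto truth labels via ``class_ids``.
    """
    report = MetricReport()
    for name, (t_id, p_id) in class_ids.items():
        j = jaccard(truth.labels == t_id, pred.labels == p_id)
        report.per_class[name] = {"jaccard": j, "dice": 2 * j / (1 + j)}
    remap = pred.labels.copy()
    for _, (t_id, p_id) in class_ids.items():
        remap[pred.labels == p_id] = t_id
    report.pixel_accuracy = pixel_accuracy(truth.labels, remap, mask=accuracy_mask)
    if reference is not None and test is not None:
        report.psnr = psnr(reference, test)
        report.ssim = ssim(reference, test)
    return report
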