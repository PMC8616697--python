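"""Reading and writing images, label maps and reports.

PNG (8-bit grayscale) via imageio, NIfTI volumes via nibabel (a single
axial slice is extracted for the 2-D algorithms), CSV via pandas and JSON
reports with stable key ordering so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .containers import ImageGrid, LabelMap
from .exceptions import InvalidSpecError

__all__ = ["read_image", "write_image", "read_labels", "write_labels", "write_json"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, *, slice_index: int | None = None, peak: float = 255.0) -> ImageGrid:
    """Read a 2-D grayscale image from PNG (or any imageio format) or NIfTI.

    For 3-D NIfTI volumes the axial slice ``slice_index`` is taken (middle
    slice when omitted).
    """
    path = Path(path)
    if _is_nifti(path):
        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 3:
            k = vol.shape[2] // 2 if slice_index is None else int(slice_index)
            arr = np.asarray(vol[:, :, k], dtype=np.float64)
        elif vol.ndim == 2:
            arr = np.asarray(vol, dtype=np.float64)
        else:
            raise InvalidSpecError(f"unsupported NIfTI dimensionality {vol.ndim}")
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse RGB(A) to luminance
            arr = arr[..., :3].mean(axis=2)
        arr = arr.astype(np.float64)
    return ImageGrid(arr, peak=peak)


def write_image(path, image: ImageGrid) -> None:
    """Write an image as 8-bit grayscale PNG or as NIfTI (float)."""
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(image.pixels.astype(np.float32), np.eye(4)), str(path))
        return
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def read_labels(path) -> LabelMap:
    path = Path(path)
    if _is_nifti(path):
        arr = np.asanyarray(nib.load(str(path)).dataobj)
        if arr.ndim == 3:
            arr = arr[:, :, arr.shape[2] // 2]
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
    return LabelMap(np.asarray(arr, dtype=np.int64))


def write_labels(path, labels: LabelMap) -> None:
    """Write labels as an 8-bit PNG (raw class indices; -1 saved as 255)."""
    path = Path(path)
    lab = labels.labels
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(lab.astype(np.int16), np.eye(4)), str(path))
        return
    out = lab.copy()
    out[out < 0] = 255
    if out.max() > 255:
        raise InvalidSpecError("too many classes for 8-bit label PNG")
    iio.imwrite(path, out.astype(np.uint8))


def write_json(path, payload: dict) -> None:
    """Deterministic JSON dump (sorted keys, fixed separators)."""
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            obj = obj.item()
        if isinstance(obj, float) and not np.isfinite(obj):
            return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
        return obj

    Path(path).write_text(json.dumps(_clean(payload), indent=2, sort_keys=True) + "\n")
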