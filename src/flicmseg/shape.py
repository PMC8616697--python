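"""Closed-boundary tracing and complex Fourier shape descriptors, used to
identify the H-shaped cerebrospinal-fluid region.

A region's boundary pixels are visited by Moore-neighbor tracing and
encoded as complex numbers s(k) = x(k) + j y(k); the descriptor is the DFT

    lambda(u) = (1/N) sum_k s(k) exp(-j 2 pi u k / N).

lambda(0) is the centroid (translation); dividing magnitudes by |lambda(1)|
removes scale; keeping magnitudes only removes rotation and the choice of
start point. Matching compares truncated normalized magnitude vectors
(harmonic orders +/-1 .. +/-8, 16 values) by Euclidean distance: low-order
harmonics carry the gross shape, so an H-shaped ventricle pattern and a
disk decoy are well separated at the default threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi

from .containers import Contour, LabelMap
from .exceptions import ContractError, DegenerateInputError, EmptyRegionError

__all__ = [
    "ShapeDescriptor",
    "trace_boundary",
    "fourier_descriptor",
    "normalize_descriptor",
    "descriptor_distance",
    "default_h_template",
    "match_h_region",
]

# Moore neighborhood ring, clockwise on screen (row axis pointing down),
# starting at the west neighbor: W, NW, N, NE, E, SE, S, SW.
_RING = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


@dataclass
class ShapeDescriptor:
    """Fourier descriptor: complex coefficients lambda(u), u = 0..N-1.

    When ``normalized`` is True the coefficients hold rotation/start-point
    invariant magnitudes: lambda(0) dropped (translation) and all
    magnitudes divided by |lambda(1)| (scale), so the u=1 entry is exactly 1.
    """

    coeffs: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.complex128)


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of the (single) foreground component.

    Returns (N, 2) array of (x, y) = (col, row) pixel coordinates; the
    contour is closed implicitly (start not repeated). Stops when the start
    pixel is re-entered with the original backtrack state (Jacob's
    criterion).
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise EmptyRegionError("no foreground pixels to trace")
    order = np.lexsort((xs, ys))  # topmost, then leftmost
    start = (int(ys[order[0]]), int(xs[order[0]]))
    if ys.size == 1:
        return np.array([[start[1], start[0]]], dtype=np.float64)

    h, w = mask.shape

    def fg(p):
        r, c = p
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    points = [start]
    p = start
    b = (start[0], start[1] - 1)  # west of start is background by choice of start
    seen = {(p, b)}
    max_steps = 8 * ys.size + 16
    for _ in range(max_steps):
        # scan clockwise around p starting just after the backtrack pixel
        rel = (b[0] - p[0], b[1] - p[1])
        i0 = _RING.index(rel)
        nxt = None
        for k in range(1, 9):
            cand_rel = _RING[(i0 + k) % 8]
            cand = (p[0] + cand_rel[0], p[1] + cand_rel[1])
            if fg(cand):
                prev_rel = _RING[(i0 + k - 1) % 8]
                nxt = cand
                b = (p[0] + prev_rel[0], p[1] + prev_rel[1])
                break
        if nxt is None:
            break  # isolated pixel
        p = nxt
        state = (p, b)
        if state in seen:  # traversal became periodic: one full cycle done
            break
        seen.add(state)
        points.append(p)
    # the cycle may close by stepping back onto the start pixel
    while len(points) > 1 and points[-1] == start:
        points.pop()
    pts = np.array([(c, r) for r, c in points], dtype=np.float64)
    return pts


def trace_boundary(labels: LabelMap, class_id: int) -> Contour:
    """Moore boundary trace of a label class, counterclockwise.

    If the class splits into several 8-connected components the largest is
    traced and the component count recorded on the contour (and warned).
    Orientation (positive shoelace area in (x, y) coordinates) is enforced
    whenever the contour encloses nonzero area; degenerate one-pixel-thin
    contours (out-and-back traversals, area 0) are returned as traced.
    """
    mask = labels.labels == class_id if isinstance(labels, LabelMap) else np.asarray(labels) == class_id
    if not mask.any():
        raise EmptyRegionError(f"class {class_id} absent from label map")
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        biggest = int(np.argmax(sizes)) + 1
        mask = lab == biggest
        warnings.warn(f"class {class_id} has {n} components; tracing the largest",
                      stacklevel=2)
    pts = _moore_trace(mask)
    contour = Contour(pts, n_components=n)
    if contour.signed_area < 0:
        contour = contour.reversed()
    return contour


def fourier_descriptor(contour: Contour) -> ShapeDescriptor:
    """DFT of the complex boundary sequence s(k) = x(k) + j y(k)."""
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, dtype=float)
    s = pts[:, 0] + 1j * pts[:, 1]
    coeffs = np.fft.fft(s) / s.size
    return ShapeDescriptor(coeffs=coeffs, normalized=False)


def normalize_descriptor(d: ShapeDescriptor) -> ShapeDescriptor:
    """Translation/scale/rotation/start-point invariant descriptor.

    Drops lambda(0), divides magnitudes by |lambda(1)| and keeps magnitudes
    only. Idempotent; raises for degenerate shapes with |lambda(1)| = 0.
    """
    lam = d.coeffs
    if lam.size < 2:
        raise DegenerateInputError("descriptor needs at least 2 coefficients")
    a1 = np.abs(lam[1])
    if a1 == 0:
        raise DegenerateInputError("degenerate shape: |lambda(1)| = 0")
    mags = np.abs(lam) / a1
    mags[0] = 0.0
    return ShapeDescriptor(coeffs=mags.astype(np.complex128), normalized=True)


def _truncated_magnitudes(d: ShapeDescriptor, n_harmonics: int = 8) -> np.ndarray:
    if not d.normalized:
        d = normalize_descriptor(d)
    m = np.abs(d.coeffs)
    N = m.size
    vec = np.zeros(2 * n_harmonics)
    for u in range(1, n_harmonics + 1):
        if u < N:
            vec[u - 1] = m[u]
        if N - u >= 1:
            vec[n_harmonics + u - 1] = m[N - u]
    return vec


def descriptor_distance(d1: ShapeDescriptor, d2: ShapeDescriptor,
                        n_harmonics: int = 8) -> float:
    """Euclidean distance between truncated normalized magnitude vectors.

    Symmetric; zero iff the truncated normalized descriptors coincide.
    """
    v1 = _truncated_magnitudes(d1, n_harmonics)
    v2 = _truncated_magnitudes(d2, n_harmonics)
    return float(np.linalg.norm(v1 - v2))


@lru_cache(maxsize=1)
def default_h_template() -> ShapeDescriptor:
    """Normalized descriptor of the reference letter-H ventricle pattern."""
    from .phantom import render_h_mask

    mask = render_h_mask(128, 128)
    contour = trace_boundary(LabelMap(mask.astype(np.int64)), 1)
    return normalize_descriptor(fourier_descriptor(contour))


def match_h_region(labels: LabelMap, csf_class: int,
                   template: ShapeDescriptor | None = None,
                   threshold: float = 0.25, *, n_harmonics: int = 8,
                   min_size: int = 8, max_relax: int = 10
                   ) -> tuple[LabelMap, float]:
    """Identify the H-shaped component of the CSF class.

    Every sufficiently large 8-connected CSF component is traced and its
    truncated normalized descriptor compared with the template. The mask of
    the best-matching component is returned when its distance passes the
    acceptance threshold; otherwise the threshold is relaxed in 5% steps up
    to ``max_relax`` times, and if no candidate ever passes an empty mask is
    returned together with the best distance.
    """
    if template is None:
        template = default_h_template()
    if not template.normalized:
        template = normalize_descriptor(template)
    lab_arr = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    mask = lab_arr == csf_class
    if not mask.any():
        raise EmptyRegionError(f"CSF class {csf_class} absent from label map")
    comp, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    best_dist = np.inf
    best_mask = np.zeros_like(mask)
    for cid in range(1, n + 1):
        cmask = comp == cid
        if cmask.sum() < min_size:
            continue
        pts = _moore_trace(cmask)
        if pts.shape[0] < 4:
            continue
        contour = Contour(pts)
        if contour.signed_area < 0:
            contour = contour.reversed()
        try:
            desc = normalize_descriptor(fourier_descriptor(contour))
        except DegenerateInputError:
            continue
        dist = descriptor_distance(desc, template, n_harmonics)
        if dist < best_dist:
            best_dist = dist
            best_mask = cmask
    thr = threshold
    for _ in range(max_relax + 1):
        if best_dist <= thr:
            return (LabelMap(best_mask.astype(np.int64),
                             class_names=("other", "h_region")), float(best_dist))
        thr *= 1.05
    return (LabelMap(np.zeros_like(mask, dtype=np.int64),
                     class_names=("other", "h_region")), float(best_dist))
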