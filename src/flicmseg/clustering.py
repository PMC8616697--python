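"""Fuzzy C-means (FCM) and fuzzy local-information C-means (FLICM) clustering.

FLICM augments the classical FCM objective

    J = sum_i sum_j  mu_ij^m ( ||x_i - v_j||^2 + B_ij )

with a parameter-free fuzzy factor computed over the 3x3 neighborhood of
each pixel,

    B_ij = sum_{r in N(i), r != i}  (1 / (1 + c_ir)) (1 - mu_rj)^m ||x_r - v_j||^2,

where c_ir is the Euclidean distance between the *coordinates* of pixels i
and r. The factor pulls each pixel's membership toward its neighbors',
giving noise robustness without a tuning parameter. Updates alternate
fuzzy factor -> memberships -> centers until the largest center shift falls
below tolerance. Setting ``use_local_term=False`` forces B = 0 and recovers
plain FCM (for which the alternating updates provably never increase J;
FLICM's updates are the standard heuristic and the objective trace is
reported diagnostically).

Two surfaces are offered: a statsmodels-style model object
(:class:`FLICM` -> :class:`FLICMResults`) and functional building blocks
(:func:`init_centers`, :func:`fuzzy_factor`, :func:`update_membership`,
:func:`update_centers`, :func:`flicm_objective`, :func:`flicm_segment`,
:func:`match_labels`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import ImageGrid, LabelMap, MembershipField, as_pixels
from .exceptions import (
    ContractError,
    ConvergenceWarning,
    DegenerateInputError,
    EmptyClusterWarning,
    InvalidSpecError,
)

__all__ = [
    "ClusterModel",
    "ConvergenceConfig",
    "FuzzyFactorField",
    "IterationTrace",
    "FLICM",
    "FLICMResults",
    "init_centers",
    "fuzzy_factor",
    "update_membership",
    "update_centers",
    "flicm_objective",
    "flicm_segment",
    "match_labels",
]


@dataclass
class ClusterModel:
    """Cluster centers and fuzzifier."""

    centers: np.ndarray
    fuzzifier: float = 2.0

    def __post_init__(self) -> None:
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=np.float64))
        if self.centers.size < 2:
            raise InvalidSpecError("need at least 2 clusters")
        if not np.all(np.isfinite(self.centers)):
            raise InvalidSpecError("centers must be finite")
        if not self.fuzzifier > 1:
            raise InvalidSpecError("fuzzifier m must be > 1")

    @property
    def n_clusters(self) -> int:
        return self.centers.size


@dataclass
class ConvergenceConfig:
    """Iteration controls. ``neighborhood`` is the window half-width
    (1 -> the 3x3 window)."""

    tol: float = 1e-5
    max_iter: int = 100
    init_seed: int = 0
    neighborhood: int = 1

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise InvalidSpecError("tol must be positive")
        if self.max_iter < 1:
            raise InvalidSpecError("max_iter must be >= 1")
        if self.neighborhood < 1:
            raise InvalidSpecError("neighborhood half-width must be >= 1")


@dataclass
class FuzzyFactorField:
    """Per-pixel, per-cluster fuzzy factor B_ij (nonnegative)."""

    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=np.float64)
        if self.B.ndim != 3:
            raise InvalidSpecError("FuzzyFactorField requires an (H, W, K) array")


@dataclass
class IterationTrace:
    """Per-iteration objective and center values plus convergence status."""

    objective: list[float] = field(default_factory=list)
    centers: list[np.ndarray] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    messages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# functional building blocks (array core + typed wrappers)
# ---------------------------------------------------------------------------


def init_centers(image, K: int, seed: int = 0) -> ClusterModel:
    """Initial centers at the K evenly spaced intensity quantiles.

    Centers are placed at quantiles q = (j + 0.5)/K of the (optionally
    masked) intensity distribution — deterministic for a fixed input; the
    seed is accepted for interface stability only. If the quantiles collide
    (heavily skewed histograms), the quantiles of the unique intensity
    values are used instead so that no two initial centers coincide.
    """
    x = (image.pixels if isinstance(image, ImageGrid) else
         np.asarray(image, dtype=np.float64)).ravel()
    uniq = np.unique(x)
    if uniq.size < K:
        raise DegenerateInputError(f"image has {uniq.size} distinct intensities, need >= {K}")
    q = (np.arange(K) + 0.5) / K
    centers = np.quantile(x, q)
    if np.unique(centers).size < K:
        centers = np.quantile(uniq, q)
    return ClusterModel(centers=centers)


def _neighbor_offsets(halfwidth: int) -> list[tuple[int, int, float]]:
    offs = []
    for dy in range(-halfwidth, halfwidth + 1):
        for dx in range(-halfwidth, halfwidth + 1):
            if dy == 0 and dx == 0:
                continue  # center pixel excluded from the neighborhood sum
            w = 1.0 / (1.0 + float(np.hypot(dy, dx)))
            offs.append((dy, dx, w))
    return offs


def _shift_sum(term: np.ndarray, offsets) -> np.ndarray:
    """Sum w_d * term shifted by each neighbor offset, truncating at borders.

    ``term`` is (H, W, K); contribution of neighbor r to pixel i is
    w_d * term[r] where r = i + (dy, dx).
    """
    h, w = term.shape[:2]
    out = np.zeros_like(term)
    for dy, dx, wgt in offsets:
        src_y = slice(max(dy, 0), h + min(dy, 0))
        src_x = slice(max(dx, 0), w + min(dx, 0))
        dst_y = slice(max(-dy, 0), h + min(-dy, 0))
        dst_x = slice(max(-dx, 0), w + min(-dx, 0))
        out[dst_y, dst_x] += wgt * term[src_y, src_x]
    return out


def _fuzzy_factor(x, mu, centers, m, halfwidth=1, mask=None):
    d2 = (x[..., None] - centers) ** 2  # (H, W, K)
    term = (1.0 - mu) ** m * d2
    if mask is not None:
        term = term * mask[..., None]
    return _shift_sum(term, _neighbor_offsets(halfwidth))


def fuzzy_factor(image, mu, model: ClusterModel, cfg: ConvergenceConfig | None = None,
                 mask: np.ndarray | None = None) -> FuzzyFactorField:
    """Spatial fuzzy factor B_ij over the (2w+1)^2 neighborhood.

    Windows are truncated at image borders; masked-out neighbors contribute
    nothing. B_ij vanishes when every neighbor has full membership to
    cluster j or intensity exactly v_j.
    """
    cfg = cfg or ConvergenceConfig()
    x = as_pixels(image)
    mu_arr = mu.mu if isinstance(mu, MembershipField) else np.asarray(mu, dtype=np.float64)
    if mu_arr.shape[:2] != x.shape:
        raise ContractError("membership field and image shapes differ")
    if mu_arr.shape[2] != model.n_clusters:
        raise ContractError("membership field and model disagree on cluster count")
    B = _fuzzy_factor(x, mu_arr, model.centers, model.fuzzifier, cfg.neighborhood, mask)
    return FuzzyFactorField(B)


def _update_membership(x, centers, B, m):
    d2 = (x[..., None] - centers) ** 2
    D = d2 + B
    zero = D <= 0.0
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        p = D ** (-1.0 / (m - 1.0))
        mu = p / p.sum(axis=2, keepdims=True)
    sing = zero.any(axis=2)
    if np.any(sing):
        # crisp membership split equally among the zero-distance clusters
        z = zero[sing].astype(np.float64)
        mu[sing] = z / z.sum(axis=1, keepdims=True)
    return mu


def update_membership(image, model: ClusterModel, B: FuzzyFactorField | np.ndarray | None = None
                      ) -> MembershipField:
    """Membership update: mu_ij = 1 / sum_k [ (d_ij^2 + B_ij) / (d_ik^2 + B_ik) ]^{1/(m-1)}.

    Pixels with a zero denominator term (exactly at a center with B = 0)
    receive crisp membership split equally among the zero-distance clusters.
    Rows always sum to 1.
    """
    x = as_pixels(image)
    K = model.n_clusters
    if B is None:
        B_arr = np.zeros(x.shape + (K,))
    else:
        B_arr = B.B if isinstance(B, FuzzyFactorField) else np.asarray(B, dtype=np.float64)
    if B_arr.shape != x.shape + (K,):
        raise ContractError("fuzzy factor shape inconsistent with image/model")
    return MembershipField(_update_membership(x, model.centers, B_arr, model.fuzzifier))


def _update_centers(x, mu, m, prev=None, mask=None):
    w = mu ** m
    if mask is not None:
        w = w * mask[..., None]
    num = (w * x[..., None]).sum(axis=(0, 1))
    den = w.sum(axis=(0, 1))
    centers = np.empty_like(den)
    empty = den <= np.finfo(float).tiny
    if np.any(empty):
        warnings.warn("cluster(s) with zero total membership weight; centers kept",
                      EmptyClusterWarning, stacklevel=2)
        if prev is None:
            raise DegenerateInputError("empty cluster with no previous centers to keep")
        centers[empty] = np.asarray(prev)[empty]
    centers[~empty] = num[~empty] / den[~empty]
    return centers


def update_centers(image, mu, m: float = 2.0, prev_centers=None,
                   mask: np.ndarray | None = None) -> ClusterModel:
    """Center update: v_j = sum_i mu_ij^m x_i / sum_i mu_ij^m.

    A cluster with zero total weight is reported via
    :class:`EmptyClusterWarning` and its center left unchanged (requires
    ``prev_centers``).
    """
    x = as_pixels(image)
    mu_arr = mu.mu if isinstance(mu, MembershipField) else np.asarray(mu, dtype=np.float64)
    if mu_arr.shape[:2] != x.shape:
        raise ContractError("membership field and image shapes differ")
    centers = _update_centers(x, mu_arr, m, prev=prev_centers, mask=mask)
    return ClusterModel(centers=centers, fuzzifier=m)


def flicm_objective(image, mu, model: ClusterModel,
                    B: FuzzyFactorField | np.ndarray | None = None,
                    mask: np.ndarray | None = None) -> float:
    """Objective J = sum_i sum_j mu_ij^m (||x_i - v_j||^2 + B_ij); with
    B = 0 this is the classical FCM objective."""
    x = as_pixels(image)
    mu_arr = mu.mu if isinstance(mu, MembershipField) else np.asarray(mu, dtype=np.float64)
    K = model.n_clusters
    if B is None:
        B_arr = np.zeros(x.shape + (K,))
    else:
        B_arr = B.B if isinstance(B, FuzzyFactorField) else np.asarray(B, dtype=np.float64)
    d2 = (x[..., None] - model.centers) ** 2
    terms = mu_arr ** model.fuzzifier * (d2 + B_arr)
    if mask is not None:
        terms = terms * mask[..., None]
    return float(terms.sum())


def match_labels(pred: LabelMap, truth: LabelMap) -> LabelMap:
    """Relabel ``pred`` by the permutation maximizing total overlap with
    ``truth`` (optimal assignment on the K x K confusion matrix).

    Pixels labeled -1 (outside the analysis mask) in either map are ignored
    when building the confusion matrix and keep their label.
    """
    p = pred.labels
    t = truth.labels
    if p.shape != t.shape:
        raise ContractError("label maps must share a shape")
    valid = (p >= 0) & (t >= 0)
    if not valid.any():
        raise ContractError("no overlapping in-mask pixels to match")
    kp = int(p[valid].max()) + 1
    kt = int(t[valid].max()) + 1
    if kp != kt:
        raise ContractError(f"label maps disagree on class count ({kp} vs {kt})")
    K = kp
    conf = np.zeros((K, K), dtype=np.int64)
    np.add.at(conf, (t[valid], p[valid]), 1)
    rows, cols = linear_sum_assignment(conf, maximize=True)
    mapping = np.arange(K)
    mapping[cols] = rows
    out = p.copy()
    out[valid] = mapping[p[valid]]
    return LabelMap(out, class_names=truth.class_names)


# ---------------------------------------------------------------------------
# iteration loop
# ---------------------------------------------------------------------------


def _fit_loop(x, centers0, m, use_local_term, tol, max_iter, halfwidth, mask):
    centers = np.asarray(centers0, dtype=np.float64).copy()
    trace = IterationTrace()
    mu = _update_membership(x, centers, np.zeros(x.shape + (centers.size,)), m)
    if mask is not None:
        mu = mu * mask[..., None]
    for _ in range(max_iter):
        if use_local_term:
            B = _fuzzy_factor(x, mu, centers, m, halfwidth, mask)
        else:
            B = np.zeros(x.shape + (centers.size,))
        mu = _update_membership(x, centers, B, m)
        if mask is not None:
            mu = mu * mask[..., None]
        new_centers = _update_centers(x, mu, m, prev=centers, mask=mask)
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        trace.objective.append(flicm_objective(x, mu, ClusterModel(centers, m), B, mask))
        trace.centers.append(centers.copy())
        trace.n_iter += 1
        if shift < tol:
            trace.converged = True
            break
    if not trace.converged:
        trace.messages.append(f"did not converge within {max_iter} iterations")
        warnings.warn(trace.messages[-1], ConvergenceWarning, stacklevel=3)
    return mu, centers, trace


def flicm_segment(image, K: int, cfg: ConvergenceConfig | None = None,
                  use_local_term: bool = True, *, mask: np.ndarray | None = None,
                  initial_centers=None
                  ) -> tuple[MembershipField, ClusterModel, LabelMap, IterationTrace]:
    """Segment an image with FLICM (or FCM when ``use_local_term=False``).

    Alternates fuzzy factor -> membership update -> center update from
    quantile-initialized centers until the max center shift drops below
    ``cfg.tol`` or ``cfg.max_iter`` is hit (warning recorded in the trace;
    best-so-far state returned). Defuzzification is per-pixel argmax with
    ties broken toward the lowest cluster index. With a ``mask``, only
    in-mask pixels participate; outside pixels get label -1.
    """
    cfg = cfg or ConvergenceConfig()
    if K < 2:
        raise InvalidSpecError("need at least 2 clusters")
    x = as_pixels(image)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != x.shape:
            raise ContractError("mask shape mismatch")
        mask_f = mask.astype(np.float64)
        data = x[mask]
    else:
        mask_f = None
        data = x
    if initial_centers is None:
        model0 = init_centers(data, K, cfg.init_seed)
        centers0 = model0.centers
    else:
        centers0 = np.asarray(initial_centers, dtype=np.float64)
        if centers0.size != K:
            raise ContractError("initial_centers length must equal K")
    mu, centers, trace = _fit_loop(x, centers0, _m_of(cfg), use_local_term,
                                   cfg.tol, cfg.max_iter, cfg.neighborhood, mask_f)
    labels = np.argmax(mu, axis=2).astype(np.int64)
    if mask is not None:
        labels[~mask] = -1
    return (MembershipField(mu), ClusterModel(centers, _m_of(cfg)),
            LabelMap(labels), trace)


def _m_of(cfg) -> float:
    # ConvergenceConfig carries no fuzzifier (it lives on ClusterModel /
    # FLICM); the functional entry point uses the standard default m = 2.
    return getattr(cfg, "fuzzifier", 2.0)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------


class FLICM:
    """FLICM/FCM clustering model for a 2-D grayscale image.

    Parameters
    ----------
    image : ImageGrid or 2-D array
        Intensities to cluster.
    n_clusters : int
        Number of tissue classes K (>= 2).
    fuzzifier : float
        Membership exponent m > 1 (default 2.0).
    use_local_term : bool
        If False, the spatial fuzzy factor is forced to zero and the model
        is plain FCM.
    mask : bool array, optional
        Restrict clustering to these pixels (e.g. a stripped brain mask).
    neighborhood : int
        Window half-width for the fuzzy factor (1 -> 3x3).

    Examples
    --------
    >>> from flicmseg import phantom
    >>> img, truth = phantom.generate_phantom(phantom.PhantomSpec())
    >>> res = FLICM(img, n_clusters=5).fit()
    >>> res.labels.labels.shape
    (128, 128)
    """

    def __init__(self, image, n_clusters: int = 3, *, fuzzifier: float = 2.0,
                 use_local_term: bool = True, mask: np.ndarray | None = None,
                 neighborhood: int = 1):
        if n_clusters < 2:
            raise InvalidSpecError("need at least 2 clusters")
        if not fuzzifier > 1:
            raise InvalidSpecError("fuzzifier m must be > 1")
        self.image = image if isinstance(image, ImageGrid) else ImageGrid(np.asarray(image))
        self.n_clusters = int(n_clusters)
        self.fuzzifier = float(fuzzifier)
        self.use_local_term = bool(use_local_term)
        self.neighborhood = int(neighborhood)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.image.shape:
                raise ContractError("mask shape mismatch")
        self.mask = mask

    def fit(self, *, initial_centers=None, tol: float = 1e-5, max_iter: int = 100
            ) -> "FLICMResults":
        """Run the alternating updates and return a results object."""
        x = self.image.pixels
        mask_f = self.mask.astype(np.float64) if self.mask is not None else None
        if initial_centers is None:
            data = x[self.mask] if self.mask is not None else x
            centers0 = init_centers(data, self.n_clusters).centers
        else:
            centers0 = np.asarray(initial_centers, dtype=np.float64)
            if centers0.size != self.n_clusters:
                raise ContractError("initial_centers length must equal n_clusters")
        if not tol > 0:
            raise InvalidSpecError("tol must be positive")
        mu, centers, trace = _fit_loop(x, centers0, self.fuzzifier,
                                       self.use_local_term, tol, max_iter,
                                       self.neighborhood, mask_f)
        labels = np.argmax(mu, axis=2).astype(np.int64)
        if self.mask is not None:
            labels[~self.mask] = -1
        return FLICMResults(self, MembershipField(mu),
                            ClusterModel(centers, self.fuzzifier),
                            LabelMap(labels), trace)


@dataclass
class FLICMResults:
    """Fitted FLICM/FCM state: memberships, centers, crisp labels, trace."""

    model: FLICM
    membership: MembershipField
    cluster_model: ClusterModel
    labels: LabelMap
    trace: IterationTrace

    @property
    def centers(self) -> np.ndarray:
        return self.cluster_model.centers

    @property
    def n_iter(self) -> int:
        return self.trace.n_iter

    @property
    def converged(self) -> bool:
        return self.trace.converged

    def intensity_order(self) -> np.ndarray:
        """Cluster indices sorted by ascending center intensity."""
        return np.argsort(self.centers, kind="stable")

    def relabeled_by_intensity(self) -> LabelMap:
        """Labels remapped so 0 is the darkest cluster, K-1 the brightest."""
        order = self.intensity_order()
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        lab = self.labels.labels.copy()
        inside = lab >= 0
        lab[inside] = inv[lab[inside]]
        return LabelMap(lab)

    def reconstruction(self) -> ImageGrid:
        """Piecewise-constant reconstruction: each pixel replaced by its
        cluster center (masked-out pixels -> 0)."""
        lab = self.labels.labels
        out = np.zeros(lab.shape, dtype=np.float64)
        inside = lab >= 0
        out[inside] = self.centers[lab[inside]]
        return ImageGrid(out, self.model.image.peak)

    def summary(self) -> str:
        lab = self.labels.labels
        lines = [
            "FLICM results" if self.model.use_local_term else "FCM results",
            "=" * 46,
            f"clusters:        {self.model.n_clusters}",
            f"fuzzifier m:     {self.model.fuzzifier:g}",
            f"iterations:      {self.n_iter} ({'converged' if self.converged else 'max_iter hit'})",
            f"final objective: {self.trace.objective[-1]:.6g}",
            f"{'cluster':>8} {'center':>12} {'pixels':>10}",
        ]
        for j in range(self.model.n_clusters):
            lines.append(f"{j:>8} {self.centers[j]:>12.4f} {int(np.sum(lab == j)):>10}")
        if np.any(lab < 0):
            lines.append(f"{'masked':>8} {'':>12} {int(np.sum(lab < 0)):>10}")
        return "\n".join(lines)
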