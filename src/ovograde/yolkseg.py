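"""Yolk segmentation by K-means color clustering inside the egg mask.

The yolk is optically denser than the albumen, so under transmission
light it appears as a darker, chromatically distinct interior region,
usually surrounded by a "ghosting" ring (the penumbra of the yolk
projection). Clustering the egg pixels into K = 3 color classes in CIELAB
space separates albumen, ghosting and yolk core; the yolk cluster is the
one nearest the egg centroid (darkest on ties).

K-means uses K-means++ seeding and Lloyd iterations with the stopping
rule: at most ``max_iter`` iterations (default 100) or maximum cluster-
center shift below ``tol`` (default 1e-6). Everything is driven by an
explicit seed, and identical seeds give bit-identical results. Empty
clusters are re-seeded to the point farthest from its assigned center.

By default clustering uses the chromatic (a*, b*) channels only: the
strong radial illumination gradient of transmission lighting lives almost
entirely in L*, and dropping it makes the clusters shell-tint invariant.
Full-Lab clustering (with the enhanced lightness substituted for L*) is
available via ``KMeansConfig.feature_space = "lab"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage import color as _skcolor
from skimage import exposure

from .eggseg import EggSegmentation, largest_component, pixel_area
from .errors import SegmentationError, ValidationError
from .images import rgb_to_lab, to_grayscale

# --------------------------------------------------------------------------
# contrast enhancement
# --------------------------------------------------------------------------


@dataclass
class EnhancementParams:
    """Contrast-enhancement chain settings.

    The chain is: linear stretch of the [p, 1-p] intensity quantiles to
    full range, global histogram equalization, then CLAHE. Defaults are the
    conventional ones of mainstream image-processing environments.
    """

    tail_saturation: float = 0.01
    histeq_bins: int = 64
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.tail_saturation < 0.5:
            raise ValidationError("tail_saturation must be in [0, 0.5)")
        if self.histeq_bins < 2:
            raise ValidationError("histeq_bins must be >= 2")
        if not 0 < self.clahe_clip <= 1:
            raise ValidationError("clahe_clip must be in (0, 1]")
        if len(self.clahe_tiles) != 2 or min(self.clahe_tiles) < 1:
            raise ValidationError("clahe_tiles must be two positive integers")


def contrast_stretch(gray: np.ndarray, tail_saturation: float) -> np.ndarray:
    """Map the [p, 1-p] quantiles of an 8-bit gray image to [0, 255].

    Degenerate images (equal quantiles) are returned unchanged.
    """
    gray = np.asarray(gray)
    lo, hi = np.quantile(gray, [tail_saturation, 1.0 - tail_saturation])
    if hi <= lo:
        return gray.copy()
    out = (gray.astype(np.float64) - lo) / (hi - lo)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def hist_equalize(gray: np.ndarray, nbins: int) -> np.ndarray:
    """Global histogram equalization of an 8-bit gray image."""
    gray = np.asarray(gray)
    if gray.min() == gray.max():
        return gray.copy()
    eq = exposure.equalize_hist(gray, nbins=nbins)
    return np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)


def enhance(gray: np.ndarray, params: EnhancementParams | None = None) -> np.ndarray:
    """Contrast-enhance a gray image: stretch -> histeq -> CLAHE.

    A constant image passes through unchanged (every step is degenerate).
    """
    params = params or EnhancementParams()
    gray = np.asarray(gray)
    if gray.min() == gray.max():
        return gray.copy()
    out = contrast_stretch(gray, params.tail_saturation)
    out = hist_equalize(out, params.histeq_bins)
    ty, tx = params.clahe_tiles
    kernel = (max(gray.shape[0] // ty, 1), max(gray.shape[1] // tx, 1))
    out = exposure.equalize_adapthist(out, kernel_size=kernel, clip_limit=params.clahe_clip)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# K-means
# --------------------------------------------------------------------------


@dataclass
class KMeansConfig:
    """K-means settings: K = 3 clusters, stop after 100 iterations or when
    the maximum center shift drops below 1e-6."""

    k: int = 3
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    feature_space: str = "ab"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValidationError("tol must be > 0")
        if self.feature_space not in ("ab", "lab"):
            raise ValidationError("feature_space must be 'ab' or 'lab'")


@dataclass
class ClusterResult:
    """Labels, centers and objective of one K-means run.

    ``sse_history`` records the sum of squared distances after each
    assignment step; it is non-increasing.
    """

    labels: np.ndarray
    centers: np.ndarray
    sse: float
    iterations_run: int
    sse_history: list[float] = field(default_factory=list)


def kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """K-means++ seeding: first center uniform, then D^2-weighted sampling."""
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if n < k:
        raise ValidationError(f"need at least k={k} points, got {n}")
    centers = np.empty((k, points.shape[1]), dtype=np.float64)
    centers[0] = points[rng.integers(n)]
    d2 = ((points - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))  # all points coincide with a center
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[j] = points[idx]
        d2 = np.minimum(d2, ((points - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    points: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> ClusterResult:
    points = np.asarray(points, dtype=np.float64)
    centers = np.array(centers, dtype=np.float64)
    k = centers.shape[0]
    sse_history: list[float] = []
    labels = np.zeros(points.shape[0], dtype=np.intp)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        d2 = cdist(points, centers, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        # re-seed empty clusters to the globally farthest point
        for j in range(k):
            if not np.any(labels == j):
                far = int(d2[np.arange(len(labels)), labels].argmax())
                centers[j] = points[far]
                d2[:, j] = ((points - centers[j]) ** 2).sum(axis=1)
                labels = d2.argmin(axis=1)
        sse_history.append(float(d2[np.arange(len(labels)), labels].sum()))
        new_centers = np.empty_like(centers)
        for j in range(k):
            new_centers[j] = points[labels == j].mean(axis=0)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            break
    # final assignment against the converged centers
    d2 = cdist(points, centers, metric="sqeuclidean")
    labels = d2.argmin(axis=1)
    sse = float(d2[np.arange(len(labels)), labels].sum())
    sse_history.append(sse)
    return ClusterResult(
        labels=labels,
        centers=centers,
        sse=sse,
        iterations_run=iterations,
        sse_history=sse_history,
    )


def kmeans(points: np.ndarray, config: KMeansConfig | None = None) -> ClusterResult:
    """K-means++ + Lloyd iterations, fully determined by ``config.seed``."""
    config = config or KMeansConfig()
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    if points.shape[0] < config.k:
        raise ValidationError(f"need at least k={config.k} points, got {points.shape[0]}")
    rng = np.random.default_rng(config.seed)
    centers = kmeanspp_init(points, config.k, rng)
    return _lloyd(points, centers, config.max_iter, config.tol)


def sse_curve(
    points: np.ndarray, k_max: int, config: KMeansConfig | None = None
) -> list[float]:
    """SSE of K-means for k = 1..k_max (elbow-method curve).

    Runs are warm-started: the run for k starts from the converged centers
    of k-1 plus one extra D^2-sampled point, which guarantees the curve is
    non-increasing in k.
    """
    config = config or KMeansConfig()
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    if k_max < 1 or k_max > points.shape[0]:
        raise ValidationError("k_max must be in [1, n_points]")
    rng = np.random.default_rng(config.seed)
    sses: list[float] = []
    centers = points.mean(axis=0, keepdims=True)
    result = _lloyd(points, centers, config.max_iter, config.tol)
    sses.append(result.sse)
    for _ in range(2, k_max + 1):
        centers = result.centers
        d2 = cdist(points, centers, metric="sqeuclidean").min(axis=1)
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(points.shape[0]))
        else:
            idx = int(rng.choice(points.shape[0], p=d2 / total))
        centers = np.vstack([centers, points[idx]])
        result = _lloyd(points, centers, config.max_iter, config.tol)
        sses.append(min(result.sse, sses[-1]))
    return sses


# --------------------------------------------------------------------------
# yolk extraction
# --------------------------------------------------------------------------


@dataclass
class YolkSegmentation:
    """Yolk mask plus its projected pixel area S_SMALL and provenance."""

    mask: np.ndarray
    area_pixels: int
    yolk_cluster_id: int
    cluster_result: ClusterResult


def select_yolk_cluster(
    cluster: ClusterResult, egg_mask: np.ndarray, gray: np.ndarray
) -> int:
    """Pick the cluster that is the yolk.

    The yolk projection sits at the egg's optical center and transmits the
    least light, so clusters are ranked by mean pixel distance to the
    egg-mask centroid (lower wins); ties go to the lower mean gray
    intensity.
    """
    egg = np.asarray(egg_mask).astype(bool)
    if cluster.labels.size == 0 or not egg.any():
        raise SegmentationError("empty clustering or empty egg mask")
    coords = np.argwhere(egg).astype(np.float64)
    if coords.shape[0] != cluster.labels.shape[0]:
        raise ValidationError("cluster labels do not match egg-mask pixel count")
    centroid = coords.mean(axis=0)
    dists = np.linalg.norm(coords - centroid, axis=1)
    gvals = np.asarray(gray, dtype=np.float64)[egg]
    k = cluster.centers.shape[0]
    mean_dist = np.full(k, np.inf)
    mean_gray = np.full(k, np.inf)
    for j in range(k):
        sel = cluster.labels == j
        if sel.any():
            mean_dist[j] = dists[sel].mean()
            mean_gray[j] = gvals[sel].mean()
    best = mean_dist.min()
    tied = np.flatnonzero(np.isclose(mean_dist, best, rtol=1e-9, atol=1e-9))
    return int(tied[np.argmin(mean_gray[tied])])


def _features(
    img: np.ndarray,
    egg_mask: np.ndarray,
    kcfg: KMeansConfig,
    ecfg: EnhancementParams,
    enhance_rgb: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (features, enhanced_gray) for the masked pixels.

    Default route: chroma (a*, b*) from the unenhanced image — histogram
    equalization distorts color ratios, so enhancement only feeds the
    lightness channel. ``enhance_rgb=True`` instead enhances each RGB
    channel before the Lab conversion (enhance-then-cluster order).
    """
    egg = np.asarray(egg_mask).astype(bool)
    gray = to_grayscale(img)
    g_enh = enhance(gray, ecfg)
    if enhance_rgb:
        chans = [enhance(img[..., c], ecfg) for c in range(3)]
        lab = rgb_to_lab(np.stack(chans, axis=-1))
    else:
        lab = rgb_to_lab(img)
        lab = lab.copy()
        lab[..., 0] = g_enh.astype(np.float64) / 255.0 * 100.0
    if kcfg.feature_space == "ab":
        feats = lab[..., 1:][egg]
    else:
        feats = lab[egg]
    return feats, g_enh


def segment_yolk(
    img: np.ndarray,
    egg: EggSegmentation,
    kcfg: KMeansConfig | None = None,
    ecfg: EnhancementParams | None = None,
    enhance_rgb: bool = False,
) -> YolkSegmentation:
    """Segment the yolk inside a previously computed egg mask.

    enhance -> Lab conversion -> K-means over masked pixels -> yolk-cluster
    selection -> largest connected component -> hole filling -> pixel area.
    The hole filling turns an annular yolk cluster (the ghosting ring can
    capture the core boundary) into the solid projected area the area-ratio
    feature requires. Raises :class:`SegmentationError` when the egg mask is
    empty or no yolk pixels survive.
    """
    kcfg = kcfg or KMeansConfig()
    ecfg = ecfg or EnhancementParams()
    egg_mask = np.asarray(egg.mask).astype(bool)
    if not egg_mask.any():
        raise SegmentationError("egg mask is empty; cannot segment yolk")
    feats, _ = _features(img, egg_mask, kcfg, ecfg, enhance_rgb)
    cluster = kmeans(feats, kcfg)
    gray = to_grayscale(img)
    yolk_id = select_yolk_cluster(cluster, egg_mask, gray)
    yolk = np.zeros(egg_mask.shape, dtype=np.uint8)
    yolk[egg_mask] = (cluster.labels == yolk_id).astype(np.uint8)
    yolk = largest_component(yolk)
    yolk = ndi.binary_fill_holes(yolk.astype(bool)) & egg_mask
    yolk = yolk.astype(np.uint8)
    area = pixel_area(yolk)
    if area == 0:
        raise SegmentationError("yolk segmentation failed: empty yolk mask")
    return YolkSegmentation(
        mask=yolk, area_pixels=area, yolk_cluster_id=yolk_id, cluster_result=cluster
    )


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two {0,1} masks (1.0 if both empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def overlay_segmentation(
    img: np.ndarray, egg_mask: np.ndarray, yolk_mask: np.ndarray
) -> np.ndarray:
    """Pseudo-color QC overlay: albumen orange, yolk green, background dim."""
    labels = np.zeros(np.asarray(egg_mask).shape, dtype=np.intp)
    labels[np.asarray(egg_mask).astype(bool)] = 1
    labels[np.asarray(yolk_mask).astype(bool)] = 2
    over = _skcolor.label2rgb(
        labels,
        image=np.asarray(img, dtype=np.float64) / 255.0,
        colors=[(1.0, 0.6, 0.1), (0.1, 0.9, 0.3)],
        bg_label=0,
        alpha=0.35,
    )
    return np.clip(np.rint(over * 255.0), 0, 255).astype(np.uint8)
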