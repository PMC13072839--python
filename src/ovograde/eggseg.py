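"""Whole-egg segmentation from a transmission view.

Under candling geometry the trans-illuminated egg is a bright blob on a
dark box interior, so segmentation is histogram thresholding. The
threshold comes from a weighted variant of Otsu's method that introduces
the pixel-weight coefficient

    omega(t) = (sigma_b(t) / sigma_t) * (N_b(t) / N_t(t))

where ``sigma_b`` is the between-class standard deviation at threshold
``t``, ``sigma_t`` the total standard deviation (constant in ``t``), and
``N_b``/``N_t`` the background/target pixel counts. Pixels with gray
value > t are target (the bright egg), pixels <= t are background.

The maximized objective is ``sigma_b^2(t) * omega(t)``: omega acts as a
weight on the classical between-class-variance criterion, favouring
thresholds that keep the target compact against a large dark background.
Maximizing omega alone is also available (``objective="omega"``) but is
degenerate in general: omega grows without bound as the target class
shrinks, so its argmax collapses onto the few brightest pixels of any
image with a continuous bright-region histogram. See docs/methods.md.

After thresholding, the binary image is cleaned by morphological opening
and closing with a disk and removal of small connected components; the
largest component is kept and its interior holes are filled (a threshold
that lands between yolk and albumen gray levels otherwise leaves a
yolk-shaped hole in the egg mask). The whole-egg projected pixel area
``S_BIG`` is the plain count of 1-pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .errors import DegenerateImageError, SegmentationError, ValidationError
from .images import to_grayscale

DEFAULT_DISK_RADIUS = 5
DEFAULT_MIN_COMPONENT_FRAC = 0.005


@dataclass
class WeightedOtsuResult:
    """Outcome of the weighted-Otsu threshold search.

    ``omega_curve`` holds omega(t) for every candidate t (NaN where a class
    is empty); ``objective_curve`` holds the maximized objective, which is
    ``sigma_b^2 * omega`` under the default objective and equals
    ``omega_curve`` under ``objective="omega"``.
    """

    threshold: int
    objective_curve: np.ndarray
    omega_curve: np.ndarray
    sigma_b: float
    sigma_t: float
    n_b: int
    n_t: int
    objective: str = "weighted"


@dataclass
class EggSegmentation:
    """Whole-egg mask plus its projected pixel area S_BIG and provenance."""

    mask: np.ndarray
    area_pixels: int
    threshold: WeightedOtsuResult
    morphology_params: dict = field(default_factory=dict)


def _class_stats(gray: np.ndarray):
    """Cumulative class statistics over the 256-bin histogram.

    Returns (n_b, n_t, mu_b, mu_t, sigma_b2, var_total, valid) where index t
    corresponds to the split background = {gray <= t}, target = {gray > t}.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValidationError(f"expected (H, W) gray image, got shape {gray.shape}")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(np.float64)
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    mu = float((hist * levels).sum() / n)
    var_total = float((hist * (levels - mu) ** 2).sum() / n)
    if var_total == 0.0:
        raise DegenerateImageError("image is constant; no threshold exists")
    n_b = np.cumsum(hist)
    n_t = n - n_b
    s_b = np.cumsum(hist * levels)
    valid = (n_b > 0) & (n_t > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_b = np.where(valid, s_b / n_b, np.nan)
        mu_t = np.where(valid, (s_b[-1] - s_b) / n_t, np.nan)
        sigma_b2 = np.where(valid, (n_b / n) * (n_t / n) * (mu_b - mu_t) ** 2, np.nan)
    return n_b, n_t, mu_b, mu_t, sigma_b2, var_total, valid


def _tie_median_argmax(values: np.ndarray, valid: np.ndarray) -> int:
    """Lower-median of the argmax set; ties within 1e-12 relative."""
    vals = np.where(valid, values, -np.inf)
    best = np.max(vals)
    ties = np.flatnonzero(vals >= best - 1e-12 * max(abs(best), 1.0))
    return int(ties[(len(ties) - 1) // 2])


def standard_otsu(gray: np.ndarray) -> int:
    """Classical Otsu threshold: argmax of between-class variance.

    Ties are broken by the lower median of the argmax set, so a perfectly
    bimodal {0, 255} image yields t = 127. Raises
    :class:`DegenerateImageError` on constant input.
    """
    _, _, _, _, sigma_b2, _, valid = _class_stats(gray)
    if not valid.any():
        raise DegenerateImageError("no valid threshold candidate")
    return _tie_median_argmax(sigma_b2, valid)


def weighted_otsu(gray: np.ndarray, objective: str = "weighted") -> WeightedOtsuResult:
    """Weighted-Otsu threshold search over all 256 candidate levels.

    Parameters
    ----------
    gray : (H, W) uint8 array
    objective : {"weighted", "omega"}
        "weighted" (default) maximizes sigma_b^2(t) * omega(t);
        "omega" maximizes omega(t) itself.
    """
    if objective not in ("weighted", "omega"):
        raise ValidationError(f"unknown objective {objective!r}")
    n_b, n_t, _, _, sigma_b2, var_total, valid = _class_stats(gray)
    if not valid.any():
        raise DegenerateImageError("no valid threshold candidate")
    sigma_t = float(np.sqrt(var_total))
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(valid, np.sqrt(sigma_b2) / sigma_t * (n_b / n_t), np.nan)
        curve = omega if objective == "omega" else sigma_b2 * omega
    t = _tie_median_argmax(np.where(valid, curve, -np.inf), valid)
    return WeightedOtsuResult(
        threshold=t,
        objective_curve=curve,
        omega_curve=omega,
        sigma_b=float(np.sqrt(sigma_b2[t])),
        sigma_t=sigma_t,
        n_b=int(n_b[t]),
        n_t=int(n_t[t]),
        objective=objective,
    )


def binarize(gray: np.ndarray, t: int) -> np.ndarray:
    """Threshold a gray image: pixel > t -> 1, else 0. t is clamped to [0, 255]."""
    gray = np.asarray(gray)
    t = int(np.clip(t, 0, 255))
    return (gray > t).astype(np.uint8)


def morphological_clean(
    mask: np.ndarray,
    radius: int = DEFAULT_DISK_RADIUS,
    min_frac: float = DEFAULT_MIN_COMPONENT_FRAC,
) -> np.ndarray:
    """Opening, closing (disk of ``radius``), then drop small components.

    Components (8-connected) smaller than ``min_frac`` of the total pixel
    count are removed. An empty result is allowed.
    """
    if radius < 1:
        raise ValidationError("radius must be >= 1")
    if not 0 <= min_frac < 1:
        raise ValidationError("min_frac must be in [0, 1)")
    m = np.asarray(mask).astype(bool)
    footprint = morphology.disk(radius)
    m = morphology.opening(m, footprint)
    m = morphology.closing(m, footprint)
    min_size = min_frac * m.size
    if min_size > 1:
        labels = measure.label(m, connectivity=2)
        if labels.max() > 0:
            counts = np.bincount(labels.ravel())
            keep = counts >= min_size  # drop components strictly smaller
            keep[0] = False
            m = keep[labels]
    return m.astype(np.uint8)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component (empty in -> empty out)."""
    m = np.asarray(mask).astype(bool)
    labels = measure.label(m, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(m, dtype=np.uint8)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (labels == counts.argmax()).astype(np.uint8)


def pixel_area(mask: np.ndarray) -> int:
    """Exact count of 1-pixels (plain count, not a weighted-pattern estimate)."""
    mask = np.asarray(mask)
    return int(np.count_nonzero(mask))


def segment_whole_egg(
    img: np.ndarray,
    radius: int = DEFAULT_DISK_RADIUS,
    min_frac: float = DEFAULT_MIN_COMPONENT_FRAC,
    objective: str = "weighted",
) -> EggSegmentation:
    """Full whole-egg segmentation of one RGB candling view.

    grayscale -> weighted Otsu -> binarize -> morphological clean ->
    largest component -> fill holes -> pixel area. Raises
    :class:`SegmentationError` when no egg-like region survives.
    """
    gray = to_grayscale(img)
    try:
        th = weighted_otsu(gray, objective=objective)
    except DegenerateImageError as exc:
        raise SegmentationError(f"whole-egg segmentation failed: {exc}") from exc
    raw = binarize(gray, th.threshold)
    cleaned = morphological_clean(raw, radius=radius, min_frac=min_frac)
    egg = largest_component(cleaned)
    egg = ndi.binary_fill_holes(egg.astype(bool)).astype(np.uint8)
    area = pixel_area(egg)
    if area == 0:
        raise SegmentationError(
            "whole-egg segmentation failed: empty mask after cleanup "
            f"(threshold={th.threshold}, raw foreground={pixel_area(raw)} px)"
        )
    return EggSegmentation(
        mask=egg,
        area_pixels=area,
        threshold=th,
        morphology_params={"radius": radius, "min_frac": min_frac},
    )
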