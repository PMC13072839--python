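"""Seeded candling-image phantoms and storage cohorts with ground truth.

The generator stands in for a physical candling rig: a dark box interior,
a bright tinted egg ellipse with a mild radial light bloom, a darker
eccentric yolk ellipse with a chromatic shift, and a "ghosting" ring of
intermediate attenuation around the yolk projection. Two shell-tint
presets (blue-green and white) emulate the two commercial shell colors; a
10 W / 5500 K cool-white source keeps their transmittance difference
small, so the presets differ mainly in chroma, not structure.

Eggs are imaged from four sides (0, 90, 180, 270 degrees). The yolk sits
eccentrically, so its apparent offset rotates with the viewing angle and
the per-view projected area ratio S varies around the egg's true value;
the four-view mean is unbiased by construction (the modulation is
sinusoidal in the view angle, and four views a quarter-turn apart sum it
to zero).

Storage cohorts model the osmotic swelling of the yolk: the true area
fraction grows linearly with storage day, per-egg random effects add
between-egg spread, and HU / grade follow the linear HU model exactly, so
cohort truth is self-consistent.

Everything is determined by the supplied seed or Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .grading import DEFAULT_INTERCEPT, DEFAULT_SLOPE, hu_grade

#: RGB transmission tints (multipliers on the base luminance) per shell color.
SHELL_TINTS = {
    "blue_green": (0.62, 0.95, 0.82),
    "white": (1.00, 0.93, 0.80),
}

_BASE_LUMINANCE = 235.0
_BACKGROUND_RGB = (16.0, 14.0, 18.0)
#: Chromatic modifiers of the yolk and ghosting regions relative to albumen.
_YOLK_TINT = (1.06, 1.00, 0.55)
_GHOST_TINT = (1.02, 1.00, 0.78)
_GHOST_DARKNESS = 0.93
#: Ghost ring outer radius relative to the yolk ellipse.
_GHOST_SCALE = 1.22

#: Sn-by-grade reference distribution (percent bins, counts out of a
#: 240-egg storage study) used as the default calibration prior. Each row:
#: (low, high, AA count, A count, B-and-below count); bin edges follow the
#: published inclusive/exclusive pattern but sampling is uniform inside
#: the open interval so the distinction is immaterial.
SN_GRADE_BINS = (
    (31.1, 38.2, 36, 3, 0),
    (38.2, 43.6, 5, 13, 0),
    (43.6, 49.7, 0, 38, 0),
    (49.7, 54.3, 0, 28, 2),
    (54.3, 78.2, 0, 10, 105),
)


@dataclass
class SyntheticEggSpec:
    """Parametric description of one phantom egg.

    ``yolk_area_fraction`` is the target S as a fraction of the egg's
    projected area; ``yolk_offset`` (dx, dy) is the eccentric displacement
    of the yolk center in pixels at the 0-degree view; ``yolk_darkness``
    scales the transmitted intensity inside the yolk; ``glow_sigma``
    controls the radial light bloom; ``noise_sigma`` is additive Gaussian
    channel noise in 8-bit units; ``boundary_wobble`` is the amplitude of
    the low-order harmonic perturbation approximating the yolk's irregular
    outline; ``angle_jitter`` is the s.d. of the per-view relative area
    perturbation.
    """

    image_size: tuple[int, int] = (176, 240)
    egg_semi_axes: tuple[float, float] = (96.0, 66.0)
    egg_center: tuple[float, float] | None = None
    shell_tint: str = "blue_green"
    yolk_area_fraction: float = 0.40
    yolk_offset: tuple[float, float] = (0.0, 0.0)
    yolk_darkness: float = 0.82
    glow_sigma: float = 70.0
    noise_sigma: float = 0.0
    boundary_wobble: float = 0.03
    angle_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.shell_tint not in SHELL_TINTS:
            raise ValidationError(f"unknown shell tint {self.shell_tint!r}")
        if not 0.0 < self.yolk_area_fraction < 1.0:
            raise ValidationError("yolk_area_fraction must be in (0, 1)")
        a, b = self.egg_semi_axes
        if a <= 0 or b <= 0:
            raise ValidationError("egg semi-axes must be positive")
        h, w = self.image_size
        cy, cx = self.center
        if not (b < cy < h - b and a < cx < w - a):
            raise ValidationError("egg ellipse must fit inside the image")
        ya, yb = self._yolk_semi_axes(self.yolk_area_fraction)
        dx, dy = self.yolk_offset
        margin = 1.0 + self.boundary_wobble
        if (abs(dx) + ya * margin) > a or (abs(dy) + yb * margin) > b:
            raise ValidationError("yolk ellipse (with offset) exceeds the egg boundary")

    @property
    def center(self) -> tuple[float, float]:
        """(cy, cx) egg center, defaulting to the image center."""
        if self.egg_center is not None:
            return self.egg_center
        h, w = self.image_size
        return (h / 2.0, w / 2.0)

    def _yolk_semi_axes(self, fraction: float) -> tuple[float, float]:
        """Yolk semi-axes giving exactly ``fraction`` of the egg ellipse
        area, shaped slightly rounder than the egg."""
        a, b = self.egg_semi_axes
        e = 0.15  # roundness shift toward a circle
        return (a * math.sqrt(fraction) / math.sqrt(1 + e), b * math.sqrt(fraction) * math.sqrt(1 + e))


def _as_rng(rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(0)
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def render_view(
    spec: SyntheticEggSpec, angle: int, rng=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one view; returns (rgb_image, egg_truth_mask, yolk_truth_mask).

    ``angle`` must be one of 0/90/180/270. The yolk offset vector is
    rotated by the view angle (so the 0- and 180-degree yolk centers
    mirror about the egg center), the per-view area fraction is modulated
    sinusoidally by the eccentricity plus optional jitter, and additive
    Gaussian noise comes from ``rng``. Truth masks are the exact
    rasterized ellipses.
    """
    if angle not in (0, 90, 180, 270):
        raise ValidationError("angle must be one of 0, 90, 180, 270")
    rng = _as_rng(rng)
    h, w = spec.image_size
    cy, cx = spec.center
    a, b = spec.egg_semi_axes
    yy, xx = np.mgrid[0:h, 0:w]
    yy = yy + 0.5 - cy  # pixel-center coordinates relative to egg center
    xx = xx + 0.5 - cx

    egg_mask = ((xx / a) ** 2 + (yy / b) ** 2 <= 1.0).astype(np.uint8)

    # eccentric yolk placement: rotate the offset with the view angle
    theta = math.radians(angle)
    dx, dy = spec.yolk_offset
    rdx = dx * math.cos(theta) - dy * math.sin(theta)
    rdy = dx * math.sin(theta) + dy * math.cos(theta)

    # per-view area modulation: sinusoidal in the view angle (zero-mean
    # over the four quarter-turn views) plus optional random jitter
    off_mag = math.hypot(dx, dy)
    phi = math.atan2(dy, dx) if off_mag > 0 else 0.0
    gamma = 0.5 * off_mag / b
    scale = 1.0 + gamma * math.cos(theta + phi)
    if spec.angle_jitter > 0:
        scale *= 1.0 + rng.normal(0.0, spec.angle_jitter)
    frac = float(np.clip(spec.yolk_area_fraction * scale, 0.02, 0.90))
    # keep the modulated yolk inside the egg: cap the fraction so the
    # wobbled ellipse plus offset still fits on both axes
    e, wob = 0.15, 1.0 + spec.boundary_wobble
    cap_x = ((1.0 - abs(rdx) / a) * math.sqrt(1 + e) / wob) ** 2
    cap_y = ((1.0 - abs(rdy) / b) / (math.sqrt(1 + e) * wob)) ** 2
    frac = min(frac, cap_x, cap_y)
    ya, yb = spec._yolk_semi_axes(frac)

    ydy = yy - rdy
    ydx = xx - rdx
    rho2 = (ydx / ya) ** 2 + (ydy / yb) ** 2
    # low-order harmonic wobble of the yolk outline (area factor 1 + amp^2/2)
    amp = spec.boundary_wobble
    if amp > 0:
        ang = np.arctan2(ydy / yb, ydx / ya)
        wobble = 1.0 + amp * np.cos(3.0 * ang + math.radians(angle))
    else:
        wobble = 1.0
    yolk_mask = ((rho2 <= wobble**2) & egg_mask.astype(bool)).astype(np.uint8)
    ghost_zone = (rho2 <= (_GHOST_SCALE * wobble) ** 2) & egg_mask.astype(bool)
    ghost_mask = ghost_zone & ~yolk_mask.astype(bool)

    # photometry: background, tinted egg with mild radial bloom, darker
    # chromatically shifted yolk, intermediate ghosting ring
    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = np.asarray(_BACKGROUND_RGB)
    tint = np.asarray(SHELL_TINTS[spec.shell_tint])
    r2 = xx**2 + yy**2
    glow = 0.88 + 0.12 * np.exp(-r2 / (2.0 * spec.glow_sigma**2))
    egg_bool = egg_mask.astype(bool)
    base = tint[None, :] * _BASE_LUMINANCE * glow[egg_bool, None]
    img[egg_bool] = base
    img[ghost_mask] *= _GHOST_DARKNESS * np.asarray(_GHOST_TINT)
    img[yolk_mask.astype(bool)] *= spec.yolk_darkness * np.asarray(_YOLK_TINT)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, egg_mask, yolk_mask


def generate_four_views(spec: SyntheticEggSpec, rng=None):
    """Render the 0/90/180/270-degree views of one egg.

    Returns a list of four (image, egg_mask, yolk_mask) triples sharing
    the egg parameters, with per-angle yolk placement.
    """
    rng = _as_rng(rng)
    return [render_view(spec, angle, rng) for angle in (0, 90, 180, 270)]


# --------------------------------------------------------------------------
# storage cohorts
# --------------------------------------------------------------------------


@dataclass
class StorageCohortParams:
    """Storage-study generator settings.

    The true area fraction of egg *i* on day *d* is
    ``sn0 + slope_per_day * d + u_i`` with ``u_i ~ N(0, egg_noise_sd)``,
    clipped to (0.05, 0.90). Defaults place day 0 in grade AA and day 36
    in grade B-and-below under the linear HU link. ``days`` defaults to the
    ten sampling days of a 36-day storage trial.
    """

    n_eggs: int = 20
    days: tuple = (0, 4, 8, 12, 16, 20, 24, 28, 32, 36)
    sn0: float = 0.33
    slope_per_day: float = 0.0075
    egg_noise_sd: float = 0.02
    angle_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eggs < 1:
            raise ValidationError("n_eggs must be >= 1")
        lo = self.sn0 + self.slope_per_day * min(self.days)
        hi = self.sn0 + self.slope_per_day * max(self.days)
        if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0):
            raise ValidationError("mean sn must stay inside (0, 1) over the day range")


@dataclass
class CohortRecord:
    """One egg-day: truth values plus (optionally) four rendered views."""

    egg_id: int
    day: float
    shell_tint: str
    sn_true: float
    hu: float
    grade: str
    views: list | None = None


def generate_storage_cohort(
    params: StorageCohortParams | None = None,
    rng=None,
    render: bool = True,
    spec_template: SyntheticEggSpec | None = None,
) -> list[CohortRecord]:
    """Generate a storage cohort; HU and grade follow the linear HU model.

    Shell tints alternate between eggs. With ``render=False`` only the
    truth table is produced (fast path for statistical tests).
    """
    params = params or StorageCohortParams()
    rng = _as_rng(params.seed if rng is None else rng)
    template = spec_template or SyntheticEggSpec()
    tints = list(SHELL_TINTS)
    records: list[CohortRecord] = []
    for egg_id in range(params.n_eggs):
        u = rng.normal(0.0, params.egg_noise_sd)
        off_mag = rng.uniform(3.0, 8.0)
        off_ang = rng.uniform(0.0, 2 * math.pi)
        tint = tints[egg_id % len(tints)]
        for day in params.days:
            sn = float(np.clip(params.sn0 + params.slope_per_day * day + u, 0.05, 0.90))
            hu = DEFAULT_SLOPE * sn + DEFAULT_INTERCEPT
            rec = CohortRecord(
                egg_id=egg_id,
                day=float(day),
                shell_tint=tint,
                sn_true=sn,
                hu=float(hu),
                grade=hu_grade(hu),
            )
            if render:
                spec = replace(
                    template,
                    shell_tint=tint,
                    yolk_area_fraction=sn,
                    yolk_offset=(off_mag * math.cos(off_ang), off_mag * math.sin(off_ang)),
                    angle_jitter=params.angle_jitter,
                )
                rec.views = generate_four_views(spec, rng)
            records.append(rec)
    return records


# --------------------------------------------------------------------------
# statistical resampling helpers
# --------------------------------------------------------------------------


def sample_from_bin_table(n_total: int = 240, rng=None, bins=SN_GRADE_BINS):
    """Resample (Sn percent, grade) pairs from the reference binned
    distribution, uniform within each bin.

    With ``n_total=240`` the exact reference counts are used; other sizes
    scale each count proportionally (largest-remainder rounding).
    """
    rng = _as_rng(rng)
    counts = np.asarray([[row[2], row[3], row[4]] for row in bins], dtype=np.float64)
    ref_total = counts.sum()
    scaled = counts * (n_total / ref_total)
    rounded = np.floor(scaled).astype(int)
    deficit = n_total - rounded.sum()
    if deficit > 0:
        order = np.argsort((scaled - rounded).ravel())[::-1]
        for idx in order[:deficit]:
            rounded.ravel()[idx] += 1
    samples = []
    from .grading import GRADES

    for (lo, hi, *_), row in zip(bins, rounded):
        for grade, cnt in zip(GRADES, row):
            if cnt > 0:
                samples.extend((float(s), grade) for s in rng.uniform(lo, hi, size=cnt))
    rng.shuffle(samples)
    return samples


def sample_regression_pairs(
    n: int,
    slope: float = DEFAULT_SLOPE,
    intercept: float = DEFAULT_INTERCEPT,
    noise_sd: float = 2.0,
    sn_range: tuple[float, float] = (0.31, 0.78),
    rng=None,
) -> np.ndarray:
    """Draw (sn fraction, hu) pairs from the linear HU model plus Gaussian
    measurement noise; the parameter-recovery benchmark for the HU fit."""
    rng = _as_rng(rng)
    if n < 3:
        raise ValidationError("need n >= 3")
    sn = rng.uniform(sn_range[0], sn_range[1], size=n)
    hu = slope * sn + intercept + rng.normal(0.0, noise_sd, size=n)
    return np.column_stack([sn, hu])
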