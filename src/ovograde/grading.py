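"""Freshness features, Haugh-Unit model, threshold calibration, evaluation.

The freshness feature is the yolk projected area ratio

    S = S_SMALL / S_BIG * 100 %          (one view)
    Sn = (S1 + S2 + S3 + S4) / 4         (mean over the four views)

where ``S_SMALL`` and ``S_BIG`` are the yolk and whole-egg projected pixel
areas. Freshness itself is measured destructively as the Haugh Unit

    HU = 100 * log10(H + 7.57 - 1.7 * W**0.37)

from albumen height H (mm) and egg weight W (g), with grades AA (HU >= 72),
A (60 <= HU < 72) and "B and below" (HU < 60, restricted for processing).
A linear model HU = slope * Sn + intercept (Sn as a FRACTION in [0, 1];
the reference fit is HU = -74.14 * Sn + 101.29) links the image feature to
HU, and two Sn cut-points assign grades directly:

    AA: Sn <= t_aa        A: t_aa < Sn < t_b        B and below: Sn >= t_b

Cut-points are calibrated by maximizing the Youden index
J = sensitivity + specificity - 1, with a food-safety constraint: the B
boundary must keep sensitivity for inedible eggs above a configurable
floor (default 0.95).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .eggseg import EggSegmentation, segment_whole_egg
from .errors import SegmentationError, ValidationError
from .yolkseg import EnhancementParams, KMeansConfig, segment_yolk

GRADES = ("AA", "A", "B")  # "B" stands for "B and below" throughout

#: HU grade boundaries: AA at HU >= 72, A at 60 <= HU < 72.
HU_AA_BOUNDARY = 72.0
HU_A_BOUNDARY = 60.0

#: Reference linear model HU = -74.14 * Sn + 101.29 (Sn as fraction).
DEFAULT_SLOPE = -74.14
DEFAULT_INTERCEPT = 101.29


# --------------------------------------------------------------------------
# feature and HU arithmetic
# --------------------------------------------------------------------------


def area_ratio(s_small: int, s_big: int) -> float:
    """Yolk-to-egg projected area ratio in percent: 100 * S_SMALL / S_BIG."""
    if s_big <= 0:
        raise ValidationError("whole-egg area must be positive")
    if s_small < 0 or s_small > s_big:
        raise ValidationError("yolk area must be in [0, whole-egg area]")
    return 100.0 * s_small / s_big


def mean_ratio(s_list) -> float:
    """Arithmetic mean of 1-4 per-view ratios (percent); Sn for four views."""
    s_list = list(s_list)
    if not 1 <= len(s_list) <= 4:
        raise ValidationError("expected between 1 and 4 per-view ratios")
    return float(np.mean(s_list))


def haugh_unit(h: float, w: float) -> float:
    """Haugh Unit from albumen height h (mm) and egg weight w (g)."""
    if h <= 0 or w <= 0:
        raise ValidationError("albumen height and egg weight must be positive")
    arg = h + 7.57 - 1.7 * w**0.37
    if arg <= 0:
        raise ValidationError(
            f"HU undefined: H + 7.57 - 1.7*W^0.37 = {arg:.4f} <= 0 (albumen too flat)"
        )
    return 100.0 * math.log10(arg)


def hu_grade(hu: float) -> str:
    """Grade from a Haugh Unit: AA (>= 72), A ([60, 72)), else B and below."""
    if not math.isfinite(hu):
        raise ValidationError("HU must be finite")
    if hu >= HU_AA_BOUNDARY:
        return "AA"
    if hu >= HU_A_BOUNDARY:
        return "A"
    return "B"


@dataclass
class ReplicateSummary:
    """Replicate albumen-height protocol: mean of readings plus RSD check.

    The measurement protocol averages three-point readings from two
    operators; a relative standard deviation >= 5% flags an unreliable
    measurement.
    """

    mean_height: float
    rsd_percent: float
    acceptable: bool


def average_albumen_height(readings, rsd_limit: float = 5.0) -> ReplicateSummary:
    """Average replicate H readings (mm) and flag RSD >= ``rsd_limit`` %."""
    readings = np.asarray(list(readings), dtype=np.float64)
    if readings.size < 2 or np.any(readings <= 0):
        raise ValidationError("need >= 2 positive albumen-height readings")
    mean = float(readings.mean())
    rsd = float(readings.std(ddof=1) / mean * 100.0)
    return ReplicateSummary(mean_height=mean, rsd_percent=rsd, acceptable=rsd < rsd_limit)


# --------------------------------------------------------------------------
# HU regression
# --------------------------------------------------------------------------


@dataclass
class HuRegression:
    """Linear HU model: HU = slope * Sn + intercept with Sn a fraction."""

    slope: float
    intercept: float
    r2: float | None = None
    mae: float | None = None
    shapiro_w: float | None = None
    shapiro_p: float | None = None


DEFAULT_MODEL = HuRegression(slope=DEFAULT_SLOPE, intercept=DEFAULT_INTERCEPT)


def predict_hu(sn: float, model: HuRegression = DEFAULT_MODEL) -> float:
    """Predicted HU at a given Sn.

    ``sn`` must be a FRACTION in [0, 1]; passing a percent value raises, as
    the linear model only makes sense on the fraction scale (slope * 38.2
    would be an absurd HU).
    """
    if not 0.0 <= sn <= 1.0:
        raise ValidationError(
            f"sn={sn!r} outside [0, 1]; pass the area ratio as a fraction, not percent"
        )
    return model.slope * sn + model.intercept


def fit_hu_regression(pairs) -> HuRegression:
    """Ordinary least squares of HU on Sn (fractions).

    Reports R^2, the mean absolute error of fitted vs observed HU, and a
    Shapiro-Wilk residual-normality statistic. Requires >= 3 pairs with
    non-constant Sn.
    """
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("need >= 3 (sn, hu) pairs")
    sn, hu = arr[:, 0], arr[:, 1]
    if np.ptp(sn) == 0:
        raise ValidationError("degenerate design: all sn values equal")
    res = _stats.linregress(sn, hu)
    fitted = res.slope * sn + res.intercept
    resid = hu - fitted
    ss_res = float((resid**2).sum())
    ss_tot = float(((hu - hu.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    mae = float(np.abs(resid).mean())
    if np.ptp(resid) > 0:
        sw = _stats.shapiro(resid)
        shapiro_w, shapiro_p = float(sw.statistic), float(sw.pvalue)
    else:
        shapiro_w, shapiro_p = 1.0, 1.0
    return HuRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        mae=mae,
        shapiro_w=shapiro_w,
        shapiro_p=shapiro_p,
    )


# --------------------------------------------------------------------------
# grade assignment and threshold calibration
# --------------------------------------------------------------------------


@dataclass
class GradingThresholds:
    """The two Sn cut-points (percent) defining AA / A / B-and-below."""

    t_aa: float = 38.2
    t_b: float = 54.3

    def __post_init__(self) -> None:
        if not 0 < self.t_aa < self.t_b < 100:
            raise ValidationError("thresholds must satisfy 0 < t_aa < t_b < 100")


DEFAULT_THRESHOLDS = GradingThresholds()


def classify(sn: float, thresholds: GradingThresholds = DEFAULT_THRESHOLDS) -> str:
    """Grade from Sn in percent: AA if Sn <= t_aa, B if Sn >= t_b, else A.

    Boundary inclusivity follows the published rule exactly (<= for AA,
    >= for B and below).
    """
    if not 0.0 <= sn <= 100.0:
        raise ValidationError("sn (percent) must be in [0, 100]")
    if sn <= thresholds.t_aa:
        return "AA"
    if sn >= thresholds.t_b:
        return "B"
    return "A"


@dataclass
class BinaryMetrics:
    sensitivity: float
    specificity: float
    youden_j: float


def binary_metrics(truth, pred, positive: str) -> BinaryMetrics:
    """Sensitivity, specificity and Youden J for one grade vs the rest."""
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise ValidationError("truth and pred must have equal length")
    t = np.asarray([x == positive for x in truth])
    p = np.asarray([x == positive for x in pred])
    if not t.any():
        raise ValidationError(f"no {positive!r} samples in truth; sensitivity undefined")
    if t.all():
        raise ValidationError(f"only {positive!r} samples in truth; specificity undefined")
    tp = int(np.count_nonzero(t & p))
    fn = int(np.count_nonzero(t & ~p))
    tn = int(np.count_nonzero(~t & ~p))
    fp = int(np.count_nonzero(~t & p))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return BinaryMetrics(sensitivity=sens, specificity=spec, youden_j=sens + spec - 1.0)


@dataclass
class CalibrationResult:
    """Calibrated thresholds plus the Youden-index curves behind them.

    ``j_curve_b`` / ``j_curve_aa`` list ``(candidate, J, sensitivity)``
    triples. ``constraint_met`` is False when no candidate satisfied the
    B-sensitivity floor, in which case the unconstrained maximum was used.
    """

    thresholds: GradingThresholds
    j_curve_b: list = field(default_factory=list)
    j_curve_aa: list = field(default_factory=list)
    constraint_met: bool = True


def calibrate_thresholds(samples, sens_floor: float = 0.95) -> CalibrationResult:
    """Calibrate (t_aa, t_b) from (Sn percent, true grade) samples.

    Candidate cut-points are the midpoints of consecutive sorted unique Sn
    values. ``t_b`` maximizes Youden J for B-and-below vs rest (predicted B
    when Sn >= t), subject to B sensitivity >= ``sens_floor``; ties take the
    lower threshold (safety). ``t_aa`` is the candidate below ``t_b``
    maximizing J for AA vs rest (predicted AA when Sn <= t), ties lower.
    """
    samples = [(float(s), g) for s, g in samples]
    if not 0.0 <= sens_floor <= 1.0:
        raise ValidationError("sens_floor must be in [0, 1]")
    grades_present = {g for _, g in samples}
    if not set(GRADES) <= grades_present:
        raise ValidationError(f"all grades {GRADES} must be present, got {grades_present}")
    if any(g not in GRADES for _, g in samples):
        raise ValidationError("sample grades must be in " + repr(GRADES))
    sn = np.asarray([s for s, _ in samples])
    grade = np.asarray([g for _, g in samples])
    uniq = np.unique(sn)
    if uniq.size < 2:
        raise ValidationError("need at least two distinct Sn values")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    is_b = grade == "B"
    j_curve_b = []
    for c in candidates:
        pred_b = sn >= c
        sens = float(np.count_nonzero(is_b & pred_b) / np.count_nonzero(is_b))
        spec = float(np.count_nonzero(~is_b & ~pred_b) / np.count_nonzero(~is_b))
        j_curve_b.append((float(c), sens + spec - 1.0, sens))
    feasible = [(c, j, s) for c, j, s in j_curve_b if s >= sens_floor]
    pool = feasible if feasible else j_curve_b
    best_j = max(j for _, j, _ in pool)
    t_b = min(c for c, j, _ in pool if np.isclose(j, best_j, rtol=0, atol=1e-12))

    is_aa = grade == "AA"
    j_curve_aa = []
    for c in candidates:
        if c >= t_b:
            continue
        pred_aa = sn <= c
        sens = float(np.count_nonzero(is_aa & pred_aa) / np.count_nonzero(is_aa))
        spec = float(np.count_nonzero(~is_aa & ~pred_aa) / np.count_nonzero(~is_aa))
        j_curve_aa.append((float(c), sens + spec - 1.0, sens))
    if not j_curve_aa:
        raise ValidationError("no candidate cut-point available below t_b")
    best_j_aa = max(j for _, j, _ in j_curve_aa)
    t_aa = min(c for c, j, _ in j_curve_aa if np.isclose(j, best_j_aa, rtol=0, atol=1e-12))

    return CalibrationResult(
        thresholds=GradingThresholds(t_aa=t_aa, t_b=t_b),
        j_curve_b=j_curve_b,
        j_curve_aa=j_curve_aa,
        constraint_met=bool(feasible),
    )


# --------------------------------------------------------------------------
# evaluation statistics
# --------------------------------------------------------------------------


@dataclass
class ConfusionMatrix3:
    """3x3 confusion counts; rows = true grade, columns = predicted,
    both ordered (AA, A, B-and-below)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValidationError("counts must be a 3x3 non-negative matrix")
        self.counts = c


@dataclass
class ConfusionSummary:
    matrix: ConfusionMatrix3
    overall_accuracy: float
    per_class_recall: dict
    weighted_accuracy: float


def summarize_confusion(matrix: ConfusionMatrix3) -> ConfusionSummary:
    """Overall accuracy, per-class recall, and prevalence-weighted accuracy.

    Weighted accuracy = sum_c prevalence_c * recall_c. With prevalence
    weights this is algebraically identical to overall accuracy (each term
    is diag_c / total); both are reported because they are quoted
    separately in practice.
    """
    c = matrix.counts
    total = int(c.sum())
    if total == 0:
        raise ValidationError("empty confusion matrix")
    overall = float(np.trace(c) / total)
    recalls = {}
    weighted = 0.0
    for i, g in enumerate(GRADES):
        row = int(c[i].sum())
        rec = float(c[i, i] / row) if row else float("nan")
        recalls[g] = rec
        if row:
            weighted += (row / total) * rec
    return ConfusionSummary(
        matrix=matrix,
        overall_accuracy=overall,
        per_class_recall=recalls,
        weighted_accuracy=float(weighted),
    )


def confusion_and_accuracy(truth, pred) -> ConfusionSummary:
    """Confusion matrix and accuracy statistics from per-sample labels."""
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise ValidationError("truth and pred must have equal length")
    idx = {g: i for i, g in enumerate(GRADES)}
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truth, pred):
        if t not in idx or p not in idx:
            raise ValidationError(f"label outside grade set {GRADES}: {(t, p)!r}")
        counts[idx[t], idx[p]] += 1
    return summarize_confusion(ConfusionMatrix3(counts))


def chi_square_compare(
    correct_a: int, n_a: int, correct_b: int, n_b: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) comparing two correct/incorrect proportions.

    No continuity correction by default. Raises on zero margins.
    """
    if not (0 <= correct_a <= n_a and 0 <= correct_b <= n_b):
        raise ValidationError("correct counts must be within totals")
    table = np.array(
        [[correct_a, n_a - correct_a], [correct_b, n_b - correct_b]], dtype=np.float64
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined: zero row or column margin")
    res = _stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# whole-egg report
# --------------------------------------------------------------------------


@dataclass
class AreaRatioResult:
    """Per-view ratios S1..S4 (percent), their mean Sn, and the raw areas."""

    s_per_angle: list
    s_mean: float
    s_small: list
    s_big: list


@dataclass
class FreshnessReport:
    """End-to-end grading result for one egg (1-4 candling views)."""

    s_per_angle: list
    sn_percent: float
    predicted_hu: float
    grade: str
    single_angle: bool
    view_failures: list = field(default_factory=list)


def grade_egg(
    views,
    model: HuRegression = DEFAULT_MODEL,
    thresholds: GradingThresholds = DEFAULT_THRESHOLDS,
    kcfg: KMeansConfig | None = None,
    ecfg: EnhancementParams | None = None,
    radius: int = 5,
    min_frac: float = 0.005,
) -> FreshnessReport:
    """Grade one egg from its candling views.

    Runs the full segmentation pipeline per view, averages the surviving
    per-view ratios into Sn, and reports the grade and predicted HU.
    Per-view failures are recorded; if every view fails a
    :class:`SegmentationError` is raised.
    """
    views = list(views)
    if not 1 <= len(views) <= 4:
        raise ValidationError("expected between 1 and 4 views")
    s_values: list[float] = []
    failures: list[tuple[int, str]] = []
    for i, img in enumerate(views):
        try:
            egg: EggSegmentation = segment_whole_egg(img, radius=radius, min_frac=min_frac)
            yolk = segment_yolk(img, egg, kcfg=kcfg, ecfg=ecfg)
            s_values.append(area_ratio(yolk.area_pixels, egg.area_pixels))
        except (SegmentationError, ValidationError) as exc:
            failures.append((i, str(exc)))
    if not s_values:
        raise SegmentationError(f"all {len(views)} views failed segmentation: {failures}")
    sn = mean_ratio(s_values)
    return FreshnessReport(
        s_per_angle=s_values,
        sn_percent=sn,
        predicted_hu=predict_hu(sn / 100.0, model),
        grade=classify(sn, thresholds),
        single_angle=len(views) == 1,
        view_failures=failures,
    )
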