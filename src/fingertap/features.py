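"""The 15 clinically aligned finger-tapping features.

From a set of detected tap peaks (times t_n, amplitudes A_n, n = 1..N) and
the subject's demographics, this module computes:

* demographics: age, sex (0 = female, 1 = male);
* amplitude: mean and population variance of A_n, plus the three parameters
  of a continuous two-segment ("broken-stick") linear trend
  y = a0 + a1*x + a2*(x - bp)*1[x > bp] fitted against the peak ordinal x,
  capturing amplitude decrement and where in the tap sequence it starts;
* velocity: pseudo-velocity V_n = (A_n + A_{n-1}) / (t_n - t_{n-1}) for each
  consecutive peak pair, its mean/population variance, and the same
  broken-stick trend parameters for velocity decrement;
* rhythm: tapping frequency (N - 1) / (t_N - t_1), peak count N, and the
  halt/hesitation count — peaks whose amplitude drops below the fitted trend
  by at least 20% of the mean of the two neighbouring amplitudes.

The broken-stick fit is solved by its definition: exhaustive search of the
breakpoint over interior peak ordinals with an ordinary least-squares fit per
candidate, earliest breakpoint winning ties.  The clinical rating criteria
reference tap count ("midway in the 10-tap sequence"), so the trend abscissa
is the peak ordinal, not wall time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .keypoints import Demographics
from .signal import PeakSet

logger = logging.getLogger(__name__)

#: Canonical feature order; every feature table and model uses exactly this.
FEATURE_NAMES: tuple[str, ...] = (
    "age",
    "sex",
    "amp_var",
    "amp_avg",
    "amp_bp",
    "amp_alpha1",
    "amp_alpha2",
    "vel_var",
    "vel_avg",
    "vel_bp",
    "vel_alpha1",
    "vel_alpha2",
    "freq",
    "hh",
    "n_peaks",
)

DEFAULT_ALPHA = 0.2  # halt/hesitation threshold fraction of neighbour mean


@dataclass
class PiecewiseFit:
    """Continuous two-segment linear fit.

    ``slope2`` is the *incremental* slope of the second segment: beyond the
    breakpoint the total slope is ``slope1 + slope2``.  ``breakpoint`` is a
    peak ordinal (1-based position in the tap sequence).  ``degenerate`` marks
    fits on < 4 points, which fall back to a single line with slope2 = 0.
    """

    intercept: float
    slope1: float
    slope2: float
    breakpoint: float
    rss: float
    fitted: np.ndarray
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        hinge = np.where(x > self.breakpoint, x - self.breakpoint, 0.0)
        return self.intercept + self.slope1 * x + self.slope2 * hinge


@dataclass
class VelocitySeries:
    """Pseudo-velocities V_n and the inter-peak intervals behind them."""

    values: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if np.any(self.intervals <= 0):
            raise ValidationError("inter-peak intervals must be positive")


@dataclass
class FeatureVector:
    """The 15 features in canonical order plus provenance metadata."""

    values: dict[str, float]
    subject_id: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValidationError(
                f"feature vector must have exactly the 15 canonical features; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def to_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_NAMES], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def amplitude_stats(peaks: PeakSet) -> tuple[float, float]:
    """Mean and population (1/N) variance of the peak amplitudes."""
    a = peaks.amplitudes
    avg = float(np.mean(a))
    var = float(np.mean((a - avg) ** 2))
    return avg, var


def velocity_series(peaks: PeakSet) -> VelocitySeries:
    """V_n = (A_n + A_{n-1}) / Delta t_n for consecutive peak pairs.

    The numerator is the opening distance covered closing then re-opening
    between two full openings, so V_n is a per-cycle average speed in palm
    units per second.
    """
    if peaks.n < 2:
        raise ValidationError("velocity needs at least 2 peaks")
    dt = np.diff(peaks.times)
    if np.any(dt <= 0):
        raise ValidationError("peak times must be strictly increasing")
    v = (peaks.amplitudes[1:] + peaks.amplitudes[:-1]) / dt
    return VelocitySeries(values=v, intervals=dt)


def velocity_stats(v: VelocitySeries) -> tuple[float, float]:
    """Mean and population variance of the pseudo-velocities."""
    avg = float(np.mean(v.values))
    var = float(np.mean((v.values - avg) ** 2))
    return avg, var


def fit_piecewise(x: np.ndarray, y: np.ndarray) -> PiecewiseFit:
    """Broken-stick OLS fit with exhaustive interior-breakpoint search.

    Candidates are the interior data positions x_2..x_{N-1}; for each, the
    continuous model [1, x, (x-bp)^+] is fitted by least squares and the
    candidate with the smallest residual sum of squares wins, earliest
    breakpoint on ties.  With fewer than 4 points the fit degrades to a
    single line (slope2 = 0, breakpoint at the x midpoint) and is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 4:
        if n < 2:
            raise ValidationError("piecewise fit needs at least 2 points")
        design = np.column_stack([np.ones(n), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
        rss = float(np.sum((y - fitted) ** 2))
        return PiecewiseFit(
            intercept=float(coef[0]),
            slope1=float(coef[1]),
            slope2=0.0,
            breakpoint=float(0.5 * (x[0] + x[-1])),
            rss=rss,
            fitted=fitted,
            degenerate=True,
        )

    best: tuple[float, float, np.ndarray, np.ndarray] | None = None
    for bp in x[1:-1]:
        hinge = np.where(x > bp, x - bp, 0.0)
        design = np.column_stack([np.ones(n), x, hinge])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
        rss = float(np.sum((y - fitted) ** 2))
        if best is None or rss < best[0] - 1e-12 * max(1.0, best[0]):
            best = (rss, float(bp), coef, fitted)
    rss, bp, coef, fitted = best  # type: ignore[misc]
    return PiecewiseFit(
        intercept=float(coef[0]),
        slope1=float(coef[1]),
        slope2=float(coef[2]),
        breakpoint=bp,
        rss=rss,
        fitted=fitted,
    )


def _amplitude_trend(peaks: PeakSet) -> PiecewiseFit:
    ordinals = np.arange(1, peaks.n + 1, dtype=float)
    return fit_piecewise(ordinals, peaks.amplitudes)


def decrement_features(values: np.ndarray) -> tuple[float, float, float]:
    """Trend parameters (slope1, slope2, breakpoint) of a peak-ordered series.

    Works for peak amplitudes and for the velocity series alike; the abscissa
    is the 1-based ordinal of each value.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        logger.warning("decrement trend undefined for %d value(s); returning zeros",
                       values.size)
        return 0.0, 0.0, 1.0
    fit = fit_piecewise(np.arange(1, values.size + 1, dtype=float), values)
    return fit.slope1, fit.slope2, fit.breakpoint


def halt_hesitation_count(
    peaks: PeakSet,
    alpha: float = DEFAULT_ALPHA,
    leave_one_out: bool = False,
) -> int:
    """Count halts/hesitations: sudden amplitude drops below the tap trend.

    The amplitude trend is the broken-stick fit over all peaks.  An interior
    peak n is flagged when its amplitude falls *below* the trend by at least
    theta = alpha * (A_{n-1} + A_{n+1}) / 2 — i.e. the drop exceeds 20% (by
    default) of the mean amplitude immediately before and after.  Upward
    outliers are not clinical halts and are never counted.

    With ``leave_one_out=True`` the trend for peak n is refitted without peak
    n (sensitivity-analysis variant; slower).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if peaks.n < 3:
        logger.warning("halt/hesitation needs >= 3 peaks; returning 0")
        return 0
    a = peaks.amplitudes
    ordinals = np.arange(1, peaks.n + 1, dtype=float)
    if leave_one_out:
        predicted = np.empty(peaks.n)
        for i in range(peaks.n):
            mask = np.ones(peaks.n, dtype=bool)
            mask[i] = False
            fit = fit_piecewise(ordinals[mask], a[mask])
            predicted[i] = fit.predict(ordinals[i : i + 1])[0]
    else:
        predicted = _amplitude_trend(peaks).fitted
    count = 0
    for i in range(1, peaks.n - 1):
        theta = alpha * 0.5 * (a[i - 1] + a[i + 1])
        residual = abs(predicted[i] - a[i])
        if residual >= theta and a[i] < predicted[i]:
            count += 1
    return count


def frequency_and_count(peaks: PeakSet) -> tuple[float, int]:
    """Tapping frequency in Hz and the number of peaks.

    Frequency is (N - 1) cycles over the first-to-last peak span, which is
    insensitive to idle recording before/after the task.  A single peak has
    no defined frequency; 0.0 is returned with a warning.
    """
    if peaks.n < 2:
        logger.warning("frequency undefined for a single peak; returning 0.0")
        return 0.0, peaks.n
    span = float(peaks.times[-1] - peaks.times[0])
    return (peaks.n - 1) / span, peaks.n


def build_feature_vector(
    peaks: PeakSet,
    demographics: Demographics,
    alpha: float = DEFAULT_ALPHA,
    subject_id: str = "",
) -> FeatureVector:
    """Assemble the 15 features in canonical order."""
    flags: list[str] = []
    amp_avg, amp_var = amplitude_stats(peaks)
    amp_a1, amp_a2, amp_bp = decrement_features(peaks.amplitudes)
    if peaks.n >= 2:
        vel = velocity_series(peaks)
        vel_avg, vel_var = velocity_stats(vel)
        vel_a1, vel_a2, vel_bp = decrement_features(vel.values)
    else:
        # a single usable tap: the task is barely performed; velocity is
        # undefined, reported as zero and flagged
        logger.warning("single peak: velocity features undefined, set to 0")
        vel_avg = vel_var = vel_a1 = vel_a2 = 0.0
        vel_bp = 1.0
        flags.append("single_peak")
    freq, n_peaks = frequency_and_count(peaks)
    hh = halt_hesitation_count(peaks, alpha=alpha)
    values = {
        "age": float(demographics.age),
        "sex": float(demographics.sex_code),
        "amp_var": amp_var,
        "amp_avg": amp_avg,
        "amp_bp": amp_bp,
        "amp_alpha1": amp_a1,
        "amp_alpha2": amp_a2,
        "vel_var": vel_var,
        "vel_avg": vel_avg,
        "vel_bp": vel_bp,
        "vel_alpha1": vel_a1,
        "vel_alpha2": vel_a2,
        "freq": freq,
        "hh": float(hh),
        "n_peaks": float(n_peaks),
    }
    return FeatureVector(values=values, subject_id=subject_id, flags=flags)


def feature_label_correlations(
    features: np.ndarray,
    labels: np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    """Pearson r between each of the 15 features and the severity label.

    ``features`` is (n_samples, 15) in canonical order.  A constant feature
    (or constant labels) has undefined r; it is reported as 0.0 and its name
    returned in the flag list.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if features.ndim != 2 or features.shape[1] != len(FEATURE_NAMES):
        raise ValidationError("features must be (n_samples, 15)")
    if features.shape[0] != labels.size or labels.size < 3:
        raise ValidationError("need >= 3 matching samples")
    flags: list[str] = []
    r = np.zeros(len(FEATURE_NAMES))
    label_sd = labels.std()
    for j, name in enumerate(FEATURE_NAMES):
        col = features[:, j]
        if col.std() == 0 or label_sd == 0:
            flags.append(name)
            continue
        r[j] = float(np.corrcoef(col, labels)[0, 1])
    return r, flags
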