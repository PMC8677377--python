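"""Similarity verdict from a warping path: regression against the ideal line.

If two movements are identical, the warping path lies on the diagonal and its
regression against the ideal line ``y = x`` is exact.  The comparison is
carried out on a single randomly chosen cycle window (comparing the entire
recording washes out differences: long paths regress toward the ideal line
regardless of shape).  Three criteria make the verdict: equal periods, the
coefficient of determination of the path regression above ``r2_min``, and the
mean absolute gap between the fitted line and the ideal line below
``diff_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .alignment import SyncResult, synchronize
from .conditioning import (
    DEFAULT_FILTER_WINDOW,
    DEFAULT_NORMALIZE_SCALE,
    min_max_normalize,
    moving_average_filter,
)
from .io_signals import MagnitudeSeries, validate_pair
from .periodicity import (
    PeakParams,
    estimate_period,
    pearson_iterations,
    periods_equal,
)
from .warping import WarpPath, cost_matrix, dp_path, greedy_path

#: operational thresholds: mean line difference < 10 (on the 0..10000
#: normalized scale) and R^2 > 0.9
DEFAULT_DIFF_MAX = 10.0
DEFAULT_R2_MIN = 0.9


class WindowTooShortError(ValueError):
    """Raised when a series cannot supply a full analysis window."""


@dataclass(frozen=True)
class Thresholds:
    diff_max: float = DEFAULT_DIFF_MAX
    r2_min: float = DEFAULT_R2_MIN


@dataclass(frozen=True)
class CycleWindow:
    """One randomly selected cycle of the aligned recordings.

    Sample numbers are 1-based and inclusive, so the window holds
    ``period + 1`` samples; ``initial_sample = k * period`` for the chosen
    cycle multiple ``k``.
    """

    initial_sample: int
    final_sample: int
    k: int
    seed: int | None

    @property
    def n_samples(self) -> int:
        return self.final_sample - self.initial_sample + 1

    def slice(self, v: MagnitudeSeries) -> np.ndarray:
        return v.values[self.initial_sample - 1 : self.final_sample]


@dataclass(frozen=True)
class ComparisonReport:
    """Full outcome of a two-recording comparison."""

    verdict: Literal["similar", "different"]
    reasons: list[str]
    periods_equal: bool
    period_expert: int
    period_learner: int
    thresholds: Thresholds
    m: float | None = None
    b: float | None = None
    r_squared: float | None = None
    mean_line_diff: float | None = None
    window: CycleWindow | None = None
    shift_applied: int | None = None
    common_length: int | None = None
    sync_low_confidence: bool = False
    discrepant_segments: list[tuple[int, int]] = field(default_factory=list)
    path_method: str = "greedy"


def select_cycle_window(
    total_length: int, period: int, seed: int | None, k: int | None = None
) -> CycleWindow:
    """Choose the cycle to analyze: ``k`` uniform in ``1..sample_limit``.

    ``sample_limit = floor(total_length / period) - 1`` so the inclusive
    window ``k*period .. k*period + period`` always fits.  Passing ``k``
    overrides the random draw (used to reproduce a specific cycle).
    """
    if period < 1:
        raise ValueError("period must be positive")
    sample_limit = total_length // period - 1
    if sample_limit < 1:
        raise WindowTooShortError(
            f"series of {total_length} samples holds fewer than two periods of {period}"
        )
    if k is None:
        k = int(np.random.default_rng(seed).integers(1, sample_limit + 1))
    elif not 1 <= k <= sample_limit:
        raise ValueError(f"cycle multiple k={k} outside 1..{sample_limit}")
    initial = k * period
    return CycleWindow(initial_sample=initial, final_sample=initial + period, k=k, seed=seed)


def fit_path_line(path: WarpPath) -> tuple[float, float]:
    """Ordinary least squares of the path's j-coordinates on its i-coordinates."""
    i, j = path.i.astype(float), path.j.astype(float)
    if i.size < 3:
        raise ValueError("need at least 3 path points to fit a line")
    if np.ptp(i) == 0:
        raise ValueError("all i-coordinates identical; slope undefined")
    res = stats.linregress(i, j)
    return float(res.slope), float(res.intercept)


def r_squared(path: WarpPath, fit: tuple[float, float]) -> float:
    """Coefficient of determination of the fitted line over the path points."""
    m, b = fit
    i, j = path.i.astype(float), path.j.astype(float)
    ss_tot = float(np.sum((j - j.mean()) ** 2))
    ss_res = float(np.sum((j - (m * i + b)) ** 2))
    if ss_tot == 0.0:
        if ss_res <= 1e-12:
            return 1.0
        raise ValueError("zero variance in j but non-zero residuals")
    return 1.0 - ss_res / ss_tot


def mean_line_difference(fit: tuple[float, float], path: WarpPath) -> float:
    """Mean absolute vertical gap between the fitted line and ``y = x``.

    Evaluated at the path's i-coordinates; depends on the path only through
    its i-range, not its j-values.
    """
    m, b = fit
    i = path.i.astype(float)
    return float(np.mean(np.abs((m * i + b) - i)))


def localize_discrepancy(
    expert_window: np.ndarray,
    learner_window: np.ndarray,
    path: WarpPath,
    band_fraction: float = 0.25,
    merge_gap: int = 5,
) -> list[tuple[int, int]]:
    """Contiguous expert-sample ranges where the matched samples stay far apart.

    A path point is discrepant when its local cost ``|u[j] - v[i]|`` exceeds
    ``band_fraction`` times the value spread of the two windows.  Discrepant
    i-ranges closer than ``merge_gap`` samples are merged.  Returned ranges
    are 1-based inclusive window coordinates.
    """
    v = np.asarray(expert_window, dtype=float)
    u = np.asarray(learner_window, dtype=float)
    spread = float(max(v.max(), u.max()) - min(v.min(), u.min()))
    if spread == 0.0:
        return []
    costs = np.abs(u[path.j - 1] - v[path.i - 1])
    bad_i = np.unique(path.i[costs > band_fraction * spread])
    if bad_i.size == 0:
        return []
    segments: list[list[int]] = [[int(bad_i[0]), int(bad_i[0])]]
    for i in bad_i[1:]:
        if i - segments[-1][1] < merge_gap:
            segments[-1][1] = int(i)
        else:
            segments.append([int(i), int(i)])
    return [(s, e) for s, e in segments]


def _verdict(
    periods_ok: bool,
    r2: float | None,
    diff: float | None,
    thresholds: Thresholds,
) -> tuple[Literal["similar", "different"], list[str]]:
    reasons: list[str] = []
    if not periods_ok:
        reasons.append("periods differ")
    if r2 is not None and not r2 > thresholds.r2_min:
        reasons.append(f"R^2 {r2:.4f} not above {thresholds.r2_min}")
    if diff is not None and not diff < thresholds.diff_max:
        reasons.append(f"mean line difference {diff:.4f} not below {thresholds.diff_max}")
    return ("similar" if not reasons else "different"), reasons


def compare_series(
    expert: MagnitudeSeries,
    learner: MagnitudeSeries,
    seed: int | None = None,
    *,
    window_k: int | None = None,
    path_method: Literal["greedy", "dp"] = "greedy",
    thresholds: Thresholds = Thresholds(),
    peak_params: PeakParams = PeakParams(),
    filter_window: int = DEFAULT_FILTER_WINDOW,
    normalize_scale: float = DEFAULT_NORMALIZE_SCALE,
    band_fraction: float = 0.25,
) -> ComparisonReport:
    """Run the full comparison pipeline on two magnitude series.

    Stages: period gate -> phase sync -> start-at-maximum -> common
    truncation -> normalization -> smoothing -> random cycle window ->
    warping path -> line regression -> verdict.
    """
    validate_pair(expert, learner)

    pe = estimate_period(pearson_iterations(expert), peak_params)
    pl = estimate_period(pearson_iterations(learner), peak_params)
    period_ok = periods_equal(pe.period_samples, pl.period_samples)
    if not period_ok:
        verdict, reasons = _verdict(False, None, None, thresholds)
        return ComparisonReport(
            verdict=verdict,
            reasons=reasons,
            periods_equal=False,
            period_expert=pe.period_samples,
            period_learner=pl.period_samples,
            thresholds=thresholds,
            path_method=path_method,
        )
    period = pe.period_samples

    sync: SyncResult = synchronize(expert, learner, period)
    v = min_max_normalize(sync.expert_aligned, normalize_scale)
    u = min_max_normalize(sync.learner_aligned, normalize_scale)
    v = moving_average_filter(v, filter_window)
    u = moving_average_filter(u, filter_window)

    window = select_cycle_window(len(v), period, seed, k=window_k)
    wv, wu = window.slice(v), window.slice(u)

    cm = cost_matrix(wv, wu)
    path = greedy_path(cm) if path_method == "greedy" else dp_path(cm)
    fit = fit_path_line(path)
    r2 = r_squared(path, fit)
    diff = mean_line_difference(fit, path)
    segments = localize_discrepancy(wv, wu, path, band_fraction)

    verdict, reasons = _verdict(True, r2, diff, thresholds)
    return ComparisonReport(
        verdict=verdict,
        reasons=reasons,
        periods_equal=True,
        period_expert=pe.period_samples,
        period_learner=pl.period_samples,
        thresholds=thresholds,
        m=fit[0],
        b=fit[1],
        r_squared=r2,
        mean_line_diff=diff,
        window=window,
        shift_applied=sync.shift_applied,
        common_length=sync.common_length,
        sync_low_confidence=sync.low_confidence,
        discrepant_segments=segments,
        path_method=path_method,
    )
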