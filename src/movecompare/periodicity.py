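"""Period detection by circular autocorrelation ("Pearson iterations").

A periodic movement recorded at a fixed rate repeats every ``p`` samples.
Correlating the series with every circular rotation of itself produces a
profile with maxima at rotations that realign whole cycles; the spacing of
those maxima estimates the period.  Two recordings are only compared further
if their estimated periods agree exactly.

Two equivalent profile computations are provided: the direct per-shift
Pearson coefficient, and an FFT-based circular autocorrelation (the default;
the two agree to floating-point accuracy and are cross-checked in the test
suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io_signals import MagnitudeSeries


class DegenerateSeriesError(ValueError):
    """Raised when a constant (flat) series makes correlation undefined."""


class AperiodicSignalError(ValueError):
    """Raised when no repeating structure can be detected in a series."""


@dataclass(frozen=True)
class PeakParams:
    """Maxima-detection settings for the correlation profile.

    ``min_height`` rejects shifts whose correlation is too weak to mark a
    cycle boundary; ``min_separation`` (in shifts) suppresses jitter peaks.
    """

    min_height: float = 0.5
    min_separation: int = 3


@dataclass(frozen=True)
class PearsonProfile:
    """Circular autocorrelation profile of a series.

    ``p_values[k-1]`` is the Pearson correlation between the series and its
    rotation by ``k`` samples, for shifts ``k = 1..n``; the full rotation
    (shift ``n``) is the identity and correlates at exactly 1.
    """

    p_values: np.ndarray
    maxima_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return self.p_values.size

    def to_csv(self, path: str | Path) -> None:
        """Export as a single-column CSV, one correlation per shift."""
        pd.DataFrame({"p": self.p_values}).to_csv(
            path, index=False, header=False, float_format="%.17g"
        )


@dataclass(frozen=True)
class PeriodEstimate:
    """Period of a series, in samples.

    ``raw_spacing`` is the median number of shifts between consecutive
    profile maxima — the mathematically natural period of the circular
    profile.  ``period_samples`` is ``raw_spacing - 1``, the convention used
    throughout the comparison pipeline (a maxima spacing of 125 shifts is
    reported as a 124-sample period); both are surfaced so callers can use
    either.
    """

    period_samples: int
    raw_spacing: int
    maxima_positions: np.ndarray


def _values(v: MagnitudeSeries | Sequence[float] | np.ndarray) -> np.ndarray:
    if isinstance(v, MagnitudeSeries):
        return v.values
    return np.asarray(v, dtype=float)


def rotate(v: MagnitudeSeries, k: int) -> MagnitudeSeries:
    """Circular ("carousel") right-rotation by ``k`` samples.

    ``rotate(v, 1)`` moves the last sample to the front; ``rotate(v, n)``
    is the identity.
    """
    if k < 0:
        raise ValueError("rotation amount must be non-negative")
    return v.with_values(np.roll(v.values, k))


def pearson_correlation(
    a: MagnitudeSeries | np.ndarray, b: MagnitudeSeries | np.ndarray
) -> float:
    """Sample Pearson correlation coefficient of two equal-length series."""
    x, y = _values(a), _values(b)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("correlation needs at least two samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSeriesError("correlation undefined for a constant series")
    return float(np.corrcoef(x, y)[0, 1])


def pearson_iterations(
    v: MagnitudeSeries, method: Literal["fft", "direct"] = "fft"
) -> PearsonProfile:
    """Correlation of a series with all of its circular rotations.

    Returns the profile over shifts ``1..n``.  The FFT path evaluates the
    circular autocorrelation in O(n log n); the direct path computes one
    Pearson coefficient per shift and exists as a transparent cross-check.
    """
    x = v.values
    n = x.size
    if n < 2:
        raise ValueError("series too short for autocorrelation")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("autocorrelation undefined for a constant series")
    if method == "direct":
        p = np.empty(n)
        for k in range(1, n + 1):
            p[k - 1] = float(np.corrcoef(x, np.roll(x, k))[0, 1])
    elif method == "fft":
        # A rotation leaves mean and variance unchanged, so the Pearson
        # coefficient at shift k reduces to the normalized circular
        # autocorrelation of the centered series.
        xc = x - x.mean()
        s = np.fft.irfft(np.abs(np.fft.rfft(xc)) ** 2, n=n)
        p = np.roll(s, -1) / s[0]  # shifts 1..n; s[0] is shift 0 == shift n
        np.clip(p, -1.0, 1.0, out=p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PearsonProfile(p_values=p)


def detect_maxima(
    profile: PearsonProfile, peak_params: PeakParams = PeakParams()
) -> np.ndarray:
    """Local maxima of the profile, as 1-based shift positions."""
    idx, _ = find_peaks(
        profile.p_values,
        height=peak_params.min_height,
        distance=max(1, peak_params.min_separation),
    )
    return idx + 1


def estimate_period(
    profile: PearsonProfile, peak_params: PeakParams = PeakParams()
) -> PeriodEstimate:
    """Estimate the period from maxima spacing in the correlation profile.

    The median spacing between consecutive maxima resists a single spurious
    peak.  At least two maxima are required; otherwise the series carries no
    detectable repetition and an :class:`AperiodicSignalError` is raised.
    """
    maxima = (
        np.asarray(profile.maxima_positions)
        if len(profile.maxima_positions)
        else detect_maxima(profile, peak_params)
    )
    if maxima.size < 2:
        raise AperiodicSignalError(
            f"found {maxima.size} profile maxima; need at least 2 to measure a period"
        )
    spacing = int(round(float(np.median(np.diff(maxima)))))
    if spacing < 2:
        raise AperiodicSignalError(f"maxima spacing {spacing} too small to be a period")
    return PeriodEstimate(
        period_samples=spacing - 1, raw_spacing=spacing, maxima_positions=maxima
    )


def periods_equal(p1: int, p2: int) -> bool:
    """Strict integer equality of two estimated periods — the pipeline gate."""
    return int(p1) == int(p2)
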