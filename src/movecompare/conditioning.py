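"""Signal conditioning: moving-average smoothing and min-max rescaling.

The pipeline normalizes both aligned series to a common 0..10000 range
(removing the amplitude differences caused by different body masses and
forces) and then smooths them with a 5-point moving average to suppress
sensor noise.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io_signals import MagnitudeSeries

DEFAULT_FILTER_WINDOW = 5
DEFAULT_NORMALIZE_SCALE = 10000.0


class ZeroRangeError(ValueError):
    """Raised when a constant series cannot be min-max normalized."""


def moving_average_filter(
    v: MagnitudeSeries, window: int = DEFAULT_FILTER_WINDOW
) -> MagnitudeSeries:
    """Mean over a sliding window of ``window`` consecutive samples.

    The output has ``n - window + 1`` samples (four fewer at the default
    window of 5): only full windows are averaged, so the tail that cannot
    fill a window is dropped.
    """
    if window < 1:
        raise ValueError("window must be positive")
    if window != DEFAULT_FILTER_WINDOW and window % 2 == 0:
        warnings.warn(
            f"even filter window {window} does not preserve phase symmetry",
            stacklevel=2,
        )
    n = len(v)
    if n < window:
        raise ValueError(f"series of {n} samples is shorter than the window ({window})")
    kernel = np.full(window, 1.0 / window)
    return v.with_values(np.convolve(v.values, kernel, mode="valid"))


def min_max_normalize(
    v: MagnitudeSeries, scale: float = DEFAULT_NORMALIZE_SCALE
) -> MagnitudeSeries:
    """Affine rescale to the range ``[0, scale]``.

    The map is monotone, so the positions of all order statistics are
    preserved; a constant series has no range to rescale and is rejected.
    """
    x = v.values
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ZeroRangeError("cannot normalize a constant series (zero range)")
    return v.with_values(scale * (x - lo) / (hi - lo))
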