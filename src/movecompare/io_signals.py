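"""Reading accelerometer recordings and reducing them to magnitude series.

A wearable accelerometer yields tri-axial samples (x, y, z).  Because the
orientation of the device on the body is not controlled, the pipeline works
on the placement-invariant magnitude ``sqrt(x^2 + y^2 + z^2)`` — a univariate
series.  Recordings may also be supplied as precomputed magnitude columns.

Units are metadata that must agree between the two recordings entering a
comparison; conversion between g and m/s^2 is available but never applied
implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

#: Standard gravity, used for explicit g <-> m/s^2 conversion.
STANDARD_GRAVITY = 9.80665

Unit = Literal["g", "m/s^2", "m/s^2x100"]
_KNOWN_UNITS = ("g", "m/s^2", "m/s^2x100")

#: factor taking a value in ``unit`` to m/s^2
_TO_MS2 = {"g": STANDARD_GRAVITY, "m/s^2": 1.0, "m/s^2x100": 0.01}


class SignalIOError(ValueError):
    """Raised for unreadable, empty or non-numeric input files."""


class IncompatiblePairError(ValueError):
    """Raised when two series cannot be compared (unit or rate mismatch)."""


@dataclass(frozen=True)
class AccelRecording:
    """Tri-axial accelerometer recording in a declared unit."""

    samples: np.ndarray  # shape (n, 3)
    unit: str = "m/s^2"
    rate_hz: float | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if arr.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("recording contains non-finite samples")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class MagnitudeSeries:
    """Univariate acceleration-magnitude series with unit/rate metadata.

    ``values`` are non-negative when the series comes from
    :func:`compute_magnitude`; intermediate pipeline stages (normalization,
    filtering) reuse the container for general real-valued series.
    """

    values: np.ndarray
    unit: str = "m/s^2"
    rate_hz: float | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float).ravel()
        if arr.size < 1:
            raise ValueError("series must contain at least one value")
        if not np.all(np.isfinite(arr)):
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    def with_values(self, values: Sequence[float] | np.ndarray) -> "MagnitudeSeries":
        """New series with the same metadata and different values."""
        return replace(self, values=np.asarray(values, dtype=float))


def _read_numeric_csv(path: str | Path, n_cols_expected: int | None) -> pd.DataFrame:
    """Read a CSV of numbers; auto-detect one optional header row.

    The deposited files are plain comma-separated numbers with a decimal
    point; a first row that does not parse as numbers is treated as a header.
    """
    p = Path(path)
    if not p.exists():
        raise SignalIOError(f"input file not found: {p}")
    try:
        df = pd.read_csv(
            p, header=None, skip_blank_lines=True, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        raise SignalIOError(f"empty input file: {p}") from None
    # header auto-detection: non-numeric first row is a header
    first = df.iloc[0]
    if first.apply(lambda v: pd.to_numeric(v, errors="coerce")).isna().any():
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise SignalIOError(f"file contains a header but no data rows: {p}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad_row = int(numeric.isna().any(axis=1).idxmax())
        raise SignalIOError(f"non-numeric cell at data row {bad_row + 1} of {p}")
    if n_cols_expected is not None and numeric.shape[1] < n_cols_expected:
        raise SignalIOError(
            f"{p}: expected at least {n_cols_expected} columns, found {numeric.shape[1]}"
        )
    return numeric


def read_recording(
    path: str | Path,
    layout: Literal["triaxial", "magnitude"] = "magnitude",
    unit: str = "m/s^2",
    rate_hz: float | None = None,
) -> AccelRecording | MagnitudeSeries:
    """Read an accelerometer CSV in the declared layout.

    ``layout="triaxial"`` expects x, y, z in the first three columns and
    returns an :class:`AccelRecording`; ``layout="magnitude"`` expects a
    single numeric column and returns a :class:`MagnitudeSeries`.  Row order
    is preserved.
    """
    if unit not in _KNOWN_UNITS:
        raise ValueError(f"unknown unit {unit!r}; expected one of {_KNOWN_UNITS}")
    if layout == "triaxial":
        numeric = _read_numeric_csv(path, 3)
        return AccelRecording(
            samples=numeric.iloc[:, :3].to_numpy(dtype=float),
            unit=unit,
            rate_hz=rate_hz,
            source_path=str(path),
        )
    if layout == "magnitude":
        numeric = _read_numeric_csv(path, 1)
        return MagnitudeSeries(
            values=numeric.iloc[:, 0].to_numpy(dtype=float),
            unit=unit,
            rate_hz=rate_hz,
            source_path=str(path),
        )
    raise ValueError(f"unknown layout {layout!r}; expected 'triaxial' or 'magnitude'")


def write_magnitude(series: MagnitudeSeries, path: str | Path) -> None:
    """Write a magnitude series as a single-column CSV (no header)."""
    pd.DataFrame({"magnitude": series.values}).to_csv(
        path, index=False, header=False, float_format="%.17g"
    )


def compute_magnitude(rec: AccelRecording) -> MagnitudeSeries:
    """Reduce a tri-axial recording to its Euclidean magnitude per sample."""
    mags = np.linalg.norm(rec.samples, axis=1)
    return MagnitudeSeries(
        values=mags, unit=rec.unit, rate_hz=rec.rate_hz, source_path=rec.source_path
    )


def convert_unit(series: MagnitudeSeries, to_unit: str) -> MagnitudeSeries:
    """Explicitly convert between g, m/s^2 and m/s^2x100 (1 g = 9.80665 m/s^2)."""
    if series.unit not in _TO_MS2 or to_unit not in _TO_MS2:
        raise ValueError(f"unsupported unit conversion {series.unit!r} -> {to_unit!r}")
    factor = _TO_MS2[series.unit] / _TO_MS2[to_unit]
    return replace(series, values=series.values * factor, unit=to_unit)


def validate_pair(
    a: MagnitudeSeries, b: MagnitudeSeries
) -> tuple[MagnitudeSeries, MagnitudeSeries]:
    """Check that two series are comparable: same unit, same known rate.

    Sampling rate is metadata; it is compared only when declared on both
    sides, since the algorithm itself is index-based.
    """
    if a.unit != b.unit:
        raise IncompatiblePairError(f"unit mismatch: {a.unit!r} vs {b.unit!r}")
    if a.rate_hz is not None and b.rate_hz is not None and a.rate_hz != b.rate_hz:
        raise IncompatiblePairError(
            f"sampling-rate mismatch: {a.rate_hz} Hz vs {b.rate_hz} Hz"
        )
    return a, b
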