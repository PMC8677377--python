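"""Phase synchronization of a learner recording to an expert recording.

Both recordings are periodic with the same (already verified) period, but
start at arbitrary phases.  Synchronization compares the first cycle of each
recording under all cyclic displacements of the learner cycle, discards that
many leading learner samples, trims both recordings to start at the raw
maximum of their first cycle, and truncates them to a common length.

The displacement profile R is indexed by the number of leading samples
discarded: R[s] is the Pearson correlation between the expert's first cycle
and the learner's first cycle advanced by s samples, so the argmax of R is
directly the head-discard that best aligns the phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_signals import MagnitudeSeries
from .periodicity import DegenerateSeriesError, pearson_correlation

#: below this best-alignment correlation the sync is flagged, not rejected
LOW_CONFIDENCE_R = 0.2


@dataclass(frozen=True)
class SyncResult:
    """Outcome of the full alignment stage."""

    shift_applied: int
    common_length: int
    expert_aligned: MagnitudeSeries
    learner_aligned: MagnitudeSeries
    r_profile: np.ndarray
    best_r: float
    low_confidence: bool


def first_cycle(v: MagnitudeSeries, period: int) -> MagnitudeSeries:
    """The first ``period`` samples of a series."""
    if period < 1:
        raise ValueError("period must be positive")
    if len(v) < period:
        raise ValueError(f"series of {len(v)} samples is shorter than one period ({period})")
    return v.with_values(v.values[:period])


def sync_shift(v1: MagnitudeSeries, u1: MagnitudeSeries) -> tuple[int, np.ndarray]:
    """Best cyclic head-discard aligning learner cycle ``u1`` to expert ``v1``.

    Returns ``(shift, r_profile)`` where ``r_profile[s]`` is the correlation
    after cyclically discarding ``s`` leading learner samples, ``s = 0..p-1``,
    and ``shift`` is the argmax (ties broken toward the smallest shift).
    """
    x, y = v1.values, u1.values
    if x.size != y.size:
        raise ValueError(f"cycle length mismatch: {x.size} vs {y.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSeriesError("cannot synchronize a constant cycle")
    p = x.size
    r = np.array([pearson_correlation(x, np.roll(y, -s)) for s in range(p)])
    shift = int(np.argmax(r))  # argmax returns the first (smallest) maximizer
    return shift, r


def apply_shift(u: MagnitudeSeries, shift: int) -> MagnitudeSeries:
    """Discard the first ``shift`` samples (head-discard, not rotation)."""
    if shift < 0:
        raise ValueError("shift must be non-negative")
    if shift >= len(u):
        raise ValueError(f"shift {shift} >= series length {len(u)}")
    return u.with_values(u.values[shift:])


def start_at_first_maximum(v: MagnitudeSeries, period: int) -> MagnitudeSeries:
    """Drop samples preceding the raw maximum of the first cycle.

    Ties resolve to the earliest maximum, so a constant cycle leaves the
    series unchanged.
    """
    cyc = first_cycle(v, period)
    pos = int(np.argmax(cyc.values))
    return v.with_values(v.values[pos:])


def truncate_common(v: MagnitudeSeries, u: MagnitudeSeries) -> tuple[MagnitudeSeries, MagnitudeSeries, int]:
    """Cut both series to the shorter of the two lengths."""
    tam = min(len(v), len(u))
    return v.with_values(v.values[:tam]), u.with_values(u.values[:tam]), tam


def synchronize(v: MagnitudeSeries, u: MagnitudeSeries, period: int) -> SyncResult:
    """Full alignment: phase-sync the learner, start both at a cycle maximum,
    truncate to a common length.

    The expert series ``v`` is never phase-shifted; only the learner ``u``
    loses leading samples for synchronization.
    """
    shift, r_profile = sync_shift(first_cycle(v, period), first_cycle(u, period))
    u_adj = apply_shift(u, shift) if shift else u
    v_adj = start_at_first_maximum(v, period)
    u_adj = start_at_first_maximum(u_adj, min(period, len(u_adj)))
    v_fin, u_fin, tam = truncate_common(v_adj, u_adj)
    best_r = float(r_profile[shift])
    return SyncResult(
        shift_applied=shift,
        common_length=tam,
        expert_aligned=v_fin,
        learner_aligned=u_fin,
        r_profile=r_profile,
        best_r=best_r,
        low_confidence=best_r < LOW_CONFIDENCE_R,
    )
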