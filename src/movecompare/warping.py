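"""Cost matrix and warping-path extraction.

Two conditioned windows are compared through the matrix of pairwise absolute
differences.  A warping path traverses the matrix from (1, 1) to (n, n) in
unit steps — right, up, or diagonal — tracing the correspondence between
expert and learner samples.  Two walkers are provided:

* ``greedy_path`` — at each cell step to whichever of the three forward
  neighbors has the smallest local cost.  This is the pipeline default.
* ``dp_path`` — classical dynamic-programming time warping, globally
  minimizing the accumulated cost over the same step set.  It serves as an
  optimality oracle for the greedy walker (its cost is a lower bound) and as
  a robust alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .io_signals import MagnitudeSeries


@dataclass(frozen=True)
class CostMatrix:
    """Pairwise distances: ``entries[j, i] = |u[j] - v[i]|`` (0-based)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("cost matrix must be square")
        if e.size and e.min() < 0:
            raise ValueError("cost matrix entries must be non-negative")
        object.__setattr__(self, "entries", e)

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class WarpPath:
    """Ordered 1-based index pairs (i into expert, j into learner)."""

    points: np.ndarray  # shape (k, 2), 1-based
    method: Literal["greedy", "dp"]
    total_cost: float

    @property
    def i(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def j(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["i", "j"]).to_csv(path, index=False)


def cost_matrix(v: MagnitudeSeries | np.ndarray, u: MagnitudeSeries | np.ndarray) -> CostMatrix:
    """Absolute-difference distance matrix between two equal-length windows."""
    x = v.values if isinstance(v, MagnitudeSeries) else np.asarray(v, dtype=float)
    y = u.values if isinstance(u, MagnitudeSeries) else np.asarray(u, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return CostMatrix(entries=np.abs(y[:, None] - x[None, :]))


# forward steps as (di, dj); listed in tie-preference order:
# diagonal first (toward the ideal line), then right, then up.
_STEPS = ((1, 1), (1, 0), (0, 1))


def greedy_path(cm: CostMatrix) -> WarpPath:
    """Locally minimal walk from (1, 1) to (n, n).

    At each cell the walker inspects the feasible forward neighbors (the
    candidate set shrinks at the matrix border) and moves to the one with the
    smallest entry; ties prefer diagonal, then right, then up.  The total
    cost sums every visited entry, including the start cell.
    """
    e = cm.entries
    n = cm.n
    i = j = 0  # 0-based (expert, learner)
    pts = [(1, 1)]
    total = e[0, 0]
    while i < n - 1 or j < n - 1:
        best = None
        for di, dj in _STEPS:
            ni, nj = i + di, j + dj
            if ni < n and nj < n:
                c = e[nj, ni]
                if best is None or c < best[0]:
                    best = (c, ni, nj)
        c, i, j = best
        total += c
        pts.append((i + 1, j + 1))
    return WarpPath(points=np.array(pts, dtype=int), method="greedy", total_cost=float(total))


def dp_path(cm: CostMatrix) -> WarpPath:
    """Globally minimal accumulated-cost path (classical DTW recurrence).

    Backtracking ties prefer the diagonal predecessor.
    """
    e = cm.entries  # e[j, i]
    n = cm.n
    acc = np.full((n, n), np.inf)
    acc[0, 0] = e[0, 0]
    for j in range(n):
        for i in range(n):
            if i == 0 and j == 0:
                continue
            prev = np.inf
            if i > 0 and j > 0:
                prev = acc[j - 1, i - 1]
            if i > 0:
                prev = min(prev, acc[j, i - 1])
            if j > 0:
                prev = min(prev, acc[j - 1, i])
            acc[j, i] = e[j, i] + prev
    # backtrack from (n-1, n-1); prefer diagonal on ties
    i = j = n - 1
    rev = [(n, n)]
    while i > 0 or j > 0:
        cands = []
        if i > 0 and j > 0:
            cands.append((acc[j - 1, i - 1], 0, i - 1, j - 1))
        if i > 0:
            cands.append((acc[j, i - 1], 1, i - 1, j))
        if j > 0:
            cands.append((acc[j - 1, i], 2, i, j - 1))
        _, _, i, j = min(cands)
        rev.append((i + 1, j + 1))
    rev.reverse()
    return WarpPath(
        points=np.array(rev, dtype=int),
        method="dp",
        total_cost=float(acc[n - 1, n - 1]),
    )


def warp(
    v: MagnitudeSeries | np.ndarray,
    u: MagnitudeSeries | np.ndarray,
    method: Literal["greedy", "dp"] = "greedy",
) -> WarpPath:
    """Cost matrix + path extraction in one call."""
    cm = cost_matrix(v, u)
    return greedy_path(cm) if method == "greedy" else dp_path(cm)
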