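"""Synthetic accelerometer-like periodic signals with labeled perturbations.

Real recordings of periodic movements (dance steps, gait) carried ~124–125
samples per cycle and ~3000 samples per recording.  The generator emulates
that regime: a periodic waveform (sine, sum of harmonics, or an asymmetric
gait-like template), an amplitude and baseline, additive Gaussian noise, an
integer phase offset, and a tempo factor that stretches or compresses the
cycle length.

``generate_pair`` produces expert/learner pairs with a controlled
perturbation and a ground-truth label: perturbations the comparison pipeline
is designed to tolerate (phase offset, amplitude scaling, mild noise) are
labeled ``similar``; a tempo change (which alters the period) and a large
mid-cycle shape distortion are labeled ``different``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, get_args

import numpy as np

from .io_signals import MagnitudeSeries

Waveform = Literal["sine", "harmonics", "gait"]
Perturbation = Literal["none", "phase", "amplitude-scale", "tempo", "shape-distortion"]

#: gait template: one sharp impact peak plus one broad swing hump per cycle,
#: as Gaussian bumps at fixed cycle phases (center, width, relative height)
_GAIT_BUMPS = ((0.15, 0.03, 1.0), (0.55, 0.15, 0.5))

#: cycle-phase span replaced by its scaled time-reverse under shape distortion
_DISTORT_SPAN = (0.25, 0.75)


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of one synthetic recording."""

    period_samples: int = 124
    n_cycles: int = 24
    waveform: Waveform = "gait"
    amplitude: float = 1.0
    baseline: float = 2.0
    noise_sd: float = 0.0
    phase_shift_samples: int = 0
    tempo_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_samples < 4:
            raise ValueError("period_samples must be >= 4")
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tempo_factor <= 0:
            raise ValueError("tempo_factor must be positive")
        if self.waveform not in get_args(Waveform):
            raise ValueError(f"unknown waveform {self.waveform!r}")


def _waveform_at(phase: np.ndarray, waveform: Waveform) -> np.ndarray:
    """Unit-amplitude periodic template evaluated at cycle phase in [0, 1)."""
    phase = np.mod(phase, 1.0)
    if waveform == "sine":
        return np.sin(2 * np.pi * phase)
    if waveform == "harmonics":
        return (
            np.sin(2 * np.pi * phase)
            + 0.5 * np.sin(4 * np.pi * phase)
            + 0.25 * np.cos(6 * np.pi * phase)
        )
    # gait: wrapped Gaussian bumps
    out = np.zeros_like(phase)
    for center, width, height in _GAIT_BUMPS:
        d = np.abs(phase - center)
        d = np.minimum(d, 1.0 - d)  # wrap around the cycle
        out += height * np.exp(-0.5 * (d / width) ** 2)
    return out


def _distort_phase_segment(
    clean: np.ndarray, phase: np.ndarray, magnitude: float
) -> np.ndarray:
    """Replace a mid-cycle phase span with its time-reverse, scaled.

    ``magnitude`` in [0, 1] blends between the original segment (0) and the
    fully reversed, amplitude-scaled segment (1), producing the mid-cycle
    divergence seen when a learner distorts the middle of a movement but
    starts and ends it correctly.
    """
    lo, hi = _DISTORT_SPAN
    frac = np.mod(phase, 1.0)
    out = clean.copy()
    mask = (frac >= lo) & (frac < hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    # process each contiguous run (one per cycle) independently
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, breaks + 1):
        seg = clean[run]
        reversed_scaled = seg[::-1] * (1.0 + 0.5 * magnitude)
        out[run] = (1.0 - magnitude) * seg + magnitude * reversed_scaled
    return out


def generate_signal(spec: SignalSpec) -> MagnitudeSeries:
    """Deterministic synthetic magnitude series for the given spec.

    Length is ``period_samples * n_cycles``; the tempo factor rescales the
    effective cycle length within that span, and noiseless signals with
    ``tempo_factor == 1`` are exactly periodic.
    """
    n = spec.period_samples * spec.n_cycles
    t = np.arange(n, dtype=float)
    phase = (t + spec.phase_shift_samples) / (spec.period_samples * spec.tempo_factor)
    clean = spec.baseline + spec.amplitude * _waveform_at(phase, spec.waveform)
    if spec.noise_sd > 0:
        clean = clean + np.random.default_rng(spec.seed).normal(0.0, spec.noise_sd, n)
    return MagnitudeSeries(values=clean, source_path=f"synthetic(seed={spec.seed})")


def generate_pair(
    expert_spec: SignalSpec,
    perturbation: Perturbation = "none",
    magnitude: float = 0.0,
    seed: int | None = None,
) -> tuple[MagnitudeSeries, MagnitudeSeries, Literal["similar", "different"]]:
    """Expert/learner pair with a controlled perturbation and truth label.

    ``magnitude`` means: samples of phase offset (``phase``), amplitude
    multiplier (``amplitude-scale``), tempo factor (``tempo``), or blend
    strength in [0, 1] (``shape-distortion``).  The learner draws independent
    noise (seeded by ``seed``); with ``perturbation="none"`` and no noise the
    pair is identical.
    """
    expert = generate_signal(expert_spec)
    learner_seed = expert_spec.seed if seed is None else seed
    learner_spec = replace(expert_spec, seed=learner_seed)

    if perturbation == "none":
        learner = generate_signal(learner_spec)
        return expert, learner, "similar"
    if perturbation == "phase":
        learner_spec = replace(learner_spec, phase_shift_samples=expert_spec.phase_shift_samples + int(magnitude))
        return expert, generate_signal(learner_spec), "similar"
    if perturbation == "amplitude-scale":
        learner_spec = replace(learner_spec, amplitude=expert_spec.amplitude * magnitude)
        return expert, generate_signal(learner_spec), "similar"
    if perturbation == "tempo":
        learner_spec = replace(learner_spec, tempo_factor=expert_spec.tempo_factor * magnitude)
        return expert, generate_signal(learner_spec), "different"
    if perturbation == "shape-distortion":
        if not 0.0 <= magnitude <= 1.0:
            raise ValueError("shape-distortion magnitude must be in [0, 1]")
        spec = learner_spec
        n = spec.period_samples * spec.n_cycles
        t = np.arange(n, dtype=float)
        phase = (t + spec.phase_shift_samples) / (spec.period_samples * spec.tempo_factor)
        clean = spec.baseline + spec.amplitude * _waveform_at(phase, spec.waveform)
        distorted = _distort_phase_segment(clean, phase, magnitude)
        if spec.noise_sd > 0:
            distorted = distorted + np.random.default_rng(spec.seed).normal(0.0, spec.noise_sd, n)
        learner = MagnitudeSeries(values=distorted, source_path=f"synthetic(seed={spec.seed})")
        # mild distortion is within tolerance; a strong one changes the movement
        label: Literal["similar", "different"] = "different" if magnitude >= 0.5 else "similar"
        return expert, learner, label
    raise ValueError(f"unknown perturbation {perturbation!r}")


def benchmark_pairs(
    n_pairs: int = 200, seed: int = 0, spec: SignalSpec | None = None
) -> list[tuple[MagnitudeSeries, MagnitudeSeries, str]]:
    """Seeded benchmark: half similar-class pairs, half different-class.

    Similar class: identical, phase offsets, amplitude scaling, mild noise.
    Different class: tempo changes (period gate) and strong mid-cycle shape
    distortion.  Used as the package's no-download end-to-end check.
    """
    base = spec or SignalSpec()
    rng = np.random.default_rng(seed)
    pairs = []
    half = n_pairs // 2
    similar_kinds = ["none", "phase", "amplitude-scale"]
    for i in range(half):
        kind = similar_kinds[i % len(similar_kinds)]
        mag = {"none": 0.0, "phase": float(rng.integers(1, base.period_samples)),
               "amplitude-scale": float(rng.uniform(0.5, 1.8))}[kind]
        s = replace(base, noise_sd=0.03 * base.amplitude, seed=int(rng.integers(2**31)))
        pairs.append(generate_pair(s, kind, mag, seed=int(rng.integers(2**31))))
    for i in range(n_pairs - half):
        s = replace(base, noise_sd=0.03 * base.amplitude, seed=int(rng.integers(2**31)))
        if i % 2 == 0:
            factor = float(rng.choice([0.5, 0.75, 1.5, 2.0]))
            pairs.append(generate_pair(s, "tempo", factor, seed=int(rng.integers(2**31))))
        else:
            mag = float(rng.uniform(0.7, 1.0))
            pairs.append(generate_pair(s, "shape-distortion", mag, seed=int(rng.integers(2**31))))
    return pairs
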