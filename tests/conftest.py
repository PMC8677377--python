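import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from movecompare.io_signals import MagnitudeSeries
from movecompare.synthetic import SignalSpec, generate_signal


@pytest.fixture
def sine_series() -> MagnitudeSeries:
    """Noiseless sine, period 50, 10 cycles."""
    t = np.arange(500)
    return MagnitudeSeries(values=2.0 + np.sin(2 * np.pi * t / 50))


@pytest.fixture
def gait_series() -> MagnitudeSeries:
    """Noiseless asymmetric gait-like signal, period 124, 24 cycles."""
    return generate_signal(SignalSpec(waveform="gait", noise_sd=0.0, seed=1))


@pytest.fixture
def magnitude_csv(tmp_path):
    """Write values to a single-column CSV and return the path."""

    def _write(values, name="series.csv", header=None):
        p = tmp_path / name
        lines = ([header] if header else []) + [f"{v!r}" for v in values]
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write
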