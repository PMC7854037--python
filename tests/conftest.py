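import numpy as np
import pytest

from exemg import Burst, BurstProfile, EmgStream, MuscleId, SensorSpec, generate_stream


@pytest.fixture
def spec():
    return SensorSpec()


@pytest.fixture
def make_rect_stream():
    """Stream with rectangular pulses on a flat floor (no jitter)."""

    def _make(pulses, floor=0.0, duration_s=None, spec=None,
              muscle=MuscleId.BICEP):
        # pulses: list of (onset_s, duration_s, amplitude_mv)
        bursts = tuple(Burst(o, d, a) for o, d, a in pulses)
        prof = BurstProfile(bursts, noise_floor_mv=floor, noise_jitter=0.0)
        return generate_stream(prof, muscle, spec or SensorSpec(),
                               total_duration_s=duration_s)

    return _make


@pytest.fixture
def constant_stream():
    def _make(value_mv, duration_s, spec=None, muscle=MuscleId.BICEP):
        spec = spec or SensorSpec()
        n = int(duration_s * spec.sampling_rate_hz)
        return EmgStream(muscle, spec, 0.0, np.full(n, float(value_mv)))

    return _make


def random_burst_profile(rng, max_bursts=6, jitter=0.0):
    """Random non-overlapping trapezoidal bursts for property tests."""
    n_bursts = int(rng.integers(0, max_bursts + 1))
    t = float(rng.uniform(0.3, 1.0))
    bursts = []
    for _ in range(n_bursts):
        rise = float(rng.uniform(0.0, 0.15))
        fall = float(rng.uniform(0.0, 0.15))
        dur = rise + fall + float(rng.uniform(0.2, 1.2))
        amp = float(rng.uniform(0.2, 1.2))
        bursts.append(Burst(t, dur, amp, rise, fall))
        t += dur + float(rng.uniform(0.05, 1.0))
    return BurstProfile(tuple(bursts), noise_floor_mv=0.02,
                        noise_jitter=jitter, seed=int(rng.integers(2**31)))
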