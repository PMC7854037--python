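"""Synthetic envelope generator emulating the wireless EMG sensor.

The pilot study's cloud recordings were never deposited, so reproducible
work needs a stand-in.  Streams are built from a *burst model*: a resting
noise floor with trapezoidal contraction bursts (linear rise, plateau,
linear fall) and multiplicative Gaussian jitter, sampled at the sensor
rate.  Trapezoids are the simplest shape that yields MVC-like plateaus,
ramped onsets for the hysteresis detector to cross, and a measurable
noise floor between contractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import EmgStream, MuscleId, SensorSpec

__all__ = ["Burst", "BurstProfile", "generate_stream", "pulse_train_profile"]


@dataclass(frozen=True)
class Burst:
    """One contraction: trapezoid from the noise floor up to a plateau.

    ``duration_s`` covers the whole burst including the rise and fall
    ramps, so the plateau occupies ``[onset + rise, onset + duration -
    fall)``.
    """

    onset_s: float
    duration_s: float
    plateau_mv: float
    rise_s: float = 0.0
    fall_s: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("burst duration must be positive")
        if self.onset_s < 0:
            raise ValueError("burst onset must be non-negative")
        if self.rise_s < 0 or self.fall_s < 0:
            raise ValueError("rise/fall times must be non-negative")
        if self.rise_s + self.fall_s > self.duration_s:
            raise ValueError("rise + fall cannot exceed burst duration")
        if self.plateau_mv < 0:
            raise ValueError("plateau amplitude must be non-negative")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class BurstProfile:
    """Recipe for one synthetic stream.

    Parameters
    ----------
    bursts
        Contractions; must not overlap once sorted by onset.
    noise_floor_mv
        Expected resting amplitude between bursts.
    noise_jitter
        Relative SD of multiplicative Gaussian noise applied to the whole
        trace (``x * (1 + jitter * N(0, 1))``, clipped at 0).
    seed
        RNG seed; equal seeds give bitwise-identical streams.
    """

    bursts: tuple[Burst, ...] = ()
    noise_floor_mv: float = 0.02
    noise_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bursts", tuple(self.bursts))
        if self.noise_floor_mv < 0:
            raise ValueError("noise floor must be non-negative")
        if self.noise_jitter < 0:
            raise ValueError("noise jitter must be non-negative")
        ordered = sorted(self.bursts, key=lambda b: b.onset_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError(
                    f"bursts overlap: one ends at {a.offset_s:g}s, "
                    f"next starts at {b.onset_s:g}s"
                )
        for b in ordered:
            if b.plateau_mv <= self.noise_floor_mv:
                raise ValueError("burst plateau must exceed the noise floor")

    @property
    def span_s(self) -> float:
        """Time by which the last burst has ended."""
        return max((b.offset_s for b in self.bursts), default=0.0)


def _trapezoid(t: np.ndarray, b: Burst, floor: float) -> np.ndarray:
    """Noise-free burst contribution above the floor at times ``t``."""
    y = np.zeros_like(t)
    height = b.plateau_mv - floor
    rise_end = b.onset_s + b.rise_s
    fall_start = b.offset_s - b.fall_s
    if b.rise_s > 0:
        m = (t >= b.onset_s) & (t < rise_end)
        y[m] = height * (t[m] - b.onset_s) / b.rise_s
    m = (t >= rise_end) & (t < fall_start)
    y[m] = height
    if b.fall_s > 0:
        m = (t >= fall_start) & (t < b.offset_s)
        y[m] = height * (b.offset_s - t[m]) / b.fall_s
    return y


def generate_stream(
    profile: BurstProfile,
    muscle: MuscleId = MuscleId.BICEP,
    spec: SensorSpec | None = None,
    total_duration_s: float | None = None,
) -> EmgStream:
    """Render a burst profile into an envelope stream.

    The stream has ``floor(total_duration_s * sampling_rate_hz)`` samples.
    Between bursts the expected amplitude is the noise floor; on a plateau
    it is the plateau amplitude.  When ``spec.quantize`` is set the samples
    are snapped to the ADC grid.

    ``total_duration_s`` defaults to the profile span plus one second of
    rest; it must cover every burst.
    """
    spec = spec or SensorSpec()
    if total_duration_s is None:
        total_duration_s = profile.span_s + 1.0
    if total_duration_s < profile.span_s:
        raise ValueError("total_duration_s does not cover all bursts")
    n = int(np.floor(total_duration_s * spec.sampling_rate_hz))
    t = np.arange(n) * spec.dt
    clean = np.full(n, float(profile.noise_floor_mv))
    for b in profile.bursts:
        clean += _trapezoid(t, b, profile.noise_floor_mv)
    if profile.noise_jitter > 0:
        rng = np.random.default_rng(profile.seed)
        clean = clean * (1.0 + profile.noise_jitter * rng.standard_normal(n))
    x = np.maximum(clean, 0.0)
    if spec.quantize:
        x = spec.quantize_values(x)
    return EmgStream(muscle, spec, 0.0, x)


def pulse_train_profile(
    n_pulses: int,
    amplitude_mv: float,
    pulse_s: float = 0.8,
    gap_s: float = 0.7,
    start_s: float = 1.0,
    rise_s: float = 0.1,
    fall_s: float = 0.1,
    noise_floor_mv: float = 0.02,
    noise_jitter: float = 0.0,
    seed: int = 0,
) -> BurstProfile:
    """Evenly spaced identical contractions — the workhorse test pattern.

    Emulates a repetition set (arm curls, punches): ``n_pulses`` bursts of
    ``pulse_s`` seconds separated by ``gap_s`` of rest.
    """
    if n_pulses < 0:
        raise ValueError("n_pulses must be non-negative")
    bursts = tuple(
        Burst(start_s + i * (pulse_s + gap_s), pulse_s, amplitude_mv,
              rise_s, fall_s)
        for i in range(n_pulses)
    )
    return BurstProfile(bursts, noise_floor_mv, noise_jitter, seed)
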