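"""EMG stream data model and envelope extraction.

The wearable sensor this package emulates transmits a *linear envelope* —
full-wave rectified surface EMG passed through a 2-pole low-pass filter —
rather than the raw interference signal.  Every downstream component
(calibration, contraction detection, the game engines) therefore consumes
non-negative envelope amplitudes sampled at a fixed rate (64 Hz by
default), and :class:`EmgStream` is the universal container for them.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sps

__all__ = [
    "MuscleId",
    "SensorSpec",
    "EmgStream",
    "extract_envelope",
    "stream_to_csv",
    "stream_from_csv",
    "stream_to_json",
    "stream_from_json",
]

#: float format that round-trips IEEE-754 doubles exactly through text
_FLOAT_FMT = "%.17g"


class MuscleId(str, Enum):
    """Upper-limb muscles monitored during the wheelchair workout."""

    BICEP = "bicep"
    TRICEP = "tricep"
    ANTERIOR_DELTOID = "anterior_deltoid"
    POSTERIOR_DELTOID = "posterior_deltoid"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SensorSpec:
    """Acquisition characteristics of the wireless envelope sensor.

    Parameters
    ----------
    sampling_rate_hz
        Envelope sample rate. The emulated sensor streams at 64 Hz.
    adc_bits
        ADC word length (15 bits for the emulated hardware).
    dynamic_range_mv
        ``(lo, hi)`` amplitude bounds of the ADC in mV.  Amplitudes are
        treated as mV throughout without asserting hardware fidelity; the
        vendor datasheet's printed range is ambiguous about units.
    quantize
        When True, generated samples are snapped to the ADC grid implied
        by ``adc_bits`` over ``dynamic_range_mv``.
    """

    sampling_rate_hz: float = 64.0
    adc_bits: int = 15
    dynamic_range_mv: tuple[float, float] = (0.0, 60.0)
    quantize: bool = False

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if int(self.adc_bits) != self.adc_bits or self.adc_bits <= 0:
            raise ValueError("adc_bits must be a positive integer")
        lo, hi = self.dynamic_range_mv
        if not hi > lo:
            raise ValueError("dynamic_range_mv must satisfy lo < hi")

    @property
    def dt(self) -> float:
        """Sample period in seconds."""
        return 1.0 / self.sampling_rate_hz

    @property
    def quantization_step_mv(self) -> float:
        """ADC grid spacing: full range over ``2**adc_bits - 1`` levels."""
        lo, hi = self.dynamic_range_mv
        return (hi - lo) / (2 ** self.adc_bits - 1)

    def quantize_values(self, x: np.ndarray) -> np.ndarray:
        """Snap amplitudes onto the ADC grid (and clip to the range)."""
        lo, hi = self.dynamic_range_mv
        q = self.quantization_step_mv
        codes = np.rint((np.clip(x, lo, hi) - lo) / q)
        return lo + codes * q


@dataclass
class EmgStream:
    """Uniformly sampled, non-negative envelope amplitudes for one muscle.

    Time is measured in seconds from the start of the stream; sample ``i``
    occurs at ``i / sampling_rate_hz``.  ``t0`` stores the absolute start
    (an epoch offset in seconds) separately and plays no role in any
    computation.
    """

    muscle: MuscleId
    spec: SensorSpec = field(default_factory=SensorSpec)
    t0: float = 0.0
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.muscle = MuscleId(self.muscle)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size and np.min(self.samples) < 0:
            raise ValueError("envelope samples must be non-negative")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def sampling_rate_hz(self) -> float:
        return self.spec.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        """Span covered by the samples, each holding one sample period."""
        return len(self) * self.spec.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from stream start (0-based index / rate)."""
        return np.arange(len(self)) * self.spec.dt

    def slice_seconds(self, start_s: float, stop_s: float) -> "EmgStream":
        """Sub-stream covering ``[start_s, stop_s)`` (sample-aligned)."""
        i0 = int(round(start_s * self.sampling_rate_hz))
        i1 = int(round(stop_s * self.sampling_rate_hz))
        if not 0 <= i0 <= i1 <= len(self):
            raise ValueError("slice outside stream span")
        return EmgStream(self.muscle, self.spec, self.t0 + start_s,
                         self.samples[i0:i1].copy())


def extract_envelope(
    raw: Sequence[float] | np.ndarray,
    spec: SensorSpec | None = None,
    cutoff_hz: float = 3.0,
    muscle: MuscleId = MuscleId.BICEP,
) -> EmgStream:
    """Linear-envelope extraction: rectify then 2-pole low-pass.

    Mirrors the on-board processing of the emulated sensor: the signed raw
    EMG is full-wave rectified and smoothed with a causal 2nd-order
    Butterworth low-pass of unit DC gain (3 Hz default cutoff, the usual
    choice for EMG linear envelopes).  The output is clamped at zero, since
    a physical envelope is non-negative even though the IIR filter can
    undershoot transients.

    Raises
    ------
    ValueError
        If ``cutoff_hz`` is not strictly below the Nyquist frequency.
    """
    spec = spec or SensorSpec()
    nyquist = spec.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff_hz must lie in (0, {nyquist}) for fs={spec.sampling_rate_hz}"
        )
    x = np.abs(np.asarray(raw, dtype=float))
    b, a = _sps.butter(2, cutoff_hz / nyquist)
    env = _sps.lfilter(b, a, x)
    return EmgStream(muscle, spec, 0.0, np.maximum(env, 0.0))


# ---------------------------------------------------------------------------
# Serialization.  CSV columns: time_s, muscle, envelope_mv.  JSON carries the
# sensor spec as well; both round-trip float64 exactly (17 significant
# digits).
# ---------------------------------------------------------------------------

def stream_to_csv(stream: EmgStream, path_or_buf) -> None:
    """Write a stream as CSV with columns ``time_s, muscle, envelope_mv``."""
    df = pd.DataFrame(
        {
            "time_s": stream.times,
            "muscle": stream.muscle.value,
            "envelope_mv": stream.samples,
        }
    )
    df.to_csv(path_or_buf, index=False, float_format=_FLOAT_FMT)


def stream_from_csv(path_or_buf, spec: SensorSpec | None = None) -> EmgStream:
    """Read a stream written by :func:`stream_to_csv`.

    The sampling rate is inferred from the time column when ``spec`` is not
    given (CSV does not carry the sensor spec; use JSON for that).
    """
    df = pd.read_csv(path_or_buf, float_precision="round_trip")
    required = {"time_s", "muscle", "envelope_mv"}
    if not required.issubset(df.columns):
        raise ValueError(f"stream CSV must have columns {sorted(required)}")
    muscles = df["muscle"].unique()
    if len(muscles) != 1:
        raise ValueError("stream CSV must contain exactly one muscle")
    if spec is None:
        t = df["time_s"].to_numpy()
        if len(t) >= 2:
            fs = 1.0 / np.median(np.diff(t))
        else:
            fs = SensorSpec().sampling_rate_hz
        spec = SensorSpec(sampling_rate_hz=float(round(fs, 6)))
    return EmgStream(MuscleId(muscles[0]), spec, 0.0,
                     df["envelope_mv"].to_numpy(dtype=float))


def stream_to_json(stream: EmgStream) -> str:
    """Lossless JSON form of a stream, including the sensor spec."""
    obj = {
        "muscle": stream.muscle.value,
        "t0": stream.t0,
        "spec": {
            "sampling_rate_hz": stream.spec.sampling_rate_hz,
            "adc_bits": stream.spec.adc_bits,
            "dynamic_range_mv": list(stream.spec.dynamic_range_mv),
            "quantize": stream.spec.quantize,
        },
        "samples_mv": [float(_FLOAT_FMT % v) for v in stream.samples],
    }
    buf = io.StringIO()
    json.dump(obj, buf)
    return buf.getvalue()


def stream_from_json(text: str) -> EmgStream:
    obj = json.loads(text)
    spec = SensorSpec(
        sampling_rate_hz=obj["spec"]["sampling_rate_hz"],
        adc_bits=obj["spec"]["adc_bits"],
        dynamic_range_mv=tuple(obj["spec"]["dynamic_range_mv"]),
        quantize=obj["spec"].get("quantize", False),
    )
    return EmgStream(MuscleId(obj["muscle"]), spec, obj.get("t0", 0.0),
                     np.asarray(obj["samples_mv"], dtype=float))
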