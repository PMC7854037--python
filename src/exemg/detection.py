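"""Dual-threshold contraction detection and iEMG quadrature.

A contraction ("hit"/"punch") opens when the envelope rises to the lower
threshold and closes when it falls back below it; the upper threshold
does not gate detection but classifies success (ringing the bell,
counting a valid punch).  This hysteresis split lets a repetition be
counted even when the target is missed, so flexions detected and
upper-target hits can be reported separately.

Comparison is closed (``>=``) at both thresholds.  Events whose gap to
the previous offset is shorter than a refractory interval are merged to
suppress chatter.  iEMG is the trapezoidal integral of the envelope
(exact for the piecewise-linear interpolant between samples, and
additive across sample-aligned intervals); the final sample of a stream
is held for one sample period so that a whole-stream integral covers the
full duration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .signal import EmgStream

__all__ = [
    "ContractionEvent",
    "ContractionDetector",
    "detect_contractions",
    "integrate_emg",
    "events_to_csv",
    "events_from_csv",
]

DEFAULT_REFRACTORY_S = 0.25

_IDLE, _OPEN, _PENDING = 0, 1, 2


@dataclass(frozen=True)
class ContractionEvent:
    """One detected contraction.

    ``[onset_s, offset_s)`` spans the samples at or above the lower
    threshold; ``iemg_mv_s`` integrates the envelope over that span
    (including the closing sub-threshold sample, so adjacent event and
    gap integrals tile the session).  ``reached_upper`` is True iff the
    peak reached the upper threshold.  ``truncated`` marks a contraction
    still open when the stream ended (closed at the stream end).
    """

    onset_s: float
    offset_s: float
    peak_mv: float
    iemg_mv_s: float
    reached_upper: bool
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError("event onset must precede offset")
        if self.iemg_mv_s < 0:
            raise ValueError("iEMG must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


class ContractionDetector:
    """Streaming hysteresis detector over envelope samples.

    Feed samples in chunks of any size; completed events come out in
    time order, and the chunking never changes the result.  An event is
    held back until the envelope has stayed below the lower threshold
    for the full refractory interval (a re-crossing within it merges
    into the same event), or until :meth:`finalize`.
    """

    def __init__(self, lower_mv: float, upper_mv: float,
                 sampling_rate_hz: float,
                 refractory_s: float = DEFAULT_REFRACTORY_S):
        if not 0 <= lower_mv < upper_mv:
            raise ValueError(
                f"thresholds must satisfy 0 <= lower < upper, got "
                f"({lower_mv}, {upper_mv})"
            )
        if refractory_s < 0:
            raise ValueError("refractory_s must be non-negative")
        self.lower = float(lower_mv)
        self.upper = float(upper_mv)
        self.fs = float(sampling_rate_hz)
        self.dt = 1.0 / self.fs
        # merge iff the gap, in samples, is shorter than this
        self._refractory_samples = refractory_s * self.fs
        self._state = _IDLE
        self._i = 0          # global index of the next sample
        self._prev = 0.0     # previous sample value
        self._onset = 0
        self._peak = 0.0
        self._iemg = 0.0
        self._pend: tuple[int, int, float, float] | None = None
        self._gap_iemg = 0.0

    def _emit(self, onset_i: int, offset_i: int, peak: float, iemg: float,
              truncated: bool) -> ContractionEvent:
        return ContractionEvent(
            onset_s=onset_i * self.dt,
            offset_s=offset_i * self.dt,
            peak_mv=float(peak),
            iemg_mv_s=float(iemg),
            reached_upper=bool(peak >= self.upper),
            truncated=truncated,
        )

    def _open(self, i: int, v: float) -> None:
        self._state = _OPEN
        self._onset = i
        self._peak = v
        self._iemg = 0.0

    def feed(self, samples: np.ndarray) -> list[ContractionEvent]:
        """Process a chunk; return the events completed within it."""
        out: list[ContractionEvent] = []
        lower, dt = self.lower, self.dt
        for v in np.asarray(samples, dtype=float):
            i = self._i
            if self._state == _OPEN:
                self._iemg += 0.5 * (self._prev + v) * dt
                if v >= lower:
                    if v > self._peak:
                        self._peak = v
                else:
                    self._pend = (self._onset, i, self._peak, self._iemg)
                    self._gap_iemg = 0.0
                    self._state = _PENDING
            elif self._state == _PENDING:
                self._gap_iemg += 0.5 * (self._prev + v) * dt
                onset0, offset0, peak0, iemg0 = self._pend  # type: ignore[misc]
                gap = i - offset0
                if v >= lower and gap < self._refractory_samples:
                    # re-crossing inside the refractory window: merge,
                    # bridging the below-threshold gap integral
                    self._state = _OPEN
                    self._onset = onset0
                    self._peak = max(peak0, v)
                    self._iemg = iemg0 + self._gap_iemg
                    self._pend = None
                elif gap >= self._refractory_samples:
                    out.append(self._emit(onset0, offset0, peak0, iemg0,
                                          truncated=False))
                    self._pend = None
                    if v >= lower:
                        self._open(i, v)
                    else:
                        self._state = _IDLE
            else:  # _IDLE
                if v >= lower:
                    self._open(i, v)
            self._prev = v
            self._i += 1
        return out

    def finalize(self) -> list[ContractionEvent]:
        """Flush: emit any pending event and close an open one."""
        out: list[ContractionEvent] = []
        if self._pend is not None:
            onset0, offset0, peak0, iemg0 = self._pend
            out.append(self._emit(onset0, offset0, peak0, iemg0,
                                  truncated=False))
            self._pend = None
        if self._state == _OPEN:
            # hold the last sample for its sample period, matching the
            # whole-stream convention of integrate_emg
            self._iemg += self._prev * self.dt
            out.append(self._emit(self._onset, self._i, self._peak,
                                  self._iemg, truncated=True))
        self._state = _IDLE
        return out


def detect_contractions(
    stream: EmgStream,
    lower_mv: float,
    upper_mv: float,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> list[ContractionEvent]:
    """Detect contractions in a whole stream (batch wrapper).

    Returns time-ordered, non-overlapping events; see the module
    docstring for the hysteresis and merge semantics.
    """
    det = ContractionDetector(lower_mv, upper_mv, stream.sampling_rate_hz,
                              refractory_s)
    events = det.feed(stream.samples)
    events.extend(det.finalize())
    return events


def integrate_emg(stream: EmgStream, t0_s: float, t1_s: float) -> float:
    """iEMG over ``[t0_s, t1_s]`` in mV·s.

    Trapezoidal integral of the envelope between sample-aligned bounds.
    ``t1_s`` may extend to the stream duration (one sample period past
    the last sample), in which case the last sample is held constant for
    its period.  Additive over adjacent intervals; non-negative.
    """
    if not t0_s < t1_s:
        raise ValueError("t0 must precede t1")
    n = len(stream)
    if n == 0:
        raise ValueError("stream is empty")
    fs = stream.sampling_rate_hz
    i0 = int(round(t0_s * fs))
    i1 = int(round(t1_s * fs))
    if abs(i0 - t0_s * fs) > 1e-6 or abs(i1 - t1_s * fs) > 1e-6:
        raise ValueError("integration bounds must be sample-aligned")
    if i0 < 0 or i1 > n:
        raise ValueError("interval outside stream span")
    dt = stream.spec.dt
    hi = min(i1, n - 1)
    total = float(np.trapezoid(stream.samples[i0:hi + 1], dx=dt))
    if i1 == n:
        total += float(stream.samples[-1]) * dt
    return total


def events_to_csv(events: list[ContractionEvent], path_or_buf) -> None:
    """Write events as CSV (onset_s, offset_s, peak_mv, iemg_mv_s, ...)."""
    close = isinstance(path_or_buf, (str, bytes))
    fh = open(path_or_buf, "w", newline="") if close else path_or_buf
    try:
        w = csv.writer(fh)
        w.writerow(["onset_s", "offset_s", "peak_mv", "iemg_mv_s",
                    "reached_upper", "truncated"])
        for e in events:
            w.writerow([repr(e.onset_s), repr(e.offset_s), repr(e.peak_mv),
                        repr(e.iemg_mv_s), int(e.reached_upper),
                        int(e.truncated)])
    finally:
        if close:
            fh.close()


def events_from_csv(path_or_buf) -> list[ContractionEvent]:
    close = isinstance(path_or_buf, (str, bytes))
    fh = open(path_or_buf, newline="") if close else path_or_buf
    try:
        rows = list(csv.DictReader(fh))
    finally:
        if close:
            fh.close()
    return [
        ContractionEvent(
            onset_s=float(r["onset_s"]),
            offset_s=float(r["offset_s"]),
            peak_mv=float(r["peak_mv"]),
            iemg_mv_s=float(r["iemg_mv_s"]),
            reached_upper=bool(int(r["reached_upper"])),
            truncated=bool(int(r.get("truncated", 0))),
        )
        for r in rows
    ]
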