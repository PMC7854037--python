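"""The three exergame engines: high striker, boxing, and car racing.

Each engine is a deterministic state machine driven purely by an
envelope stream, a threshold pair from the goal store, and the user's
MVC — no clocks, no randomness — so a session replays bit-identically.
Engines accept samples in chunks of any size (the chunking never
changes the outcome) and emit :class:`FeedbackEvent` records in place
of the app's audio-visual feedback, plus a :class:`GameSummary` at the
end.

* **High striker** (resistance-band sets): each detected contraction
  raises a bar whose height is the contraction's iEMG relative to a
  full-effort reference; reaching the upper amplitude target rings the
  bell.
* **Boxing** (high-cadence ball exchange): 30 valid punches advance the
  round, 3 rounds total, and the amplitude that counts as a punch
  escalates each round.
* **Racing** (spinning): the car's angular speed is proportional to the
  instantaneous effort, the envelope as a fraction of MVC; amplitudes
  below the resting noise floor do not move the car.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import GoalSet, Thresholds
from .detection import DEFAULT_REFRACTORY_S, ContractionDetector, ContractionEvent
from .signal import EmgStream, MuscleId

__all__ = [
    "FeedbackEvent",
    "GameConfig",
    "GameSummary",
    "HighStrikerEngine",
    "BoxingEngine",
    "RacingEngine",
    "RaceOutcome",
    "play_high_striker",
    "play_boxing",
    "play_racing",
    "replay_ghost",
]

EVENT_KINDS = frozenset({
    "rep_detected", "bell_hit", "round_advanced", "punch_detected",
    "lap_completed", "final_lap_cue", "encouragement_text", "game_over",
})


@dataclass(frozen=True)
class FeedbackEvent:
    """One piece of in-game feedback (stands in for audio/visual cues)."""

    time_s: float
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown feedback kind {self.kind!r}")


@dataclass(frozen=True)
class GameConfig:
    """Parameters for one game session.

    ``thresholds`` is the (lower, upper) pair fetched from the goal
    store for this game and muscle.  Game-specific knobs:

    high_striker
        ``reference_duration_s`` — the sustained-MVC duration whose iEMG
        fills the bar (defaults to the 3 s calibration window);
        ``bell_rule`` — ``"peak"`` rings the bell when the contraction
        peak reaches the upper target (default), ``"bar"`` when the
        iEMG bar saturates.
    boxing
        ``punches_per_round`` (30), ``n_rounds`` (3) and an optional
        explicit ``round_thresholds_mv`` schedule; by default the punch
        threshold escalates linearly from the lower to the upper goal
        across rounds.
    racing
        ``n_laps`` to complete, optional ``target_time_s``, and
        ``reference_lap_s`` — the lap time at sustained 100% effort,
        which fixes the speed gain ``2*pi / reference_lap_s`` rad/s.
    """

    game: str
    muscle: MuscleId
    thresholds: Thresholds
    refractory_s: float = DEFAULT_REFRACTORY_S
    # high striker
    reference_duration_s: float = 3.0
    bell_rule: str = "peak"
    # boxing
    punches_per_round: int = 30
    n_rounds: int = 3
    round_thresholds_mv: tuple[float, ...] | None = None
    # racing
    n_laps: int = 3
    target_time_s: float | None = None
    reference_lap_s: float = 10.0

    def __post_init__(self) -> None:
        if self.game not in ("high_striker", "boxing", "racing"):
            raise ValueError(f"unknown game {self.game!r}")
        if self.punches_per_round <= 0 or self.n_rounds <= 0:
            raise ValueError("punches_per_round and n_rounds must be positive")
        if self.n_laps <= 0:
            raise ValueError("n_laps must be positive")
        if self.reference_lap_s <= 0 or self.reference_duration_s <= 0:
            raise ValueError("reference durations must be positive")
        if self.bell_rule not in ("peak", "bar"):
            raise ValueError("bell_rule must be 'peak' or 'bar'")
        if self.round_thresholds_mv is not None:
            sched = tuple(self.round_thresholds_mv)
            if len(sched) != self.n_rounds:
                raise ValueError("round schedule length must equal n_rounds")
            if any(b < a for a, b in zip(sched, sched[1:])):
                raise ValueError("round thresholds must be non-decreasing")
            object.__setattr__(self, "round_thresholds_mv", sched)

    @classmethod
    def from_goals(cls, game: str, muscle: MuscleId, goals: GoalSet,
                   **kwargs) -> "GameConfig":
        """Build a config by fetching this game's thresholds from the store."""
        return cls(game=game, muscle=MuscleId(muscle),
                   thresholds=goals.get(game, muscle), **kwargs)

    def round_schedule(self) -> tuple[float, ...]:
        """Punch thresholds per boxing round (mV), escalating."""
        if self.round_thresholds_mv is not None:
            return self.round_thresholds_mv
        lo, up = self.thresholds.lower_mv, self.thresholds.upper_mv
        if self.n_rounds == 1:
            return (up,)
        return tuple(np.linspace(lo, up, self.n_rounds))

    @property
    def racing_gain(self) -> float:
        """Angular speed at 100% effort, rad/s."""
        return 2.0 * math.pi / self.reference_lap_s


@dataclass(frozen=True)
class GameSummary:
    """Per-session outcome metrics (the end-of-game summary screen)."""

    game: str
    duration_s: float
    reps_detected: int = 0
    bells_hit: int = 0
    rounds_completed: int = 0
    punches_per_round_detected: tuple[int, ...] = ()
    laps_completed: int = 0
    time_to_complete_s: float | None = None
    iemg_mv_s: float = 0.0
    peak_emg_mv: float = 0.0
    peak_emg_pct_mvc: float = 0.0

    def __post_init__(self) -> None:
        if self.bells_hit > self.reps_detected:
            raise ValueError("bells_hit cannot exceed reps_detected")
        if self.duration_s < 0 or self.iemg_mv_s < 0:
            raise ValueError("duration and iEMG must be non-negative")


class _EngineBase:
    """Shared plumbing: sample bookkeeping and whole-session totals."""

    def __init__(self, cfg: GameConfig, mvc_mv: float,
                 sampling_rate_hz: float):
        if mvc_mv <= 0:
            raise ValueError("mvc_mv must be positive")
        self.cfg = cfg
        self.mvc = float(mvc_mv)
        self.fs = float(sampling_rate_hz)
        self.dt = 1.0 / self.fs
        self._n = 0
        self._prev = 0.0
        self._iemg_total = 0.0
        self._peak_env = 0.0
        self._events: list[FeedbackEvent] = []
        self._finalized = False

    def _accumulate(self, x: np.ndarray) -> None:
        if x.size == 0:
            return
        # sequential trapezoid so the total is independent of how the
        # stream was chunked (exact streaming/batch equivalence)
        prev, half_dt = self._prev, 0.5 * self.dt
        first = self._n == 0
        for v in x:
            if not first:
                self._iemg_total += (prev + v) * half_dt
            first = False
            prev = v
        self._peak_env = max(self._peak_env, float(np.max(x)))
        self._prev = float(x[-1])
        self._n += x.size

    def _close_totals(self) -> None:
        # hold the last sample for one period: total equals the
        # whole-stream integrate_emg
        if self._n:
            self._iemg_total += self._prev * self.dt

    @property
    def duration_s(self) -> float:
        return self._n * self.dt

    def _emit(self, time_s: float, kind: str, **payload) -> None:
        self._events.append(FeedbackEvent(time_s, kind, payload))

    # subclasses implement feed() and _summary()
    def finalize(self) -> tuple[list[FeedbackEvent], GameSummary]:
        if self._finalized:
            raise RuntimeError("engine already finalized")
        self._finalized = True
        self._flush()
        self._close_totals()
        return list(self._events), self._summary()

    def _flush(self) -> None:  # pragma: no cover - overridden
        pass

    def _summary(self) -> GameSummary:  # pragma: no cover - overridden
        raise NotImplementedError


class HighStrikerEngine(_EngineBase):
    """Carnival high-striker: contraction iEMG drives the bar height.

    The bar fraction for a contraction is ``min(1, iemg / (mvc *
    reference_duration_s))`` — a contraction worth ``reference_duration_s``
    seconds of sustained MVC fills the bar.  The bell rings per
    ``cfg.bell_rule``: on reaching the upper amplitude target (default)
    or on bar saturation.
    """

    def __init__(self, cfg: GameConfig, mvc_mv: float,
                 sampling_rate_hz: float):
        super().__init__(cfg, mvc_mv, sampling_rate_hz)
        th = cfg.thresholds
        self._det = ContractionDetector(th.lower_mv, th.upper_mv,
                                        sampling_rate_hz, cfg.refractory_s)
        self.reps = 0
        self.bells = 0

    def _bar_fraction(self, ev: ContractionEvent) -> float:
        return min(1.0, ev.iemg_mv_s / (self.mvc * self.cfg.reference_duration_s))

    def _handle(self, ev: ContractionEvent) -> None:
        bar = self._bar_fraction(ev)
        self.reps += 1
        self._emit(ev.onset_s, "rep_detected",
                   bar_height_fraction=bar, peak_mv=ev.peak_mv,
                   iemg_mv_s=ev.iemg_mv_s)
        bell = ev.reached_upper if self.cfg.bell_rule == "peak" else bar >= 1.0
        if bell:
            self.bells += 1
            self._emit(ev.offset_s, "bell_hit", peak_mv=ev.peak_mv)

    def feed(self, samples: np.ndarray) -> list[FeedbackEvent]:
        x = np.asarray(samples, dtype=float)
        start = len(self._events)
        for ev in self._det.feed(x):
            self._handle(ev)
        self._accumulate(x)
        return self._events[start:]

    def _flush(self) -> None:
        for ev in self._det.finalize():
            self._handle(ev)
        self._emit(self.duration_s, "game_over", reps=self.reps,
                   bells=self.bells)

    def _summary(self) -> GameSummary:
        return GameSummary(
            game="high_striker",
            duration_s=self.duration_s,
            reps_detected=self.reps,
            bells_hit=self.bells,
            iemg_mv_s=self._iemg_total,
            peak_emg_mv=self._peak_env,
            peak_emg_pct_mvc=self._peak_env / self.mvc,
        )


class BoxingEngine(_EngineBase):
    """Three rounds of punches with an escalating punch threshold.

    A contraction is a *valid punch* when its peak reaches the current
    round's threshold.  Completing ``punches_per_round`` valid punches
    advances the round; completing the final round ends the game.
    """

    def __init__(self, cfg: GameConfig, mvc_mv: float,
                 sampling_rate_hz: float):
        super().__init__(cfg, mvc_mv, sampling_rate_hz)
        th = cfg.thresholds
        self._det = ContractionDetector(th.lower_mv, th.upper_mv,
                                        sampling_rate_hz, cfg.refractory_s)
        self.schedule = cfg.round_schedule()
        self.reps = 0
        self.round_idx = 0          # 0-based current round
        self.rounds_completed = 0
        self.punch_counts = [0] * cfg.n_rounds
        self.game_done = False

    def _handle(self, ev: ContractionEvent) -> None:
        self.reps += 1
        if self.game_done:
            return
        if ev.peak_mv >= self.schedule[self.round_idx]:
            self.punch_counts[self.round_idx] += 1
            self._emit(ev.onset_s, "punch_detected",
                       round=self.round_idx + 1, peak_mv=ev.peak_mv,
                       count=self.punch_counts[self.round_idx])
            if self.punch_counts[self.round_idx] >= self.cfg.punches_per_round:
                self.rounds_completed += 1
                if self.round_idx + 1 < self.cfg.n_rounds:
                    self.round_idx += 1
                    self._emit(ev.offset_s, "round_advanced",
                               round=self.round_idx + 1,
                               threshold_mv=self.schedule[self.round_idx])
                else:
                    self.game_done = True
                    self._emit(ev.offset_s, "game_over",
                               rounds_completed=self.rounds_completed)

    def feed(self, samples: np.ndarray) -> list[FeedbackEvent]:
        x = np.asarray(samples, dtype=float)
        start = len(self._events)
        for ev in self._det.feed(x):
            self._handle(ev)
        self._accumulate(x)
        return self._events[start:]

    def _flush(self) -> None:
        for ev in self._det.finalize():
            self._handle(ev)
        if not self.game_done:
            self._emit(self.duration_s, "game_over",
                       rounds_completed=self.rounds_completed)

    def _summary(self) -> GameSummary:
        return GameSummary(
            game="boxing",
            duration_s=self.duration_s,
            reps_detected=self.reps,
            rounds_completed=self.rounds_completed,
            punches_per_round_detected=tuple(self.punch_counts),
            iemg_mv_s=self._iemg_total,
            peak_emg_mv=self._peak_env,
            peak_emg_pct_mvc=self._peak_env / self.mvc,
        )


class RacingEngine(_EngineBase):
    """Car racing: angular speed proportional to instantaneous effort.

    Per sample, ``effort = clamp(envelope / mvc, 0, upper / mvc)``,
    zeroed below the lower threshold (the resting noise floor so the car
    does not creep at rest).  The car advances ``gain * effort * dt``
    radians per sample and a lap completes every ``2*pi``.
    """

    def __init__(self, cfg: GameConfig, mvc_mv: float,
                 sampling_rate_hz: float):
        super().__init__(cfg, mvc_mv, sampling_rate_hz)
        self.gain = cfg.racing_gain
        self.angle = 0.0
        # samples consumed by the kinematics (== _n, tracked separately
        # because _accumulate runs after the per-sample loop)
        self._n_kinematic = 0
        self.laps = 0
        self.time_to_complete_s: float | None = None
        self.lap_times_s: list[float] = []
        self._cued_final = False
        self._cued_half = False
        self._check_cues(0.0)

    def _check_cues(self, now_s: float) -> None:
        remaining = self.cfg.n_laps - self.laps
        if remaining == 1 and not self._cued_final:
            self._cued_final = True
            self._emit(now_s, "final_lap_cue", text="One final lap!")
        half = self.cfg.n_laps // 2
        if (self.cfg.n_laps >= 2 and self.laps >= half and self.laps > 0
                and not self._cued_half and remaining > 1):
            self._cued_half = True
            self._emit(now_s, "encouragement_text", text="Halfway there!")

    def feed(self, samples: np.ndarray) -> list[FeedbackEvent]:
        x = np.asarray(samples, dtype=float)
        start = len(self._events)
        lo = self.cfg.thresholds.lower_mv
        up = self.cfg.thresholds.upper_mv
        for v in x:
            t_end = (self._n_kinematic + 1) * self.dt
            if self.time_to_complete_s is None:
                effort = 0.0 if v < lo else min(v, up) / self.mvc
                self.angle += self.gain * effort * self.dt
                while (self.angle >= 2.0 * math.pi * (self.laps + 1)
                       and self.laps < self.cfg.n_laps):
                    self.laps += 1
                    self.lap_times_s.append(t_end)
                    self._emit(t_end, "lap_completed", lap=self.laps)
                    if self.laps >= self.cfg.n_laps:
                        self.time_to_complete_s = t_end
                        self._emit(t_end, "game_over",
                                   laps=self.laps,
                                   time_to_complete_s=t_end)
                        break
                    self._check_cues(t_end)
            self._n_kinematic += 1
        self._accumulate(x)
        return self._events[start:]

    def _flush(self) -> None:
        if self.time_to_complete_s is None:
            self._emit(self.duration_s, "game_over", laps=self.laps,
                       time_to_complete_s=None)

    def _summary(self) -> GameSummary:
        return GameSummary(
            game="racing",
            duration_s=self.duration_s,
            laps_completed=self.laps,
            time_to_complete_s=self.time_to_complete_s,
            iemg_mv_s=self._iemg_total,
            peak_emg_mv=self._peak_env,
            peak_emg_pct_mvc=self._peak_env / self.mvc,
        )


_ENGINES = {
    "high_striker": HighStrikerEngine,
    "boxing": BoxingEngine,
    "racing": RacingEngine,
}


def _play(engine_cls, game: str, stream: EmgStream, cfg: GameConfig,
          mvc_mv: float) -> tuple[list[FeedbackEvent], GameSummary]:
    if cfg.game != game:
        raise ValueError(f"config is for {cfg.game!r}, not {game!r}")
    if cfg.muscle != stream.muscle:
        raise ValueError(
            f"config muscle {cfg.muscle} does not match stream muscle "
            f"{stream.muscle}"
        )
    eng = engine_cls(cfg, mvc_mv, stream.sampling_rate_hz)
    eng.feed(stream.samples)
    return eng.finalize()


def play_high_striker(stream: EmgStream, cfg: GameConfig,
                      mvc_mv: float) -> tuple[list[FeedbackEvent], GameSummary]:
    """Run a high-striker session over a whole stream."""
    return _play(HighStrikerEngine, "high_striker", stream, cfg, mvc_mv)


def play_boxing(stream: EmgStream, cfg: GameConfig,
                mvc_mv: float) -> tuple[list[FeedbackEvent], GameSummary]:
    """Run a boxing session over a whole stream."""
    return _play(BoxingEngine, "boxing", stream, cfg, mvc_mv)


def play_racing(stream: EmgStream, cfg: GameConfig,
                mvc_mv: float) -> tuple[list[FeedbackEvent], GameSummary]:
    """Run a racing session over a whole stream."""
    return _play(RacingEngine, "racing", stream, cfg, mvc_mv)


@dataclass(frozen=True)
class RaceOutcome:
    """Dual-track (ghost) race result."""

    ghost_summary: GameSummary
    live_summary: GameSummary
    ghost_lap_times_s: tuple[float, ...]
    live_lap_times_s: tuple[float, ...]
    winner: str  # "ghost" | "live" | "tie"


def replay_ghost(ghost: EmgStream, live: EmgStream, cfg: GameConfig,
                 mvc_mv: float) -> RaceOutcome:
    """Race a live stream against a recorded one on identical kinematics.

    Both cars are simulated by :class:`RacingEngine`; the winner is the
    car that finishes the configured laps sooner (an unfinished car
    loses to a finished one; ties are reported as ties).
    """
    if ghost.sampling_rate_hz != live.sampling_rate_hz:
        raise ValueError("ghost and live streams must share a sampling rate")

    def _run(stream: EmgStream) -> tuple[GameSummary, tuple[float, ...]]:
        eng = RacingEngine(replace(cfg, muscle=stream.muscle), mvc_mv,
                           stream.sampling_rate_hz)
        eng.feed(stream.samples)
        _, summary = eng.finalize()
        return summary, tuple(eng.lap_times_s)

    gs, g_laps = _run(ghost)
    ls, l_laps = _run(live)
    g_t, l_t = gs.time_to_complete_s, ls.time_to_complete_s
    if g_t is not None and (l_t is None or g_t < l_t):
        winner = "ghost"
    elif l_t is not None and (g_t is None or l_t < g_t):
        winner = "live"
    elif g_t is None and l_t is None and gs.laps_completed != ls.laps_completed:
        winner = "ghost" if gs.laps_completed > ls.laps_completed else "live"
    else:
        winner = "tie"
    return RaceOutcome(gs, ls, g_laps, l_laps, winner)
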