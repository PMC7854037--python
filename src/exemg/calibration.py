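"""MVC calibration and the per-game threshold store.

Every game normalizes effort against the user's maximum voluntary
contraction (MVC).  Calibration runs three MVC trials per muscle; the
100% effort level is the best 3-second average within a trial, and the
MVC is the maximum across trials (all trial values are retained for
audit).  Default thresholds, as percentages of MVC:

========  ======  ============================
game      upper   lower
========  ======  ============================
high striker  90%   20%
boxing        80%   30%
racing       100%   measured resting noise floor
========  ======  ============================

Users may override any threshold; only the ordering ``0 <= lower <
upper`` is enforced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .signal import EmgStream, MuscleId

__all__ = [
    "GAMES",
    "CalibrationResult",
    "Thresholds",
    "GoalSet",
    "estimate_noise_floor",
    "calibrate_mvc",
    "default_goals",
    "DEFAULT_THRESHOLD_PCT",
]

GAMES = ("high_striker", "boxing", "racing")

#: (upper, lower) as fractions of MVC; racing lower comes from the rest
#: recording instead.
DEFAULT_THRESHOLD_PCT: dict[str, tuple[float, float | None]] = {
    "high_striker": (0.90, 0.20),
    "boxing": (0.80, 0.30),
    "racing": (1.00, None),
}


@dataclass(frozen=True)
class CalibrationResult:
    """Per-muscle normalization reference.

    ``mvc_mv`` is the 100% effort level; ``trial_means_mv`` holds each
    trial's best window mean, in trial order.
    """

    muscle: MuscleId
    mvc_mv: float
    noise_floor_mv: float
    trial_means_mv: tuple[float, ...]
    window_s: float = 3.0

    def __post_init__(self) -> None:
        if self.mvc_mv <= 0:
            raise ValueError("mvc_mv must be positive")
        if self.noise_floor_mv < 0:
            raise ValueError("noise_floor_mv must be non-negative")
        if self.mvc_mv <= self.noise_floor_mv:
            raise ValueError("MVC must exceed the noise floor")


@dataclass(frozen=True)
class Thresholds:
    """One game's (lower, upper) amplitude pair in mV."""

    lower_mv: float
    upper_mv: float

    def __post_init__(self) -> None:
        if not 0 <= self.lower_mv < self.upper_mv:
            raise ValueError(
                f"thresholds must satisfy 0 <= lower < upper, got "
                f"({self.lower_mv}, {self.upper_mv})"
            )


@dataclass
class GoalSet:
    """Persistent per-(game, muscle) threshold store.

    Mirrors the app's "My Goals" page: thresholds are saved once and
    fetched for the appropriate game at the start of each session.
    """

    entries: dict[tuple[str, MuscleId], Thresholds] = field(default_factory=dict)

    def set(self, game: str, muscle: MuscleId, lower_mv: float,
            upper_mv: float) -> None:
        if game not in GAMES:
            raise ValueError(f"unknown game {game!r}; expected one of {GAMES}")
        self.entries[(game, MuscleId(muscle))] = Thresholds(lower_mv, upper_mv)

    def get(self, game: str, muscle: MuscleId) -> Thresholds:
        key = (game, MuscleId(muscle))
        if key not in self.entries:
            raise KeyError(
                f"no thresholds stored for game={game!r}, muscle={muscle}; "
                "run calibration first"
            )
        return self.entries[key]

    # -- persistence (JSON keyed by game then muscle) ----------------------
    def to_json(self) -> str:
        obj: dict[str, dict[str, dict[str, float]]] = {}
        for (game, muscle), th in sorted(
            self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            obj.setdefault(game, {})[muscle.value] = {
                "lower_mv": th.lower_mv,
                "upper_mv": th.upper_mv,
            }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GoalSet":
        obj = json.loads(text)
        gs = cls()
        for game, per_muscle in obj.items():
            for muscle, th in per_muscle.items():
                gs.set(game, MuscleId(muscle), th["lower_mv"], th["upper_mv"])
        return gs


def estimate_noise_floor(rest: EmgStream) -> float:
    """Resting envelope level: the median of a burst-free rest recording.

    The median is robust to stray movement artifacts, matching how a
    technician would read an "empirical" baseline off a quiet trace.
    """
    if len(rest) == 0:
        raise ValueError("rest stream is empty")
    return float(np.median(rest.samples))


def _best_window_mean(x: np.ndarray, w: int) -> float:
    """Maximum mean over all contiguous length-``w`` windows (sliding)."""
    if w > x.size:
        raise ValueError("window longer than trial")
    c = np.concatenate(([0.0], np.cumsum(x)))
    sums = c[w:] - c[:-w]
    return float(np.max(sums) / w)


def calibrate_mvc(
    trials: list[EmgStream],
    rest: EmgStream | None = None,
    window_s: float = 3.0,
    n_trials_expected: int = 3,
    combine: str = "max",
) -> CalibrationResult:
    """Derive the 100% effort level from MVC trials.

    For each trial the mean is taken over every contiguous ``window_s``
    window at sample resolution and the best window wins, so the result
    does not depend on when in the trial the contraction happened.  The
    trial values combine via ``combine`` ("max" by default — standard MVC
    practice; "mean" and "last" are provided for sensitivity checks).

    ``rest`` supplies the resting noise floor (median); without it the
    floor is taken as 0.
    """
    if not trials:
        raise ValueError("at least one MVC trial is required")
    if len(trials) != n_trials_expected:
        raise ValueError(
            f"expected {n_trials_expected} MVC trials, got {len(trials)}"
        )
    muscles = {t.muscle for t in trials}
    if len(muscles) != 1:
        raise ValueError("all trials must record the same muscle")
    means = []
    for tr in trials:
        w = int(round(window_s * tr.sampling_rate_hz))
        if w <= 0 or w > len(tr):
            raise ValueError(
                f"trial of {tr.duration_s:g}s is shorter than the "
                f"{window_s:g}s averaging window"
            )
        means.append(_best_window_mean(tr.samples, w))
    if combine == "max":
        mvc = max(means)
    elif combine == "mean":
        mvc = float(np.mean(means))
    elif combine == "last":
        mvc = means[-1]
    else:
        raise ValueError("combine must be one of 'max', 'mean', 'last'")
    floor = estimate_noise_floor(rest) if rest is not None else 0.0
    return CalibrationResult(
        muscle=muscles.pop(),
        mvc_mv=mvc,
        noise_floor_mv=floor,
        trial_means_mv=tuple(means),
        window_s=window_s,
    )


def default_goals(calib: CalibrationResult) -> GoalSet:
    """Per-game default thresholds from a calibration.

    High striker: 90% / 20% of MVC; boxing: 80% / 30%; racing: 100% of
    MVC over the measured noise floor.
    """
    if calib.mvc_mv <= calib.noise_floor_mv:
        raise ValueError("MVC must exceed the noise floor")
    gs = GoalSet()
    for game, (up_frac, lo_frac) in DEFAULT_THRESHOLD_PCT.items():
        lower = (calib.noise_floor_mv if lo_frac is None
                 else lo_frac * calib.mvc_mv)
        gs.set(game, calib.muscle, lower, up_frac * calib.mvc_mv)
    return gs
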