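"""Synthetic usage cohorts shaped like the home pilot.

Emulates the study conditions for the analytics pipeline: a small
cohort (4 users by default) using the app over 8 weeks, around 3
sessions per week of roughly 45 minutes, spending about half of their
logged-in time actually exergaming, with per-session iEMG proportional
to exergaming minutes (the linear iEMG–energy relationship) plus
multiplicative noise.  Per-user mean weekly app minutes are drawn
uniformly over 89–267 minutes, the span reported for the pilot cohort,
and the exergaming fraction is centred on 0.53.

The generator returns both the session records and a ground-truth
ledger (per-user-week minute and iEMG totals, and the iEMG-per-minute
constant) so tests can check the analytics against bookkeeping rather
than against the code under test.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .analytics import GameSessionRecord, SessionRecord
from .games import GameSummary
from .signal import MuscleId

__all__ = ["CohortTruth", "generate_cohort"]

_GAMES = ("high_striker", "boxing", "racing")
_MUSCLES = tuple(MuscleId)

#: default iEMG accrual, mV·s per exergaming minute (~0.3 mV mean envelope)
DEFAULT_IEMG_PER_MIN = 18.0


@dataclass(frozen=True)
class CohortTruth:
    """Generator bookkeeping for validating the analytics."""

    weekly_minutes_on_app: dict[tuple[str, int], float]
    weekly_minutes_exergaming: dict[tuple[str, int], float]
    weekly_iemg: dict[tuple[str, int], float]
    iemg_per_minute: float
    user_mean_weekly_minutes: dict[str, float]


def generate_cohort(
    n_users: int = 4,
    n_weeks: int = 8,
    sessions_per_week: int = 3,
    weekly_minutes_range: tuple[float, float] = (89.0, 267.0),
    exergaming_fraction: float = 0.53,
    exergaming_fraction_sd: float = 0.06,
    iemg_per_minute: float = DEFAULT_IEMG_PER_MIN,
    iemg_noise_rel_sd: float = 0.08,
    session_length_rel_sd: float = 0.2,
    mvc_mv: float = 1.0,
    start: datetime = datetime(2021, 1, 4, 9, 0, 0),
    seed: int = 0,
) -> tuple[list[SessionRecord], CohortTruth]:
    """Generate a synthetic cohort of app sessions.

    Each user logs ``sessions_per_week`` sessions per week on separate
    days.  A session's app minutes jitter around the user's weekly
    budget split evenly across sessions; a fraction of each session is
    spent in 1–3 game sub-sessions, and each game sub-session accrues
    ``iemg_per_minute * minutes * (1 + noise)`` of iEMG.  Deterministic
    per seed.
    """
    if n_users <= 0 or n_weeks <= 0 or sessions_per_week <= 0:
        raise ValueError("cohort dimensions must be positive")
    rng = np.random.default_rng(seed)
    records: list[SessionRecord] = []
    on_app: dict[tuple[str, int], float] = {}
    gaming: dict[tuple[str, int], float] = {}
    iemg_truth: dict[tuple[str, int], float] = {}
    user_weekly: dict[str, float] = {}

    day_slots = np.linspace(0, 6, sessions_per_week + 1)[:-1]
    for u in range(n_users):
        user_id = f"S{u + 1}"
        weekly = float(rng.uniform(*weekly_minutes_range))
        user_weekly[user_id] = weekly
        # one time-of-day per user keeps week boundaries exact multiples
        # of 7 days from the first login
        minute_offset = int(rng.integers(0, 60))
        for w in range(n_weeks):
            for k in range(sessions_per_week):
                base_min = weekly / sessions_per_week
                minutes = base_min * float(
                    np.exp(rng.normal(0.0, session_length_rel_sd))
                )
                minutes = max(minutes, 5.0)
                frac = float(np.clip(
                    rng.normal(exergaming_fraction, exergaming_fraction_sd),
                    0.2, 0.9,
                ))
                login = (start + timedelta(days=7 * w + int(day_slots[k]),
                                           hours=u)
                         + timedelta(minutes=minute_offset))
                logout = login + timedelta(seconds=round(minutes * 60))
                game_min_total = minutes * frac
                n_games = int(rng.integers(1, 4))
                shares = rng.dirichlet(np.ones(n_games))
                cursor = login
                game_sessions = []
                for g in range(n_games):
                    gmin = float(game_min_total * shares[g])
                    game = _GAMES[int(rng.integers(0, len(_GAMES)))]
                    muscle = _MUSCLES[int(rng.integers(0, len(_MUSCLES)))]
                    g_start = cursor
                    g_end = g_start + timedelta(seconds=round(gmin * 60))
                    gmin_actual = (g_end - g_start).total_seconds() / 60.0
                    iemg = (iemg_per_minute * gmin_actual
                            * (1.0 + float(rng.normal(0.0, iemg_noise_rel_sd))))
                    iemg = max(iemg, 0.0)
                    peak = float(rng.uniform(0.5, 1.0)) * mvc_mv
                    summary = GameSummary(
                        game=game,
                        duration_s=gmin_actual * 60.0,
                        iemg_mv_s=iemg,
                        peak_emg_mv=peak,
                        peak_emg_pct_mvc=peak / mvc_mv,
                    )
                    game_sessions.append(GameSessionRecord(
                        game=game, muscle=muscle, start_time=g_start,
                        end_time=g_end, summary=summary,
                    ))
                    cursor = g_end
                rec = SessionRecord(user_id, login, logout,
                                    tuple(game_sessions))
                records.append(rec)
                key = (user_id, w)
                on_app[key] = on_app.get(key, 0.0) + rec.minutes_on_app
                gaming[key] = gaming.get(key, 0.0) + rec.minutes_exergaming
                iemg_truth[key] = iemg_truth.get(key, 0.0) + sum(
                    gs.summary.iemg_mv_s for gs in game_sessions
                )
    truth = CohortTruth(on_app, gaming, iemg_truth, iemg_per_minute,
                        user_weekly)
    return records, truth
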