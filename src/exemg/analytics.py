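"""Session persistence and usage/energy/survey analytics.

The original system wrote every game session to a cloud store and
analyzed log-ins, time on the app versus time actually exergaming,
integrated EMG (a linear proxy for energy expenditure), and peak EMG,
plus 1–5 Likert questionnaires.  This module provides the same pipeline
over a documented local schema: one JSON file per app session plus an
index CSV, weekly per-user usage rollups, Pearson correlations between
session length and iEMG, an affine energy proxy, and survey summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .games import GameSummary
from .signal import MuscleId

__all__ = [
    "GameSessionRecord",
    "SessionRecord",
    "WeeklyUsage",
    "SurveyResponse",
    "SurveyItemSummary",
    "weekly_usage",
    "iemg_vs_time_correlation",
    "energy_estimate",
    "summarize_survey",
    "session_to_json",
    "session_from_json",
    "save_sessions",
    "load_sessions",
    "weekly_usage_frame",
    "plot_weekly_usage",
]

_ISO = "%Y-%m-%dT%H:%M:%S"


@dataclass(frozen=True)
class GameSessionRecord:
    """One game played within an app session."""

    game: str
    muscle: MuscleId
    start_time: datetime
    end_time: datetime
    summary: GameSummary
    stream_ref: str | None = None

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError("game session must end after it starts")

    @property
    def minutes(self) -> float:
        return (self.end_time - self.start_time).total_seconds() / 60.0


@dataclass(frozen=True)
class SessionRecord:
    """One app session: a login span containing zero or more games."""

    user_id: str
    login_time: datetime
    logout_time: datetime
    game_sessions: tuple[GameSessionRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "game_sessions", tuple(self.game_sessions))
        if self.logout_time < self.login_time:
            raise ValueError("logout must not precede login")
        for gs in self.game_sessions:
            if gs.start_time < self.login_time or gs.end_time > self.logout_time:
                raise ValueError("game session outside the login span")

    @property
    def minutes_on_app(self) -> float:
        return (self.logout_time - self.login_time).total_seconds() / 60.0

    @property
    def minutes_exergaming(self) -> float:
        return sum(gs.minutes for gs in self.game_sessions)


@dataclass(frozen=True)
class WeeklyUsage:
    """Per-user, per-week usage rollup (weeks count from first login)."""

    user_id: str
    week_index: int
    minutes_on_app: float
    minutes_exergaming: float
    pct_exergaming: float
    n_logins: int
    total_iemg_mv_s: float
    peak_emg_mv: float

    def __post_init__(self) -> None:
        if not 0 <= self.minutes_exergaming <= self.minutes_on_app + 1e-9:
            raise ValueError("exergaming minutes cannot exceed app minutes")


def _check_no_overlap(sessions: list[SessionRecord]) -> None:
    ordered = sorted(sessions, key=lambda s: s.login_time)
    for a, b in zip(ordered, ordered[1:]):
        if b.login_time < a.logout_time:
            raise ValueError(
                f"overlapping sessions for user {a.user_id!r} at "
                f"{b.login_time.isoformat()}"
            )


def weekly_usage(records: list[SessionRecord]) -> list[WeeklyUsage]:
    """Roll app sessions up into per-user weeks.

    Weeks are user-relative: week 0 starts at each user's first login.
    Overlapping sessions for one user are a data-integrity error.
    """
    out: list[WeeklyUsage] = []
    by_user: dict[str, list[SessionRecord]] = {}
    for rec in records:
        by_user.setdefault(rec.user_id, []).append(rec)
    for user_id in sorted(by_user):
        sessions = by_user[user_id]
        _check_no_overlap(sessions)
        first = min(s.login_time for s in sessions)
        weeks: dict[int, list[SessionRecord]] = {}
        for s in sessions:
            w = int((s.login_time - first).total_seconds() // (7 * 86400))
            weeks.setdefault(w, []).append(s)
        for w in sorted(weeks):
            ss = weeks[w]
            on_app = sum(s.minutes_on_app for s in ss)
            gaming = sum(s.minutes_exergaming for s in ss)
            iemg = sum(gs.summary.iemg_mv_s
                       for s in ss for gs in s.game_sessions)
            peaks = [gs.summary.peak_emg_mv
                     for s in ss for gs in s.game_sessions]
            out.append(WeeklyUsage(
                user_id=user_id,
                week_index=w,
                minutes_on_app=on_app,
                minutes_exergaming=gaming,
                pct_exergaming=100.0 * gaming / on_app if on_app > 0 else 0.0,
                n_logins=len(ss),
                total_iemg_mv_s=iemg,
                peak_emg_mv=max(peaks, default=0.0),
            ))
    return out


def weekly_usage_frame(records: list[SessionRecord]) -> pd.DataFrame:
    """Weekly usage as a DataFrame (one row per user-week)."""
    rows = weekly_usage(records)
    return pd.DataFrame([r.__dict__ for r in rows])


def _session_pairs(records: list[SessionRecord]) -> pd.DataFrame:
    rows = []
    for s in records:
        for gs in s.game_sessions:
            rows.append({
                "user_id": s.user_id,
                "game": gs.game,
                "minutes": gs.minutes,
                "iemg_mv_s": gs.summary.iemg_mv_s,
            })
    return pd.DataFrame(rows)


def iemg_vs_time_correlation(
    records: list[SessionRecord],
    per: str = "session",
) -> dict[str, float]:
    """Pearson r between time played and iEMG, per game and pooled.

    ``per="session"`` (default) pairs each game session's minutes with
    its iEMG; ``per="week"`` first sums both within user-weeks.  Returns
    ``{"all": r, "<game>": r, ...}`` for every game with at least 3
    pairs; raises if either variable has zero variance (r undefined).
    """
    if per not in ("session", "week"):
        raise ValueError("per must be 'session' or 'week'")
    df = _session_pairs(records)
    if df.empty:
        raise ValueError("no game sessions to correlate")
    if per == "week":
        wk = weekly_usage_frame(records)
        df = wk.rename(columns={"minutes_exergaming": "minutes",
                                "total_iemg_mv_s": "iemg_mv_s"})
        df["game"] = "all"
    out: dict[str, float] = {}
    groups: list[tuple[str, pd.DataFrame]] = [("all", df)]
    if per == "session":
        groups += [(g, sub) for g, sub in df.groupby("game")]
    for name, sub in groups:
        if len(sub) < 3:
            continue
        x = sub["minutes"].to_numpy(float)
        y = sub["iemg_mv_s"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(
                f"Pearson r undefined for {name!r}: zero variance"
            )
        out[str(name)] = float(_st.pearsonr(x, y).statistic)
    return out


def energy_estimate(iemg_mv_s: float, slope: float = 1.0,
                    intercept: float = 0.0) -> float:
    """Affine energy-expenditure proxy from iEMG.

    iEMG rises linearly with energy expenditure, so the proxy is
    ``slope * iemg + intercept``.  With the default unit coefficients the
    result is in arbitrary units — it is a monotone proxy, not a
    validated kilocalorie measurement; calibrated coefficients (e.g.
    kcal or MET-minutes per mV·s) can be supplied when available.
    """
    if slope < 0:
        raise ValueError("slope must be non-negative")
    if intercept < 0:
        raise ValueError("intercept must be non-negative")
    return slope * iemg_mv_s + intercept


# ---------------------------------------------------------------------------
# Likert surveys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyResponse:
    """One respondent's 1–5 Likert answer to one item."""

    item_id: str
    likert_value: int
    respondent: str = ""

    def __post_init__(self) -> None:
        if self.likert_value not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"Likert value must be in 1..5, got {self.likert_value}"
            )


@dataclass(frozen=True)
class SurveyItemSummary:
    """Per-item mean and sample SD (n-1); SD is None when n < 2."""

    item_id: str
    mean: float
    sd: float | None
    n: int


def summarize_survey(
    responses: list[SurveyResponse],
) -> dict[str, SurveyItemSummary]:
    """Mean (SD) per item, in the usual questionnaire-table format."""
    by_item: dict[str, list[int]] = {}
    for r in responses:
        by_item.setdefault(r.item_id, []).append(r.likert_value)
    out = {}
    for item in sorted(by_item):
        vals = np.asarray(by_item[item], dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else None
        out[item] = SurveyItemSummary(item, float(np.mean(vals)), sd,
                                      int(vals.size))
    return out


def survey_from_csv(path_or_buf) -> list[SurveyResponse]:
    """Read responses from CSV with columns item_id, likert_value[, respondent]."""
    df = pd.read_csv(path_or_buf)
    if not {"item_id", "likert_value"}.issubset(df.columns):
        raise ValueError("survey CSV needs columns item_id, likert_value")
    return [
        SurveyResponse(str(r.item_id), int(r.likert_value),
                       str(getattr(r, "respondent", "")))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Persistence: one JSON per session + an index CSV.  The writer is
# deterministic (fixed key order, repr floats) so write -> read -> write
# is byte-identical.
# ---------------------------------------------------------------------------

def _summary_to_obj(s: GameSummary) -> dict:
    return {
        "game": s.game,
        "duration_s": s.duration_s,
        "reps_detected": s.reps_detected,
        "bells_hit": s.bells_hit,
        "rounds_completed": s.rounds_completed,
        "punches_per_round_detected": list(s.punches_per_round_detected),
        "laps_completed": s.laps_completed,
        "time_to_complete_s": s.time_to_complete_s,
        "iemg_mv_s": s.iemg_mv_s,
        "peak_emg_mv": s.peak_emg_mv,
        "peak_emg_pct_mvc": s.peak_emg_pct_mvc,
    }


def _summary_from_obj(o: dict) -> GameSummary:
    return GameSummary(
        game=o["game"],
        duration_s=o["duration_s"],
        reps_detected=o["reps_detected"],
        bells_hit=o["bells_hit"],
        rounds_completed=o["rounds_completed"],
        punches_per_round_detected=tuple(o["punches_per_round_detected"]),
        laps_completed=o["laps_completed"],
        time_to_complete_s=o["time_to_complete_s"],
        iemg_mv_s=o["iemg_mv_s"],
        peak_emg_mv=o["peak_emg_mv"],
        peak_emg_pct_mvc=o["peak_emg_pct_mvc"],
    )


def session_to_json(rec: SessionRecord) -> str:
    obj = {
        "user_id": rec.user_id,
        "login_time": rec.login_time.strftime(_ISO),
        "logout_time": rec.logout_time.strftime(_ISO),
        "game_sessions": [
            {
                "game": gs.game,
                "muscle": gs.muscle.value,
                "start_time": gs.start_time.strftime(_ISO),
                "end_time": gs.end_time.strftime(_ISO),
                "stream_ref": gs.stream_ref,
                "summary": _summary_to_obj(gs.summary),
            }
            for gs in rec.game_sessions
        ],
    }
    return json.dumps(obj, indent=2)


def session_from_json(text: str) -> SessionRecord:
    o = json.loads(text)
    return SessionRecord(
        user_id=o["user_id"],
        login_time=datetime.strptime(o["login_time"], _ISO),
        logout_time=datetime.strptime(o["logout_time"], _ISO),
        game_sessions=tuple(
            GameSessionRecord(
                game=g["game"],
                muscle=MuscleId(g["muscle"]),
                start_time=datetime.strptime(g["start_time"], _ISO),
                end_time=datetime.strptime(g["end_time"], _ISO),
                summary=_summary_from_obj(g["summary"]),
                stream_ref=g.get("stream_ref"),
            )
            for g in o["game_sessions"]
        ),
    )


def save_sessions(records: list[SessionRecord], directory) -> Path:
    """Write one JSON per session plus ``index.csv``; returns the directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in sorted(records, key=lambda r: (r.user_id, r.login_time)):
        name = f"session_{rec.user_id}_{rec.login_time.strftime('%Y%m%dT%H%M%S')}.json"
        (d / name).write_text(session_to_json(rec))
        rows.append({
            "user_id": rec.user_id,
            "login_time": rec.login_time.strftime(_ISO),
            "logout_time": rec.logout_time.strftime(_ISO),
            "n_games": len(rec.game_sessions),
            "file": name,
        })
    pd.DataFrame(rows).to_csv(d / "index.csv", index=False)
    return d


def load_sessions(directory) -> list[SessionRecord]:
    d = Path(directory)
    index = pd.read_csv(d / "index.csv")
    return [session_from_json((d / f).read_text()) for f in index["file"]]


def plot_weekly_usage(records: list[SessionRecord], out_path) -> None:
    """Bar panels of weekly app minutes, exergaming minutes, and percent.

    Optional figure mirroring the shape of the pilot usage plots; writes
    a PNG and never shows a window.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = weekly_usage_frame(records)
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    for ax, col, label in zip(
        axes,
        ["minutes_on_app", "minutes_exergaming", "pct_exergaming"],
        ["Minutes on app", "Minutes exergaming", "% time exergaming"],
    ):
        for user, sub in df.groupby("user_id"):
            ax.plot(sub["week_index"] + 1, sub[col], marker="o", label=user)
        ax.set_ylabel(label)
    axes[0].legend(loc="upper right", fontsize=8)
    axes[-1].set_xlabel("Week")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
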