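"""The three game engines: scoring rules, closed forms, invariants."""

import math

import numpy as np
import pytest

from exemg import (
    BoxingEngine,
    EmgStream,
    GameConfig,
    HighStrikerEngine,
    MuscleId,
    RacingEngine,
    SensorSpec,
    Thresholds,
    generate_stream,
    play_boxing,
    play_high_striker,
    play_racing,
    pulse_train_profile,
    replay_ghost,
)

MVC = 1.0
M = MuscleId.BICEP


def _cfg(game, lower, upper, **kw):
    return GameConfig(game=game, muscle=M,
                      thresholds=Thresholds(lower, upper), **kw)


def _train(n, amp, **kw):
    kw.setdefault("noise_floor_mv", 0.02)
    prof = pulse_train_profile(n, amp, **kw)
    return generate_stream(prof, M, total_duration_s=prof.span_s + 1.0)


def _const(value, duration_s, fs=64.0):
    spec = SensorSpec(sampling_rate_hz=fs)
    return EmgStream(M, spec, 0.0, np.full(int(duration_s * fs), value))


class TestHighStriker:
    CFG = dict(lower=0.2 * MVC, upper=0.9 * MVC)

    def test_silent_stream_scores_nothing(self):
        ev, s = play_high_striker(_const(0.0, 5.0),
                                  _cfg("high_striker", **self.CFG), MVC)
        assert (s.reps_detected, s.bells_hit) == (0, 0)

    def test_ten_hard_contractions_ring_ten_bells(self):
        ev, s = play_high_striker(_train(10, 0.95),
                                  _cfg("high_striker", **self.CFG), MVC)
        assert s.reps_detected == 10
        assert s.bells_hit == 10
        assert sum(e.kind == "bell_hit" for e in ev) == 10

    def test_soft_contractions_count_reps_but_no_bells(self):
        ev, s = play_high_striker(_train(10, 0.5),
                                  _cfg("high_striker", **self.CFG), MVC)
        assert s.reps_detected == 10
        assert s.bells_hit == 0

    def test_bar_height_is_iemg_over_reference(self):
        # one 3 s contraction at full MVC saturates the default 3 s bar
        stream = _train(1, MVC + 0.05, pulse_s=3.0, rise_s=0.0, fall_s=0.0)
        ev, s = play_high_striker(stream, _cfg("high_striker", **self.CFG),
                                  MVC)
        reps = [e for e in ev if e.kind == "rep_detected"]
        assert reps[0].payload["bar_height_fraction"] == pytest.approx(1.0)
        # a half-second contraction fills about a sixth of the bar
        stream = _train(1, MVC, pulse_s=0.5, rise_s=0.0, fall_s=0.0)
        ev, _ = play_high_striker(stream, _cfg("high_striker", **self.CFG),
                                  MVC)
        reps = [e for e in ev if e.kind == "rep_detected"]
        assert reps[0].payload["bar_height_fraction"] == pytest.approx(
            0.5 / 3.0, rel=0.1)

    def test_bar_bell_rule(self):
        stream = _train(1, MVC + 0.1, pulse_s=3.5, rise_s=0.0, fall_s=0.0)
        cfg = _cfg("high_striker", lower=0.2, upper=2.0, bell_rule="bar")
        ev, s = play_high_striker(stream, cfg, MVC)
        assert s.bells_hit == 1  # bar saturated even though peak < upper

    def test_bells_never_exceed_reps(self):
        rng = np.random.default_rng(21)
        for seed in range(10):
            prof = pulse_train_profile(
                8, float(rng.uniform(0.3, 1.2)), noise_jitter=0.15, seed=seed)
            stream = generate_stream(prof, M)
            _, s = play_high_striker(stream,
                                     _cfg("high_striker", **self.CFG), MVC)
            assert s.bells_hit <= s.reps_detected


class TestBoxing:
    CFG = dict(lower=0.3 * MVC, upper=0.8 * MVC)

    def test_default_schedule_escalates_linearly(self):
        cfg = _cfg("boxing", **self.CFG)
        assert cfg.round_schedule() == pytest.approx((0.30, 0.55, 0.80))

    def test_ninety_hard_punches_complete_three_rounds(self):
        stream = _train(90, 0.85, pulse_s=0.5, gap_s=0.5)
        ev, s = play_boxing(stream, _cfg("boxing", **self.CFG), MVC)
        assert s.rounds_completed == 3
        assert s.punches_per_round_detected == (30, 30, 30)
        assert sum(e.kind == "round_advanced" for e in ev) == 2
        assert [e.kind for e in ev if e.kind in ("round_advanced",
                                                 "game_over")][-1] == "game_over"

    def test_twenty_nine_punches_do_not_advance(self):
        stream = _train(29, 0.85, pulse_s=0.5, gap_s=0.5)
        _, s = play_boxing(stream, _cfg("boxing", **self.CFG), MVC)
        assert s.rounds_completed == 0
        assert s.punches_per_round_detected[0] == 29

    def test_weak_punches_stall_after_round_one(self):
        # 0.35 MVC clears round 1 (0.30) but never round 2 (0.55)
        stream = _train(70, 0.35, pulse_s=0.5, gap_s=0.5)
        _, s = play_boxing(stream, _cfg("boxing", **self.CFG), MVC)
        assert s.rounds_completed == 1
        assert s.punches_per_round_detected[0] == 30
        assert s.punches_per_round_detected[1] == 0

    def test_exactly_thirty_advances(self):
        stream = _train(30, 0.85, pulse_s=0.5, gap_s=0.5)
        ev, s = play_boxing(stream, _cfg("boxing", **self.CFG), MVC)
        assert s.rounds_completed == 1
        assert sum(e.kind == "round_advanced" for e in ev) == 1

    def test_explicit_schedule_validated(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            _cfg("boxing", **self.CFG, round_thresholds_mv=(0.5, 0.4, 0.6))
        with pytest.raises(ValueError, match="length"):
            _cfg("boxing", **self.CFG, round_thresholds_mv=(0.5, 0.6))


class TestRacing:
    CFG = dict(lower=0.05, upper=MVC)

    def test_constant_full_effort_lap_time_closed_form(self):
        cfg = _cfg("racing", **self.CFG, n_laps=3, reference_lap_s=10.0)
        ev, s = play_racing(_const(MVC, 40.0), cfg, MVC)
        g = cfg.racing_gain
        assert g == pytest.approx(2 * math.pi / 10.0)
        assert s.laps_completed == 3
        assert s.time_to_complete_s == pytest.approx(3 * 2 * math.pi / g,
                                                     abs=3 / 64)

    def test_half_effort_doubles_lap_time(self):
        cfg = _cfg("racing", **self.CFG, n_laps=1, reference_lap_s=10.0)
        _, full = play_racing(_const(MVC, 30.0), cfg, MVC)
        _, half = play_racing(_const(MVC / 2, 30.0), cfg, MVC)
        assert half.time_to_complete_s == pytest.approx(
            2 * full.time_to_complete_s, abs=2 / 64)

    def test_below_noise_floor_never_moves(self):
        cfg = _cfg("racing", **self.CFG, n_laps=1)
        _, s = play_racing(_const(0.04, 20.0), cfg, MVC)
        assert s.laps_completed == 0
        assert s.time_to_complete_s is None

    def test_effort_clamped_at_upper(self):
        cfg = _cfg("racing", lower=0.05, upper=0.5 * MVC, n_laps=1,
                   reference_lap_s=10.0)
        _, s = play_racing(_const(MVC, 40.0), cfg, MVC)
        # envelope at MVC but clamped to 0.5 -> lap takes 20 s
        assert s.time_to_complete_s == pytest.approx(20.0, abs=2 / 64)

    def test_final_lap_cue_fires_once_when_one_remains(self):
        cfg = _cfg("racing", **self.CFG, n_laps=2, reference_lap_s=5.0)
        ev, _ = play_racing(_const(MVC, 20.0), cfg, MVC)
        cues = [e for e in ev if e.kind == "final_lap_cue"]
        assert len(cues) == 1
        assert cues[0].payload["text"] == "One final lap!"
        assert cues[0].time_s == pytest.approx(5.0, abs=2 / 64)

    def test_laps_monotone_in_pointwise_larger_envelope(self):
        rng = np.random.default_rng(17)
        cfg = _cfg("racing", **self.CFG, n_laps=50, reference_lap_s=5.0)
        base = rng.uniform(0.0, 1.0, size=64 * 30)
        bigger = np.minimum(base + rng.uniform(0.0, 0.3, size=base.size), 1.0)
        spec = SensorSpec()
        _, s_lo = play_racing(EmgStream(M, spec, 0.0, base), cfg, MVC)
        _, s_hi = play_racing(EmgStream(M, spec, 0.0, bigger), cfg, MVC)
        assert s_hi.laps_completed >= s_lo.laps_completed


class TestGhostReplay:
    def test_identical_streams_tie(self):
        cfg = _cfg("racing", lower=0.05, upper=MVC, n_laps=2)
        stream = _const(0.8, 40.0)
        out = replay_ghost(stream, stream, cfg, MVC)
        assert out.winner == "tie"
        assert out.ghost_lap_times_s == out.live_lap_times_s

    def test_faster_ghost_wins_with_half_lap_time(self):
        cfg = _cfg("racing", lower=0.01, upper=MVC, n_laps=2,
                   reference_lap_s=8.0)
        ghost = _const(MVC, 60.0)
        live = _const(MVC / 2, 60.0)
        out = replay_ghost(ghost, live, cfg, MVC)
        assert out.winner == "ghost"
        assert out.ghost_summary.time_to_complete_s == pytest.approx(
            out.live_summary.time_to_complete_s / 2, abs=3 / 64)

    def test_rate_mismatch_rejected(self):
        cfg = _cfg("racing", lower=0.05, upper=MVC)
        a = _const(0.5, 10.0, fs=64.0)
        b = _const(0.5, 10.0, fs=32.0)
        with pytest.raises(ValueError, match="sampling rate"):
            replay_ghost(a, b, cfg, MVC)


class TestEngineMechanics:
    """Cross-cutting engine invariants."""

    @pytest.mark.parametrize("engine_cls,game,kw", [
        (HighStrikerEngine, "high_striker", dict(lower=0.2, upper=0.9)),
        (BoxingEngine, "boxing", dict(lower=0.3, upper=0.8)),
        (RacingEngine, "racing", dict(lower=0.05, upper=1.0)),
    ])
    def test_chunked_feed_equals_one_pass(self, engine_cls, game, kw):
        prof = pulse_train_profile(40, 0.9, pulse_s=0.5, gap_s=0.5,
                                   noise_jitter=0.1, seed=5)
        stream = generate_stream(prof, M)
        cfg = _cfg(game, **kw)
        one = engine_cls(cfg, MVC, stream.sampling_rate_hz)
        one.feed(stream.samples)
        ev_one, sum_one = one.finalize()
        two = engine_cls(cfg, MVC, stream.sampling_rate_hz)
        cut = len(stream) // 3
        two.feed(stream.samples[:cut])
        two.feed(stream.samples[cut:])
        ev_two, sum_two = two.finalize()
        assert ev_one == ev_two
        assert sum_one == sum_two

    @pytest.mark.parametrize("player,game,kw", [
        (play_high_striker, "high_striker", dict(lower=0.2, upper=0.9)),
        (play_boxing, "boxing", dict(lower=0.3, upper=0.8)),
        (play_racing, "racing", dict(lower=0.05, upper=1.0)),
    ])
    def test_replay_is_bit_identical(self, player, game, kw):
        prof = pulse_train_profile(20, 0.9, noise_jitter=0.1, seed=9)
        stream = generate_stream(prof, M)
        cfg = _cfg(game, **kw)
        assert player(stream, cfg, MVC) == player(stream, cfg, MVC)

    def test_session_iemg_equals_whole_stream_integral(self):
        from exemg import integrate_emg
        prof = pulse_train_profile(10, 0.9, noise_jitter=0.1, seed=2)
        stream = generate_stream(prof, M)
        _, s = play_high_striker(stream,
                                 _cfg("high_striker", lower=0.2, upper=0.9),
                                 MVC)
        assert s.iemg_mv_s == pytest.approx(
            integrate_emg(stream, 0.0, stream.duration_s), rel=1e-9)

    def test_events_are_time_ordered(self):
        prof = pulse_train_profile(35, 0.85, pulse_s=0.5, gap_s=0.5)
        stream = generate_stream(prof, M)
        ev, _ = play_boxing(stream, _cfg("boxing", lower=0.3, upper=0.8), MVC)
        times = [e.time_s for e in ev]
        assert times == sorted(times)

    def test_wrong_game_config_rejected(self):
        with pytest.raises(ValueError, match="config is for"):
            play_boxing(_const(0.0, 2.0),
                        _cfg("racing", lower=0.05, upper=1.0), MVC)

    def test_non_positive_mvc_rejected(self):
        with pytest.raises(ValueError, match="mvc"):
            play_racing(_const(0.5, 2.0),
                        _cfg("racing", lower=0.05, upper=1.0), 0.0)
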