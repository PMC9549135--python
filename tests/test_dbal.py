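"""D'_BAL kinetics: timelines, convolution evaluation, summaries."""

import numpy as np
import pandas as pd
import pytest

from dprimebal import (
    Segment,
    SessionPlan,
    SessionTimeline,
    balance_at,
    build_timeline,
    simulate_dbal,
    summarize,
    timeline_from_log,
)


def dense_grid_dbal(timeline, cs, d_prime, tau, t_eval, dt=1e-3):
    """Independent oracle: brute-force numerical convolution on a fine grid.

    Left-Riemann accumulation of expenditure increments, each decayed by
    exp(-(t-u)/tau); O(dt) accurate, kept free of the package's
    per-segment closed form.
    """
    # piecewise-constant rate on the dense grid
    edges, rates = [0.0], []
    for seg in timeline.segments:
        edges.append(edges[-1] + seg.duration)
        rates.append(max(seg.speed - cs, 0.0))
    results = []
    for t in np.atleast_1d(t_eval):
        u = np.arange(0.0, t, dt)
        rate_u = np.zeros_like(u)
        for (a, b), r in zip(zip(edges[:-1], edges[1:]), rates):
            rate_u[(u >= a) & (u < b)] = r
        s = np.sum(rate_u * np.exp(-(t - u) / tau) * dt)
        results.append(d_prime - s)
    return np.array(results)


class TestBuildTimeline:
    def test_two_lap_plan_matches_hand_arithmetic(self):
        plan = SessionPlan(work_speed=1.42, lap_distance=50, work_relief_ratio=2)
        tl = build_timeline(plan, n_laps=2)
        kinds = [s.kind for s in tl.segments]
        assert kinds == ["work", "rest", "work", "rest"]
        assert tl.segments[0].duration == pytest.approx(50 / 1.42)  # ~35.2 s
        assert tl.segments[1].duration == pytest.approx(50 / 1.42 / 2)  # ~17.6 s
        assert tl.segments[0].speed == 1.42
        assert tl.segments[1].speed == 0.0

    def test_ratio_four_rest_is_quarter_work(self):
        plan = SessionPlan(work_speed=1.42, work_relief_ratio=4)
        tl = build_timeline(plan, n_laps=1)
        assert tl.segments[1].duration == pytest.approx(tl.segments[0].duration / 4)

    def test_total_time_truncates_exactly(self):
        plan = SessionPlan(work_speed=1.25, work_relief_ratio=2)
        tl = build_timeline(plan, total_time=100.0)
        assert tl.total_duration == pytest.approx(100.0)

    def test_argument_validation(self):
        plan = SessionPlan(work_speed=1.42)
        with pytest.raises(ValueError):
            build_timeline(plan)
        with pytest.raises(ValueError):
            build_timeline(plan, n_laps=3, total_time=100.0)
        with pytest.raises(ValueError):
            build_timeline(plan, n_laps=0)


class TestTimelineFromLog:
    def _log(self, lap_times, rests, exhausted_last=True, lap_dist=50.0):
        rows = []
        for i, (lt, r) in enumerate(zip(lap_times, rests), start=1):
            rows.append(
                dict(swimmer_id="X", lap_index=i, lap_distance_m=lap_dist,
                     lap_time_s=lt, rest_after_s=r,
                     exhausted=int(exhausted_last and i == len(lap_times)))
            )
        return pd.DataFrame(rows)

    def test_constant_log_matches_planned_timeline(self):
        plan = SessionPlan(work_speed=1.25, work_relief_ratio=2)
        planned = build_timeline(plan, n_laps=3)
        w, r = plan.work_duration, plan.rest_duration
        observed = timeline_from_log(self._log([w] * 3, [r] * 3, exhausted_last=False))
        for a, b in zip(observed.segments, planned.segments):
            assert a.kind == b.kind
            assert a.duration == pytest.approx(b.duration)
            assert a.speed == pytest.approx(b.speed)

    def test_jittered_log_varies_lap_speeds(self):
        tl = timeline_from_log(self._log([35.0, 36.0, 34.0], [17.5] * 3))
        speeds = [s.speed for s in tl.segments if s.kind == "work"]
        assert len(set(np.round(speeds, 6))) == 3

    def test_duration_conservation_and_exhaustion_clock(self):
        tl = timeline_from_log(self._log([35.0, 36.0], [17.0, 17.0]))
        # rest after the exhausted final lap is discarded
        assert tl.total_duration == pytest.approx(35 + 17 + 36)
        assert tl.observed_exhaustion_time == pytest.approx(35 + 17 + 36)

    def test_nonpositive_lap_time_rejected_with_message(self):
        df = self._log([35.0, -1.0, 36.0], [17.0] * 3)
        with pytest.warns(UserWarning, match="rejected"):
            tl = timeline_from_log(df)
        assert sum(s.kind == "work" for s in tl.segments) == 2


class TestSimulateDbal:
    def test_sub_cs_timeline_expends_nothing(self):
        tl = SessionTimeline((Segment(1.0, 120.0, "work"),))
        traj = simulate_dbal(tl, cs=1.23, d_prime=33.69, tau=300.0)
        assert np.allclose(traj.d_bal, 33.69)
        assert traj.total_expended == 0.0
        assert traj.d_end == pytest.approx(33.69)

    def test_continuous_bout_infinite_tau_depletes_at_d_over_excess(self):
        # tau -> inf removes reconstitution: zero at D'/(s - CS) ~ 180 s
        s, cs, dp = 1.417, 1.23, 33.69
        t_zero = dp / (s - cs)
        tl = SessionTimeline((Segment(s, 200.0, "work"),))
        assert balance_at(tl, cs, dp, 1e12, t_zero) == pytest.approx(0.0, abs=1e-6)
        traj = simulate_dbal(tl, cs, dp, 1e12, dt=0.01)
        crossing = traj.times[np.argmax(traj.d_bal <= 0)]
        assert crossing == pytest.approx(t_zero, abs=0.02)

    def test_boundaries_match_dense_grid_oracle(self):
        # two 35 s work bouts at 1.42 m/s with 18 s passive rest
        tl = SessionTimeline(
            (
                Segment(1.42, 35.0, "work"),
                Segment(0.0, 18.0, "rest"),
                Segment(1.42, 35.0, "work"),
                Segment(0.0, 18.0, "rest"),
            )
        )
        cs, dp, tau = 1.23, 33.69, 80.0
        boundaries = np.cumsum([s.duration for s in tl.segments])
        expected = dense_grid_dbal(tl, cs, dp, tau, boundaries)
        for t, want in zip(boundaries, expected):
            assert balance_at(tl, cs, dp, tau, t) == pytest.approx(want, abs=0.01)

    def test_oracle_agreement_on_mixed_speed_timeline(self):
        tl = SessionTimeline(
            (
                Segment(1.5, 20.0, "work"),
                Segment(0.8, 10.0, "rest"),   # sub-CS active recovery
                Segment(1.35, 30.0, "work"),
                Segment(0.0, 12.0, "rest"),
                Segment(1.6, 15.0, "work"),
            )
        )
        cs, dp, tau = 1.23, 25.0, 120.0
        boundaries = np.cumsum([s.duration for s in tl.segments])
        expected = dense_grid_dbal(tl, cs, dp, tau, boundaries)
        got = [balance_at(tl, cs, dp, tau, t) for t in boundaries]
        assert np.allclose(got, expected, atol=0.01)

    def test_starts_at_d_prime_and_never_exceeds_it(self, severe_plan):
        tl = build_timeline(severe_plan, n_laps=6)
        traj = simulate_dbal(tl, 1.23, 33.69, 380.0)
        assert traj.d_bal[0] == pytest.approx(33.69)
        assert np.all(traj.d_bal <= 33.69 + 1e-9)

    def test_small_tau_rest_restores_balance(self):
        # tau -> 0+: any positive rest returns the balance to D' within e^{-rest/tau}
        tl = SessionTimeline(
            (Segment(1.42, 35.0, "work"), Segment(0.0, 18.0, "rest"))
        )
        traj = simulate_dbal(tl, 1.23, 33.69, tau=1.0)
        assert traj.d_end == pytest.approx(33.69, abs=1e-6)

    def test_grid_refinement_stability_of_d_low(self, severe_plan):
        tl = build_timeline(severe_plan, n_laps=8)
        coarse = simulate_dbal(tl, 1.23, 33.69, 380.0, dt=0.02)
        fine = simulate_dbal(tl, 1.23, 33.69, 380.0, dt=0.01)
        assert abs(coarse.d_low - fine.d_low) < 0.01

    def test_domain_errors(self, severe_plan):
        tl = build_timeline(severe_plan, n_laps=1)
        with pytest.raises(ValueError):
            simulate_dbal(tl, 1.23, 33.69, tau=-1.0)
        with pytest.raises(ValueError):
            simulate_dbal(tl, 1.23, 33.69, tau=100.0, dt=0.0)
        with pytest.raises(ValueError):
            simulate_dbal(tl, 1.23, -5.0, tau=100.0)


class TestSummarize:
    def test_monotone_trajectory_has_d_low_at_end(self):
        tl = SessionTimeline((Segment(1.42, 100.0, "work"),))
        traj = simulate_dbal(tl, 1.23, 33.69, 400.0)
        d_end, d_low, _, _ = summarize(traj)
        assert d_low == pytest.approx(d_end)

    def test_expenditure_is_rate_times_time(self):
        tl = SessionTimeline(
            (
                Segment(1.417, 35.0, "work"),
                Segment(0.0, 18.0, "rest"),
                Segment(1.417, 35.0, "work"),
            )
        )
        traj = simulate_dbal(tl, 1.23, 33.69, 80.0)
        assert traj.total_expended == pytest.approx(2 * 35 * 0.187, abs=1e-9)

    def test_reconstitution_bookkeeping_identity(self, severe_plan):
        tl = build_timeline(severe_plan, n_laps=6)
        traj = simulate_dbal(tl, 1.23, 33.69, 380.0)
        assert traj.total_reconstituted == pytest.approx(
            traj.total_expended - (traj.d_prime - traj.d_end), abs=1e-9
        )
        assert traj.d_low <= traj.d_end + 1e-12
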