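"""D'-balance (D'_BAL) kinetics over interval-session timelines.

The model tracks the distance capacity above critical speed, D', during
intermittent exercise.  Whenever the swimming speed s(u) exceeds CS, D' is
expended at rate ``s(u) - CS`` (m per s); every expended increment is then
reconstituted exponentially with a single time constant tau, at all later
times, so the balance at time t is the convolution

    D'_bal(t) = D' - integral_0^t max(s(u) - CS, 0) * exp(-(t - u)/tau) du.

Timelines are piecewise constant (work laps and rest intervals), so the
convolution has an exact per-segment closed form: writing
S(t) for the integral above, a segment of constant excess rate r starting
at time a with state S(a) gives

    S(t) = S(a) + (r*tau - S(a)) * (1 - exp(-(t - a)/tau)).

All evaluation below uses this recursion; a dt grid is used only for
reporting the trajectory and locating its minimum (D'_LOW).

The session time constant tau is not assumed: it is solved per session by
bisection so that the modelled balance is exactly zero at the observed
exhaustion time (D'_END = 0), and can then be transferred to another
session to predict its time to exhaustion (TTE).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "WORK",
    "REST",
    "Segment",
    "SessionPlan",
    "SessionTimeline",
    "BalanceTrajectory",
    "TauSolveResult",
    "TtePrediction",
    "build_timeline",
    "timeline_from_log",
    "simulate_dbal",
    "summarize",
    "balance_at",
    "solve_tau",
    "predict_tte",
    "estimate_tau_skiba",
]

WORK = "work"
REST = "rest"


@dataclass(frozen=True)
class Segment:
    """A constant-speed stretch of a session: (speed m/s, duration s, kind)."""

    speed: float
    duration: float
    kind: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        if self.speed < 0:
            raise ValueError(f"segment speed must be >= 0, got {self.speed}")
        if self.kind not in (WORK, REST):
            raise ValueError(f"segment kind must be {WORK!r} or {REST!r}")


@dataclass(frozen=True)
class SessionPlan:
    """Prescription of an interval session.

    Work laps of ``lap_distance`` m at ``work_speed`` m/s are interspersed
    with recovery intervals whose duration is the work duration divided by
    ``work_relief_ratio`` (2:1 and 4:1 in the sessions modelled here).
    ``recovery_speed`` of 0 denotes passive rest.
    """

    work_speed: float
    lap_distance: float = 50.0
    work_relief_ratio: float = 2.0
    recovery_speed: float = 0.0

    def __post_init__(self) -> None:
        if self.work_speed <= 0:
            raise ValueError("work_speed must be > 0")
        if self.lap_distance <= 0:
            raise ValueError("lap_distance must be > 0")
        if self.work_relief_ratio <= 0:
            raise ValueError("work_relief_ratio must be > 0")
        if self.recovery_speed < 0:
            raise ValueError("recovery_speed must be >= 0")

    @property
    def work_duration(self) -> float:
        """Seconds to swim one lap at the prescribed speed."""
        return self.lap_distance / self.work_speed

    @property
    def rest_duration(self) -> float:
        """Seconds of relief per lap under the work/relief ratio."""
        return self.work_duration / self.work_relief_ratio

    def cycle(self) -> tuple[Segment, Segment]:
        """One work+rest cycle of the plan."""
        return (
            Segment(self.work_speed, self.work_duration, WORK),
            Segment(self.recovery_speed, self.rest_duration, REST),
        )


@dataclass(frozen=True)
class SessionTimeline:
    """Ordered constant-speed segments with an optional exhaustion time."""

    segments: tuple[Segment, ...]
    observed_exhaustion_time: float | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("timeline must contain at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.observed_exhaustion_time is not None:
            if self.observed_exhaustion_time <= 0:
                raise ValueError("observed_exhaustion_time must be > 0")
            if self.observed_exhaustion_time > self.total_duration + 1e-9:
                raise ValueError(
                    "observed_exhaustion_time exceeds timeline duration "
                    f"({self.observed_exhaustion_time:.2f} > "
                    f"{self.total_duration:.2f} s)"
                )

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))


@dataclass
class BalanceTrajectory:
    """D'_BAL over a reporting grid plus its scalar summary.

    ``d_end`` is the balance at the observed exhaustion time when one is
    present, else at the end of the timeline.  ``d_low`` (D'_LOW) is the
    minimum over the grid; it can be negative because no floor is applied.
    ``total_reconstituted`` satisfies the book-keeping identity
    ``total_expended - (D' - d_end)``.
    """

    times: np.ndarray
    d_bal: np.ndarray
    d_end: float
    d_low: float
    total_expended: float
    total_reconstituted: float
    d_prime: float
    cs: float
    tau: float


@dataclass(frozen=True)
class TauSolveResult:
    """Outcome of the iterative tau determination at observed exhaustion."""

    tau: float
    d_end_residual: float
    iterations: int
    converged: bool
    bracket: tuple[float, float]
    message: str = ""


@dataclass(frozen=True)
class TtePrediction:
    """Predicted time to exhaustion (work plus recovery clock time)."""

    tte: float | None
    reached_zero: bool
    cap: float


def build_timeline(
    plan: SessionPlan,
    n_laps: int | None = None,
    total_time: float | None = None,
) -> SessionTimeline:
    """Lay out a planned session as alternating work/rest segments.

    Exactly one of ``n_laps`` / ``total_time`` must be given.  With
    ``total_time`` the cycle is repeated and the last segment truncated so
    the timeline lasts exactly that long.
    """
    if (n_laps is None) == (total_time is None):
        raise ValueError("give exactly one of n_laps or total_time")
    work, rest = plan.cycle()
    segments: list[Segment] = []
    if n_laps is not None:
        if n_laps < 1:
            raise ValueError("n_laps must be >= 1 (empty timeline)")
        for _ in range(n_laps):
            segments.extend((work, rest))
    else:
        if total_time <= 0:
            raise ValueError("total_time must be > 0 (empty timeline)")
        elapsed = 0.0
        while elapsed < total_time - 1e-12:
            for seg in (work, rest):
                remaining = total_time - elapsed
                if remaining <= 1e-12:
                    break
                dur = min(seg.duration, remaining)
                segments.append(Segment(seg.speed, dur, seg.kind))
                elapsed += dur
    return SessionTimeline(tuple(segments))


def timeline_from_log(
    lap_records: "Sequence[Mapping] | 'pd.DataFrame'",
) -> SessionTimeline:
    """Reconstruct a timeline from observed per-lap records.

    Each record carries ``lap_distance_m``, ``lap_time_s``, ``rest_after_s``
    and an ``exhausted`` flag (truthy on the final lap when the session
    ended in task failure).  Per-lap speeds are ``distance / time``, so
    observed lap-to-lap variability is preserved — this is what lets the
    modelled minimum D'_LOW fall below zero once tau is solved to a zero
    balance at exhaustion.  Records with non-positive lap times are dropped
    with a warning.  The rest following an exhausted lap is ignored and the
    exhaustion time is the cumulative session clock at the end of that lap.
    """
    if hasattr(lap_records, "to_dict"):  # pandas DataFrame
        lap_records = lap_records.to_dict("records")
    segments: list[Segment] = []
    elapsed = 0.0
    exhaustion: float | None = None
    records = list(lap_records)
    for i, rec in enumerate(records):
        lap_time = float(rec["lap_time_s"])
        if lap_time <= 0:
            warnings.warn(
                f"lap record {i} rejected: non-positive lap time {lap_time}",
                stacklevel=2,
            )
            continue
        speed = float(rec["lap_distance_m"]) / lap_time
        segments.append(Segment(speed, lap_time, WORK))
        elapsed += lap_time
        if bool(rec.get("exhausted", False)):
            exhaustion = elapsed
            break
        rest = float(rec.get("rest_after_s", 0.0))
        if rest > 0:
            segments.append(Segment(0.0, rest, REST))
            elapsed += rest
    if not segments:
        raise ValueError("no valid lap records in session log")
    return SessionTimeline(tuple(segments), observed_exhaustion_time=exhaustion)


def _excess_rate(speed: float, cs: float) -> float:
    # expenditure applies whenever speed exceeds CS, work or "rest" alike;
    # sub-CS segments expend nothing (and reconstitution needs no rate term)
    return max(speed - cs, 0.0)


def _step_state(s: float, rate: float, tau: float, dt: float) -> float:
    """Advance the convolved-expenditure state S across dt at constant rate."""
    # S(t) = S_a + (r*tau - S_a)(1 - e^{-dt/tau}); -expm1 keeps precision
    # for tau >> dt (the tau -> infinity no-recovery limit)
    return s - (rate * tau - s) * math.expm1(-dt / tau)


def balance_at(
    timeline: SessionTimeline,
    cs: float,
    d_prime: float,
    tau: float,
    t: float,
) -> float:
    """Exact D'_BAL at clock time ``t`` via the per-segment recursion."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    s_state = 0.0
    elapsed = 0.0
    for seg in timeline.segments:
        rate = _excess_rate(seg.speed, cs)
        if t <= elapsed + seg.duration:
            s_state = _step_state(s_state, rate, tau, t - elapsed)
            return d_prime - s_state
        s_state = _step_state(s_state, rate, tau, seg.duration)
        elapsed += seg.duration
    # beyond the timeline: pure decay of whatever is outstanding
    return d_prime - s_state * math.exp(-(t - elapsed) / tau)


def simulate_dbal(
    timeline: SessionTimeline,
    cs: float,
    d_prime: float,
    tau: float,
    dt: float = 0.01,
) -> BalanceTrajectory:
    """Evaluate the D'_BAL trajectory over the session.

    Segment boundaries are handled by the exact recursion; within each
    segment the closed form is evaluated on a dt grid (reporting and
    minimum search only — refining dt does not change boundary values).
    When the timeline records an observed exhaustion time the trajectory,
    totals and d_end are truncated there.
    """
    if d_prime <= 0:
        raise ValueError("d_prime must be > 0")
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be > 0")

    t_end = timeline.observed_exhaustion_time
    if t_end is None:
        t_end = timeline.total_duration

    grids: list[np.ndarray] = [np.array([0.0])]
    vals: list[np.ndarray] = [np.array([d_prime])]
    s_state = 0.0
    elapsed = 0.0
    total_expended = 0.0
    for seg in timeline.segments:
        if elapsed >= t_end:
            break
        dur = min(seg.duration, t_end - elapsed)
        rate = _excess_rate(seg.speed, cs)
        local = np.arange(dt, dur, dt)
        local = np.append(local, dur)
        # closed form within the segment, vectorised over the local grid
        s_vals = s_state - (rate * tau - s_state) * np.expm1(-local / tau)
        grids.append(elapsed + local)
        vals.append(d_prime - s_vals)
        s_state = float(s_vals[-1])
        total_expended += rate * dur
        elapsed += dur

    times = np.concatenate(grids)
    d_bal = np.concatenate(vals)
    d_endv = float(d_bal[-1])
    d_low = float(d_bal.min())
    total_recon = total_expended - (d_prime - d_endv)
    return BalanceTrajectory(
        times=times,
        d_bal=d_bal,
        d_end=d_endv,
        d_low=d_low,
        total_expended=total_expended,
        total_reconstituted=total_recon,
        d_prime=d_prime,
        cs=cs,
        tau=tau,
    )


def summarize(trajectory: BalanceTrajectory) -> tuple[float, float, float, float]:
    """(d_end, d_low, total_expended, total_reconstituted) of a trajectory."""
    return (
        trajectory.d_end,
        trajectory.d_low,
        trajectory.total_expended,
        trajectory.total_reconstituted,
    )


def solve_tau(
    timeline: SessionTimeline,
    cs: float,
    d_prime: float,
    bracket: tuple[float, float] = (0.1, 1e6),
    tolerance: float = 1e-3,
    max_iterations: int = 200,
) -> TauSolveResult:
    """Solve for the tau at which D'_BAL is zero at observed exhaustion.

    The residual d_end(tau) is monotone non-increasing in tau (slower
    reconstitution can only lower the balance), so plain bisection is used.
    Non-bracketing residuals are reported as non-converged results, not
    raised: a residual already negative at the fast-recovery end means the
    observed exhaustion came before even a loss-free session could deplete
    D'; a residual still positive at the slow end means the session never
    depletes (e.g. a recovery-free continuous bout, where the convolution
    keeps d_end > 0 for every finite tau).
    """
    if timeline.observed_exhaustion_time is None:
        raise ValueError("timeline has no observed exhaustion time")
    if d_prime <= 0:
        raise ValueError("d_prime must be > 0")
    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError(f"bad tau bracket {bracket}")
    t_exh = timeline.observed_exhaustion_time

    def residual(tau: float) -> float:
        return balance_at(timeline, cs, d_prime, tau, t_exh)

    f_lo = residual(lo)
    f_hi = residual(hi)
    if abs(f_lo) <= tolerance:
        return TauSolveResult(lo, f_lo, 0, True, bracket)
    if abs(f_hi) <= tolerance:
        return TauSolveResult(hi, f_hi, 0, True, bracket)
    if f_lo < 0:
        return TauSolveResult(
            lo, f_lo, 0, False, bracket,
            "d_end < 0 even at fastest-recovery bracket end: exhaustion "
            "observed before a loss-free session could deplete D'",
        )
    if f_hi > 0:
        return TauSolveResult(
            hi, f_hi, 0, False, bracket,
            "d_end > 0 even at slowest-recovery bracket end: session does "
            "not deplete D' at the observed exhaustion time",
        )

    tau_mid = 0.5 * (lo + hi)
    f_mid = residual(tau_mid)
    iters = 0
    while abs(f_mid) > tolerance and iters < max_iterations:
        if f_mid > 0:
            lo = tau_mid
        else:
            hi = tau_mid
        tau_mid = 0.5 * (lo + hi)
        f_mid = residual(tau_mid)
        iters += 1
    return TauSolveResult(
        tau_mid, f_mid, iters, abs(f_mid) <= tolerance, bracket,
        "" if abs(f_mid) <= tolerance else "max iterations reached",
    )


def _iter_cycle(source: SessionPlan | SessionTimeline) -> Iterable[Segment]:
    """Endless segment stream: a plan's cycle, or a timeline repeated."""
    if isinstance(source, SessionPlan):
        segs = source.cycle()
    else:
        segs = source.segments
    while True:
        yield from segs


def predict_tte(
    source: SessionPlan | SessionTimeline,
    cs: float,
    d_prime: float,
    tau: float,
    cap: float = 7200.0,
) -> TtePrediction:
    """Predict time to exhaustion under a given tau.

    The work/rest cycle is extended until D'_BAL first reaches zero inside
    a work segment (rest segments cannot terminate a session); the TTE is
    the session clock — work plus recovery time — at that crossing, located
    analytically within the segment.  If the balance never reaches zero by
    ``cap`` seconds (per-cycle reconstitution matching expenditure), the
    prediction is reported as not reached.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if cap <= 0:
        raise ValueError("cap must be > 0")
    s_state = 0.0
    elapsed = 0.0
    for seg in _iter_cycle(source):
        rate = _excess_rate(seg.speed, cs)
        if seg.kind == WORK and rate > 0:
            if s_state >= d_prime:
                return TtePrediction(elapsed, True, cap)
            # S rises toward rate*tau; a zero crossing inside the segment
            # exists iff that asymptote exceeds D'
            if rate * tau > d_prime:
                # S(a+dt) = d_prime  =>  dt = -tau*log1p(-(D'-S)/(r*tau-S))
                x = (d_prime - s_state) / (rate * tau - s_state)
                dt_cross = -tau * math.log1p(-x)
                if dt_cross <= seg.duration:
                    t_cross = elapsed + dt_cross
                    if t_cross > cap:
                        return TtePrediction(None, False, cap)
                    return TtePrediction(t_cross, True, cap)
        s_state = _step_state(s_state, rate, tau, seg.duration)
        elapsed += seg.duration
        if elapsed >= cap:
            return TtePrediction(None, False, cap)
    raise RuntimeError("unreachable")  # pragma: no cover


def estimate_tau_skiba(d_cs: float) -> float:
    """Closed-form tau estimator from the cycling literature.

    ``tau = 546 * exp(-0.01 * D_cs) + 316`` where D_cs is the gap between
    recovery intensity and CS/CP (in the original calibration, watts below
    CP).  Provided for comparison with the iteratively solved tau; it is
    not used by the solver, and its cycling-derived constants transfer
    poorly to swimming.
    """
    if d_cs < 0:
        raise ValueError("d_cs must be >= 0")
    return 546.0 * math.exp(-0.01 * d_cs) + 316.0
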