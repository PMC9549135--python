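"""End-to-end report stages tying the model layers together.

Each stage consumes/produces plain pandas tables in the package's CSV
dialects, so the whole pipeline can be driven from Python or from the
thin CLI wrapper: fit CS/D' per swimmer, solve the session tau at observed
exhaustion, cross-predict TTE/D'_END with the taus swapped between
sessions, and summarise agreement.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .agreement import PairedSample, bland_altman, exclude_subjects
from .config import AnalysisConfig
from .cs_model import CsFit, fit_distance_time, target_speed
from .dbal import (
    SessionPlan,
    predict_tte,
    simulate_dbal,
    solve_tau,
    timeline_from_log,
)
from .io import trials_for_swimmer

log = logging.getLogger("dprimebal")


def fit_cs_report(trials_df: pd.DataFrame, target_tte: float = 180.0) -> pd.DataFrame:
    """Per-swimmer CS/D' fits with diagnostics and the target speed.

    Swimmers with fewer than two trials are skipped with a warning.
    ``target_speed_ms`` is the constant speed predicted to exhaust D' in
    ``target_tte`` seconds of continuous swimming.
    """
    rows = []
    for sid in trials_df.swimmer_id.unique():
        trials = trials_for_swimmer(trials_df, sid)
        if len(trials) < 2:
            log.warning("swimmer %s has %d trial(s); skipped", sid, len(trials))
            continue
        fit = fit_distance_time(trials)
        rows.append(
            {
                "swimmer_id": sid,
                "cs_ms": fit.cs,
                "d_prime_m": fit.d_prime,
                "r_squared": fit.r_squared,
                "see_cs_ms": fit.see_cs,
                "see_cs_pct": fit.see_cs_percent,
                "see_d_prime_m": fit.see_d_prime,
                "see_d_prime_pct": fit.see_d_prime_percent,
                "n_trials": fit.n_trials,
                "negative_d_prime": fit.negative_d_prime,
                "target_speed_ms": target_speed(fit, target_tte),
            }
        )
    return pd.DataFrame(rows)


def fits_from_report(report: pd.DataFrame) -> dict[str, CsFit]:
    """Rehydrate CsFit objects from a fit_cs_report table."""
    return {
        r.swimmer_id: CsFit(
            cs=r.cs_ms,
            d_prime=r.d_prime_m,
            r_squared=r.r_squared,
            see_cs=r.see_cs_ms,
            see_d_prime=r.see_d_prime_m,
            n_trials=int(r.n_trials),
            negative_d_prime=bool(r.negative_d_prime),
        )
        for r in report.itertuples()
    }


def plan_from_log(swimmer_log: pd.DataFrame) -> SessionPlan:
    """Recover the nominal session prescription from an observed log.

    Uses the completed (non-exhausted) laps: lap distance and speed are
    medians, and the work/relief ratio the median lap-time/rest ratio.
    """
    full = swimmer_log[swimmer_log.exhausted == 0]
    if full.empty:
        full = swimmer_log
    lap_distance = float(full.lap_distance_m.median())
    speed = float((full.lap_distance_m / full.lap_time_s).median())
    rests = full.rest_after_s[full.rest_after_s > 0]
    if rests.empty:
        ratio = 1e9  # effectively continuous
    else:
        ratio = float((full.lap_time_s[rests.index] / rests).median())
    return SessionPlan(
        work_speed=speed, lap_distance=lap_distance, work_relief_ratio=ratio
    )


def solve_tau_report(
    session_df: pd.DataFrame,
    cs_fits: Mapping[str, CsFit],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Solve tau at observed exhaustion per swimmer, with balance summary.

    Non-converged solves (residuals that do not bracket zero) are ordinary
    result rows, not errors.  A swimmer whose log carries no exhausted
    flag cannot be solved and raises.
    """
    config = config or AnalysisConfig()
    rows = []
    for sid in session_df.swimmer_id.unique():
        if sid not in cs_fits:
            log.warning("no CS fit for swimmer %s; skipped", sid)
            continue
        fit = cs_fits[sid]
        timeline = timeline_from_log(session_df[session_df.swimmer_id == sid])
        if timeline.observed_exhaustion_time is None:
            raise ValueError(f"session log for swimmer {sid} has no exhausted flag")
        res = solve_tau(
            timeline,
            fit.cs,
            fit.d_prime,
            bracket=config.tau_bracket,
            tolerance=config.tau_tolerance,
        )
        traj = simulate_dbal(timeline, fit.cs, fit.d_prime, res.tau, dt=config.dt)
        rows.append(
            {
                "swimmer_id": sid,
                "tau_s": res.tau,
                "d_end_residual_m": res.d_end_residual,
                "converged": res.converged,
                "iterations": res.iterations,
                "message": res.message,
                "exhaustion_time_s": timeline.observed_exhaustion_time,
                "d_end_m": traj.d_end,
                "d_low_m": traj.d_low,
                "total_expended_m": traj.total_expended,
                "total_reconstituted_m": traj.total_reconstituted,
            }
        )
    return pd.DataFrame(rows)


def cross_predict_report(
    session_a: pd.DataFrame,
    session_b: pd.DataFrame,
    cs_fits: Mapping[str, CsFit],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Swap taus between two sessions and predict TTE and D'_END.

    For each swimmer, tau solved in session A drives a prediction of
    session B (TTE from the session's nominal plan; D'_END by re-running
    the observed timeline at the swapped tau) and vice versa.  Swimmers
    whose tau did not converge in the source session are skipped with a
    warning; predictions that never reach zero by the cap are reported
    with ``reached_zero = False``.
    """
    config = config or AnalysisConfig()
    tau_a = solve_tau_report(session_a, cs_fits, config).set_index("swimmer_id")
    tau_b = solve_tau_report(session_b, cs_fits, config).set_index("swimmer_id")
    rows = []
    for target_name, target_df, source in (
        ("A", session_a, tau_b),
        ("B", session_b, tau_a),
    ):
        for sid in target_df.swimmer_id.unique():
            if sid not in source.index or sid not in cs_fits:
                continue
            src = source.loc[sid]
            if not src.converged:
                log.warning(
                    "swimmer %s: source tau not converged; row skipped", sid
                )
                continue
            fit = cs_fits[sid]
            swimmer_log = target_df[target_df.swimmer_id == sid]
            timeline = timeline_from_log(swimmer_log)
            plan = plan_from_log(swimmer_log)
            pred = predict_tte(
                plan, fit.cs, fit.d_prime, src.tau_s, cap=config.tte_cap
            )
            traj = simulate_dbal(
                timeline, fit.cs, fit.d_prime, src.tau_s, dt=config.dt
            )
            rows.append(
                {
                    "session": target_name,
                    "swimmer_id": sid,
                    "tau_applied_s": src.tau_s,
                    "actual_tte_s": timeline.observed_exhaustion_time,
                    "predicted_tte_s": pred.tte,
                    "reached_zero": pred.reached_zero,
                    "predicted_d_end_m": traj.d_end,
                }
            )
    return pd.DataFrame(rows)


def agreement_report(
    sample: PairedSample, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Bias/LoA/CV/t summary, with and without the configured exclusions."""
    config = config or AnalysisConfig()
    variants = [("all", sample)]
    if config.exclusions:
        variants.append(
            ("excluded:" + ",".join(map(str, config.exclusions)),
             exclude_subjects(sample, config.exclusions))
        )
    rows = []
    for name, samp in variants:
        res = bland_altman(samp, k=config.loa_k)
        rows.append(
            {
                "subset": name,
                "n": res.n,
                "bias": res.bias,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
                "cv_percent": res.cv_percent,
                "t_stat": res.t_stat,
                "df": res.df,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "units": res.units,
            }
        )
    return pd.DataFrame(rows)
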