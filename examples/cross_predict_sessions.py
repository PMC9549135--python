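"""Swap tau between two interval sessions and test its transferability.

Generates a small cohort, simulates each swimmer's 2:1 and 4:1 sessions,
solves tau in each, then applies the 2:1 tau to the 4:1 session (and
vice versa) to predict time to exhaustion.  If tau were a stable trait
of a swimmer-plus-recovery-intensity, predicted and actual TTE would
agree; the within-subject CV quantifies how far they do.
"""

import warnings

import pandas as pd

from dprimebal import CohortSpec, PairedSample, SessionPlan, generate_cohort, within_subject_cv
from dprimebal import pipeline
from dprimebal.synthetic import simulate_session, simulate_time_trials

warnings.filterwarnings("ignore")

cohort = generate_cohort(CohortSpec(n=8, master_seed=3))
trials, logs = [], {2.0: [], 4.0: []}
for sw in cohort:
    for tr in simulate_time_trials(sw):
        trials.append({"swimmer_id": sw.id, "distance_m": tr.distance, "time_s": tr.time})
    speed = sw.cs_true + sw.d_prime_true / 180.0
    for ratio in (2.0, 4.0):
        plan = SessionPlan(work_speed=speed, work_relief_ratio=ratio)
        logs[ratio].append(simulate_session(sw, plan, exhaustion_slack_sd=1.5))

fits = pipeline.fits_from_report(pipeline.fit_cs_report(pd.DataFrame(trials)))
log2 = pd.concat(logs[2.0]); log4 = pd.concat(logs[4.0])
ex = set(log2[log2.exhausted == 1].swimmer_id) & set(log4[log4.exhausted == 1].swimmer_id)
report = pipeline.cross_predict_report(
    log2[log2.swimmer_id.isin(ex)], log4[log4.swimmer_id.isin(ex)], fits
)

print(report[["session", "swimmer_id", "tau_applied_s", "actual_tte_s",
              "predicted_tte_s", "reached_zero"]].round(1).to_string(index=False))
ok = report[report.reached_zero & report.predicted_tte_s.notna()]
if len(ok) >= 2:
    sample = PairedSample(
        ids=tuple(zip(ok.session, ok.swimmer_id)),
        a=tuple(ok.actual_tte_s), b=tuple(ok.predicted_tte_s), units="s",
    )
    print(f"\nwithin-subject CV of actual vs predicted TTE: "
          f"{within_subject_cv(sample):.0f}%")
# Rows with reached_zero = False are sessions the transferred tau deems
# sustainable forever — prediction is impossible there.
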