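"""Agreement statistics on the bundled per-swimmer session-tau table.

Asks whether tau solved from the 2:1 session agrees with tau solved
from the 4:1 session across thirteen swimmers: paired t with CI,
Bland-Altman bias and limits of agreement, and the within-subject CV —
with a reanalysis excluding the extreme outlier subject.
"""

from dprimebal import bland_altman, exclude_subjects, paired_t_ci, within_subject_cv
from dprimebal.reference import OUTLIER_SUBJECT, tau_paired_sample

sample = tau_paired_sample()
t, df, ci = paired_t_ci(sample)
res = bland_altman(sample)

print(f"paired t({df}) = {t:.2f}, 95% CI ({ci[0]:.0f}, {ci[1]:.0f}) s")
print(f"bias = {res.bias:.1f} s, LoA ({res.loa_low:.0f}, {res.loa_high:.0f}) s")
print(f"within-subject CV, all 13 swimmers: {within_subject_cv(sample):.0f}%")

reduced = exclude_subjects(sample, [OUTLIER_SUBJECT])
print(f"within-subject CV, excluding subject {OUTLIER_SUBJECT}: "
      f"{within_subject_cv(reduced):.1f}%")
# A CV of this size means tau is anything but constant between sessions
# that differ only in relief duration.
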