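"""Fit CS and D' from maximal time trials and derive a training speed.

Uses the bundled group-mean race times of a trained swimmer cohort
(200-800 m).  The slope of distance on time is the critical speed CS,
the intercept the supra-CS distance capacity D'; Speed = CS + D'/t then
gives the constant pace predicted to exhaust D' in a chosen time.
"""

from dprimebal import TimeTrial, fit_distance_time, percent_of_pace, target_speed
from dprimebal.reference import GROUP_MEAN_TRIALS

fit = fit_distance_time(GROUP_MEAN_TRIALS)
print(f"CS       = {fit.cs:.3f} m/s  (SE {fit.see_cs:.4f}, {fit.see_cs_percent:.1f}%)")
print(f"D'       = {fit.d_prime:.2f} m   (SE {fit.see_d_prime:.2f}, {fit.see_d_prime_percent:.1f}%)")
print(f"R^2      = {fit.r_squared:.4f}  over {fit.n_trials} trials")

speed = target_speed(fit, 180.0)
pct = percent_of_pace(speed, TimeTrial(400, 297))
print(f"target speed for exhaustion in 180 s: {speed:.3f} m/s "
      f"({pct:.1f}% of the 400 m pace)")
print(f"a 50 m lap at that speed takes {50 / speed:.1f} s")
# CS is the heavy/severe boundary; swimming above it spends the finite
# D' reserve, and the target speed spends exactly D' over 180 s.
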