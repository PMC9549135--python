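"""Track D'_BAL through a 50 m interval session with 2:1 work/relief.

Builds the planned timeline (laps at the 180-s target speed, passive
rests of half the lap duration), evaluates the balance convolution with
a reconstitution time constant tau, and reports the summary quantities.
"""

from dprimebal import SessionPlan, build_timeline, simulate_dbal, summarize

cs, d_prime, tau = 1.23, 33.69, 380.0
speed = cs + d_prime / 180.0

plan = SessionPlan(work_speed=speed, lap_distance=50.0, work_relief_ratio=2.0)
print(f"plan: {plan.work_duration:.1f} s laps at {speed:.3f} m/s, "
      f"{plan.rest_duration:.1f} s passive rests")

timeline = build_timeline(plan, n_laps=10)
traj = simulate_dbal(timeline, cs, d_prime, tau, dt=0.01)
d_end, d_low, expended, reconstituted = summarize(traj)

print(f"after 10 laps ({timeline.total_duration:.0f} s):")
print(f"  D'_END              = {d_end:7.2f} m   (balance remaining)")
print(f"  D'_LOW              = {d_low:7.2f} m   (session minimum)")
print(f"  total D' expended   = {expended:7.2f} m")
print(f"  total reconstituted = {reconstituted:7.2f} m")
# Expenditure per lap exceeds what each rest restores, so the balance
# ratchets downward; exhaustion is predicted where it would reach zero.
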