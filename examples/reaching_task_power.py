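"""Reaching-task metrics and the design-stage sample-size computation.

Shows the single-pellet reaching task readouts (success/fail rate,
intra-session learning) and the balanced one-way ANOVA power calculation
that sized the study.
"""

import ratclas as rc

session = rc.SessionCounts(attempts=55, successes=20, fails=30, drop_ins=5)
sr, fr = rc.success_fail_rates(session)
print(f"session: {session.attempts} attempts, SR {sr:.1%}, FR {fr:.1%} "
      f"(drop-ins excluded from both numerators)")

change = rc.intra_session_change(successes_first_bin=4, successes_last_bin=8)
print(f"intra-session change log2(8/4) = {change:+.1f} "
      f"(+1 means twice the successes of the first bin)")

excluded = rc.apply_exclusion_rule({2: 0.05, 3: 0.12, 4: 0.09})
print(f"exclusion rule (SR < 10% on every day from day 2): exclude = {excluded}")

n = rc.anova_sample_size(group_means=[15.0, 0.0, -10.0], within_sd=15.0,
                         alpha=0.05, power=0.80)
power = rc.anova_power(n, [15.0, 0.0, -10.0], 15.0)
print(f"ANOVA sample size for expected delta changes +15/0/-10 % (SD 15%): "
      f"n = {n} per group (power {power:.3f} at alpha 0.05)")
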