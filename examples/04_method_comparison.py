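"""End-to-end synthetic study: a cohort measured with both protocols.

Each subject is acquired with the fixed-range and the adaptive protocol,
analysed, and the cohort compared: moving distance (pulse depth proxy)
mean +- SD per method, a paired t-test on the per-subject differences, and
the correlation between the two methods' CFS values.
"""

from pulsedepth import simulate_method_comparison

report, analyses = simulate_method_comparison(n=8, seed=2)

print(f"n = {report.n} subjects, both protocols each")
print(f"moving distance, fixed   : {report.move_existing_mean:.3f} "
      f"+- {report.move_existing_sd:.3f} mm")
print(f"moving distance, adaptive: {report.move_proposed_mean:.3f} "
      f"+- {report.move_proposed_sd:.3f} mm")
print(f"paired t-test: t = {report.t_stat:.2f}, df = {report.df}, "
      f"p = {report.p_value:.2e}")
print(f"Pearson r between CFS columns: {report.cfs_pearson_r:.3f}")
print(f"discordant floating/sinking calls: {report.discordant_count} "
      f"({report.discordant_subjects})")
print("The adaptive protocol travels farther because it follows each")
print("subject's own perceptible range instead of a fixed 40-240 mmHg window.")
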