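"""Recompute the reference study's summary statistics from the packaged
20-subject results table.

The packaged table holds each subject's BMI, step1-step5 motor travel, CFS
and floating/sinking call under both protocols.  All summary numbers are
recomputed here with the package's own statistical kernels.
"""

from pulsedepth import classify_floating_sinking, load_table1
from pulsedepth.cohort_stats import compare_table1

rep = compare_table1()
df = load_table1()

print(f"moving distance, fixed   : {rep.move_existing_mean:.3f} "
      f"+- {rep.move_existing_sd:.3f} mm")
print(f"moving distance, adaptive: {rep.move_proposed_mean:.3f} "
      f"+- {rep.move_proposed_sd:.3f} mm")
print(f"paired t-test: t = {rep.t_stat:.3f}, df = {rep.df}, p = {rep.p_value:.4f}")
print(f"Pearson r between CFS columns: {rep.cfs_pearson_r:.3f}")
print(f"discordant subjects: {rep.discordant_subjects} "
      f"(all {rep.overweight_count} with BMI >= 25)")

relabelled = [classify_floating_sinking(v) for v in df.cfs_existing] + [
    classify_floating_sinking(v) for v in df.cfs_proposed
]
printed = [s.lower() for s in df.label_existing] + [s.lower() for s in df.label_proposed]
n_ok = sum(a == b for a, b in zip(relabelled, printed))
print(f"threshold rule (CFS >= 5 -> sinking) reproduces {n_ok}/40 printed labels")
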