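"""Simulate a full developmental cohort and run the group analysis.

123 synthetic participants in five age groups (5, 7, 9, 11 years, adult)
each complete the equivalent-noise and motion-coherence tasks at two
speeds.  Internal noise falls with age (faster at 6 deg/s), sampling
rises, lapse rate falls.  The analysis pipeline screens catch trials,
lapse-corrects, decomposes, fits log-log developmental trajectories and
runs the hierarchical regression on coherence thresholds.
"""

import numpy as np

from equinoise import CohortConfig, analyze, simulate

ds = simulate(CohortConfig(seed=42))
print(f"simulated {ds.config.n_participants} participants, {len(ds.trials)} trials")

report = analyze(ds)
inc = report.screened.included
print(f"excluded by catch screen: {len(report.excluded_participants)}; "
      f"outlier rows removed: {int((~report.screened.data['included']).sum())}")

print("\nrecovered group means (sigma_int deg / n_samp / coherence %):")
g = inc.groupby(["age_group", "speed"])
for grp in ("5y", "7y", "9y", "11y", "adult"):
    row = []
    for sp in (1.5, 6.0):
        row.append(f"{g['sigma_int'].mean().loc[(grp, sp)]:5.2f} / "
                   f"{g['n_samp'].mean().loc[(grp, sp)]:4.2f} / "
                   f"{100 * g['coherence_threshold'].mean().loc[(grp, sp)]:4.1f}%")
    print(f"  {grp:>5}:  slow {row[0]}   fast {row[1]}")

traj = report.trajectories["sigma_int"]
print("\ninternal-noise trajectories (log-log slopes):")
for _, r in traj.per_speed.iterrows():
    print(f"  {r['speed']} deg/s: slope {r['slope']:+.3f} (p = {r['slope_p']:.3g})")
print(f"  speed x log-age interaction: {traj.interaction_slope:+.3f} "
      f"(p = {traj.interaction_p:.3g}) -> steeper development at the fast speed")

print("\nhierarchical regression on log coherence thresholds:")
for sp, rep in report.regressions.items():
    dropped = {k: round(v, 3) for k, v in rep.excluded.items()}
    print(f"  {sp} deg/s: entered {list(rep.entered)}, excluded {dropped}")
    print(f"           R2 step1 = {rep.steps[0].r2:.3f}, step2 = {rep.steps[1].r2:.3f}")
print("  -> sampling, not internal noise, carries the age-related improvement")
print("     in coherence sensitivity (true by construction in the generator).")
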