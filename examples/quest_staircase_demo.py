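"""Run the 165-trial equivalent-noise task on a known synthetic observer.

Two 75-trial QUEST staircases are randomly interleaved with 15 catch
trials: the no-noise staircase varies the mean direction offset at
direction SD 0, the high-noise staircase varies the direction SD at a
+/-45 deg signal.  Both track the 84%-correct point.
"""

import math

import numpy as np
from scipy.stats import norm

from equinoise import ObserverParams, en_curve, run_en_task

obs = ObserverParams(sigma_int=6.0, n_samp=1.85, lapse=0.02)
res = run_en_task(obs, speed=1.5, rng=np.random.default_rng(7))

print(f"observer: sigma_int = {obs.sigma_int} deg, n_samp = {obs.n_samp}, lapse = {obs.lapse}")
print(f"trials emitted: {len(res.trials)} "
      f"(incl. {sum(t['is_catch'] for t in res.trials)} catch trials, "
      f"{res.catch_incorrect} answered incorrectly)")

pred_nn = norm.ppf(0.84) * en_curve(obs.sigma_int, obs.n_samp, 0.0)
mtn_pred = math.sqrt(obs.n_samp * (45.0 / norm.ppf(0.84)) ** 2 - obs.sigma_int**2)
print(f"single run: no-noise threshold = {res.thresholds['no_noise']:.2f} deg, "
      f"MTN = {res.thresholds['high_noise']:.1f} deg")

reps = [run_en_task(obs, 1.5, np.random.default_rng(100 + i)).thresholds for i in range(20)]
nn = np.median([r["no_noise"] for r in reps])
hn = np.median([r["high_noise"] for r in reps])
print(f"median of 20 runs: no-noise = {nn:.2f} deg (closed form {pred_nn:.2f}), "
      f"MTN = {hn:.1f} deg (closed form {mtn_pred:.1f})")
print("  -> a single 75-trial staircase scatters by ~0.07-0.09 log10 units")
print("     around the true threshold; the median of replicates homes in on it.")
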