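"""Build the two stimulus dialects and inspect their statistics.

The equivalent-noise task draws every dot direction from a wrapped normal
(mean = signal direction, SD = external noise); the motion-coherence task
mixes a fixed fraction of signal dots with uniformly random noise dots.
"""

import numpy as np
from scipy.stats import circmean, circstd

from equinoise import (
    StimulusSpec,
    displacement_per_update,
    generate_dot_trajectory,
    make_coherence_directions,
    sample_wrapped_normal_directions,
)

rng = np.random.default_rng(1)

fld = sample_wrapped_normal_directions(mean=45.0, sd=45.0, n=100_000, rng=rng)
print(f"wrapped normal (mean 45, SD 45): circular mean = "
      f"{circmean(fld.directions, high=180, low=-180):.2f} deg, "
      f"circular SD = {circstd(fld.directions, high=180, low=-180):.2f} deg")
print("  -> the sampler reproduces the requested circular moments.")

coh = make_coherence_directions(coherence=0.47, signal_direction=-90.0, n=100, rng=rng)
n_sig = int(np.sum(coh.directions == -90.0))
print(f"coherence mixture (47%): {n_sig} signal dots at -90 deg, {100 - n_sig} random")

spec = StimulusSpec(speed=1.5)
traj = generate_dot_trajectory(spec, sample_wrapped_normal_directions(0.0, 0.0, 100, rng), rng)
step = np.hypot(*(traj[1] - traj[0]).T)
print(f"kinematics at 1.5 deg/s: {spec.n_updates} updates over {spec.duration:.0f} ms, "
      f"step = {np.median(step):.3f} deg "
      f"(design value {displacement_per_update(1.5, 60, 3):.3f} deg)")
print(f"kinematics at 6 deg/s: step = {displacement_per_update(6.0, 60, 3):.3f} deg")
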