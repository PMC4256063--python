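"""Re-derive the MTN -> n_samp mapping by Monte Carlo and compare it with
the published exponential-quadratic coefficients.

For a grid of sampling levels (internal noise fixed at a negligible 1 deg)
the 84% maximum-tolerable-noise threshold of the generative observer is
measured by constant-stimuli simulation, and log n_samp is fit as a
quadratic in MTN — the functional form of the published mapping.
"""

import numpy as np

from equinoise import MtnSimulationConfig, nsamp_from_mtn, rederive_mtn_mapping

mapping = rederive_mtn_mapping(MtnSimulationConfig(), np.random.default_rng(5))
a, b, c = mapping.coeffs
print(f"fitted:    log n_samp = {a:+.6f}*MTN^2 {b:+.4f}*MTN {c:+.4f}   (R^2 = {mapping.r_squared:.4f})")
print(f"published: log n_samp = +0.000121*MTN^2 +0.0357*MTN -1.8093")
print()
print(" MTN   simulated-fit   published   ratio")
for mtn in (15, 25, 35, 45, 55, 60):
    f, p = mapping.predict(mtn), nsamp_from_mtn(mtn)
    print(f"  {mtn:2d}      {f:6.3f}        {p:6.3f}     {f / p:4.2f}")
print()
print("The two mappings agree near unit sampling (MTN ~ 45 deg) but diverge")
print("towards the band edges: an ideal variance-averaging observer obeys")
print("n_samp ~ (MTN/45.5)^2, which the published quadratic does not track")
print("below ~ 33 deg.  Estimates for low-sampling observers therefore differ")
print("systematically between the two mappings.")
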