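"""Two-stage MCMC fit of noisy spherical-mean signals.

Simulates 10 noisy realizations of a macaque-like voxel (SNR 150), fits
them with the two-stage sampler, and prints the posterior means.  Stage 1
samples all six parameters; stage 2 re-samples the fractions and diameter
with the diffusivities pinned at their stage-1 means, which tightens the
f_ia and d_a posteriors.  Runs the full-length default chains (70,000
iterations per stage); all realizations are advanced as one vectorized
batch, so this takes a few seconds.
"""

import numpy as np

from axomyelin import (
    MCMCConfig,
    PriorSet,
    SphericalMeanSignal,
    default_exvivo_protocol,
    two_stage_fit,
)
from axomyelin.synthetic import preset_tissue_params, simulate_spherical_means

protocol = default_exvivo_protocol()
theta = preset_tissue_params("macaque", d_a=4.0)

noisy = simulate_spherical_means(theta, protocol, snr=150.0,
                                 n_realizations=10, seed=42)
signal = SphericalMeanSignal(b_values=protocol.b_values, means=noisy)

config = MCMCConfig(seed=1)
result = two_stage_fit(signal, protocol, PriorSet(), config)
s2 = result.stage2

print("ground truth: f_ia=0.80  f_dot=0.10  d_a=4.0 um  D_par=0.45 um^2/ms")
print("posterior means over 10 noisy realizations (stage 2):")
for name, gt in [("f_ia", 0.8), ("f_dot", 0.1), ("d_a", 4.0)]:
    est = s2.mean(name)
    print(f"  {name:6s} {est.mean():.3f} +/- {est.std():.3f}  (truth {gt})")
print(f"  d_par  {result.stage1.mean('d_par_ia').mean():.3f} (stage 1; "
      "pinned in stage 2)")
print(f"stage-2 vs stage-1 posterior SD of f_ia: "
      f"{s2.sd('f_ia').mean():.3f} vs {result.stage1.sd('f_ia').mean():.3f} "
      "(stage 2 is tighter)")
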