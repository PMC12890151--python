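"""Replicate study, bootstrap uncertainty and regularisation-strength scan.

Generates noisy replicate datasets of the g_abs_x = 0.4 scenario, fits each
one, then (a) summarises the estimates, (b) bootstraps the replicate means
for percentile intervals and a percentile p-value against the generating
value, and (c) scans the regularisation strength lambda.  A small replicate
count keeps the example quick; the acceptance script runs the full design.
"""

import numpy as np

from coupledpk import (NoiseSpec, add_noise, bootstrap_fit, build_constraints,
                       lambda_scan, make_scenario, replicate_fits, simulate,
                       summarize_replicates)
from coupledpk.pso import PSOConfig

scenario = make_scenario(g_abs_x=0.4)
traj = simulate(scenario, horizon=12.6, output_step=0.01)
datasets = add_noise(traj, NoiseSpec(sd_frac=0.1, n_reps=8, seed=5))
base = make_scenario()
cons = build_constraints(base.drug_x.rates, base.drug_y.rates, 0.6, 1.0,
                         max(float(p.obs_x.max()) for p in datasets),
                         max(float(p.obs_y.max()) for p in datasets))
cfg = PSOConfig(n_particles=24, max_iter=120, patience=25, seed=9)

fits = replicate_fits(datasets, base, cons, cfg, lambda_=0.6, amount_scale=1000.0)
print("replicate summary (8 noisy datasets, lambda=0.6):")
print(summarize_replicates(fits).round(4).to_string(index=False))

boot = bootstrap_fit(datasets, base, cons, cfg, lambda_=0.6, n_boot=200, seed=3,
                     amount_scale=1000.0, fits=fits,
                     null_values=[0.4, 0, 0, 0, 0, 0, 0, 0])
print("\nbootstrap (200 resamples; p-value vs the generating vector):")
print(boot.round(4).to_string(index=False))

scan = lambda_scan(datasets[:4], base, cons, cfg, [0.1, 0.6], amount_scale=1000.0)
print("\nlambda scan of the absorption coefficient:")
print(scan[scan['parameter'] == 'x_abs'].round(4).to_string(index=False))
print("\nThe bootstrap interval brackets the generating value 0.4; with "
      "mg-scale residuals the penalty is gentle, so the scan moves little.")
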