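"""Two-stage estimation on synthetic data: monotherapy fit, then coupling fit.

Stage 1 fits one drug's rate constants and apparent volume from a noise-free
monotherapy concentration curve.  Stage 2 generates a noisy combined-
administration dataset from a scenario with a known absorption coupling
(g_abs_x = 0.4) and recovers the eight interaction coefficients by
constrained particle-swarm minimisation of the regularised objective.
"""

import numpy as np

from coupledpk import (ConcentrationSeries, NoiseSpec, ObjectiveSpec,
                       add_noise, analytic_uncoupled, build_constraints,
                       fit_interactions_pso, fit_single_drug, make_scenario,
                       simulate)
from coupledpk.pso import PSOConfig

# --- stage 1: monotherapy rates + volume (known Vc keeps the fit identifiable)
times = np.geomspace(0.1, 24, 25)
truth = make_scenario()
conc = analytic_uncoupled(truth.drug_x.rates, 0.6, times) / 2000.0
stage1 = fit_single_drug(ConcentrationSeries(times=times, values=conc,
                                             unit="g/ml"), dose=0.6,
                         v_central=2000.0)
print("stage 1 (drug X): rates =", np.round(stage1.rates.as_array(), 4),
      " Vc =", stage1.v_central, "ml  R^2 =", round(stage1.r2, 6))

# --- stage 2: recover the coupling from one noisy combined dataset
scenario = make_scenario(g_abs_x=0.4)
traj = simulate(scenario, horizon=12.6, output_step=0.01)
pair = add_noise(traj, NoiseSpec(sd_frac=0.1, n_reps=1, seed=20))[0]
cons = build_constraints(truth.drug_x.rates, truth.drug_y.rates, 0.6, 1.0,
                         float(pair.obs_x.max()), float(pair.obs_y.max()))
spec = ObjectiveSpec(lambda_=0.6, data=pair, amount_scale=1000.0)
fit = fit_interactions_pso(spec, cons, PSOConfig(n_particles=24, max_iter=120,
                                                 patience=25, seed=1),
                           make_scenario())
print("\nstage 2 estimates (true vector has g_abs_x = 0.4, others 0):")
for name, value in zip(fit.labels, fit.w):
    print(f"  {name:6s} {value: .4f}")
print(f"objective z = {fit.z:.4f}   R^2: drug X {fit.r2_x:.4f}, drug Y {fit.r2_y:.4f}")
print("\nA single noisy replicate identifies the absorption coefficient only "
      "roughly (correlated nuisance terms absorb part of the noise); averaging "
      "over replicate datasets, as in example 03, centres it on 0.4.")
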