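# Methods

## Model

`coupledpk` implements a linearly coupled pair of two-compartment oral
pharmacokinetic models.  Each drug occupies a gut (absorption) compartment,
a central compartment (plasma plus well-perfused tissue) and a peripheral
compartment, with first-order transfer and elimination.  Writing drug X's
amounts as (x0, x1, x2) for gut/central/peripheral and drug Y's as
(y0, y1, y2), the system is

    x0' = -(ka_x + gx_abs * y0) * x0
    x1' =  (ka_x + gx_abs * y0) * x0 - (k12_x + gx_cp * y1) * x1
          + (k21_x + gx_pc * y2) * x2 - (k10_x + gx_el * y1) * x1
    x2' =  (k12_x + gx_cp * y1) * x1 - (k21_x + gx_pc * y2) * x2

and symmetrically for Y with x and y exchanged.  Each rate constant is
modulated *linearly* by the partner drug's current amount in the compartment
that drives the process (gut amount for absorption, central amount for
distribution-out and elimination, peripheral amount for distribution-back).
A negative coefficient is inhibition, a positive one promotion, zero
recovers two independent classical models.  The linearity is a first-order
(small-signal) approximation of concentration-dependent interaction and is
only credible over a limited dose range; saturable mechanisms
(Michaelis–Menten transport or metabolism) are out of scope.

Two cumulative-elimination states are carried alongside the six amounts so
that `gut + central + peripheral + eliminated = dose` holds identically;
the test suite enforces this balance to 1e-8 relative at all stored times.

**Units.** Canonical amounts are 10^3 mg (grams), time is hours, rates 1/h,
interaction coefficients 10^3/(mg·h).  Plasma concentrations convert to
central amounts through the apparent central volume, `amount = Vc * c`; Vc
is per drug (a shared Vc is the special case of equal values).

## Simulation and summary metrics

`simulate` integrates the eight-state system with a stiff-capable adaptive
solver (LSODA, rtol 1e-9, atol 1e-12, dense output).  The defaults — a 40 h
horizon with 0.001 h output step — were frozen because the finite-window
AUC of the reference uncoupled scenario then reproduces its tabulated value:
AUC(T) = dose/k10 − tail, with the dominant-mode tail
1.40498·exp(−0.190983·T) at the reference parameters, so T = 40 h gives
1.19932 against the infinite-horizon 1.2.

The uncoupled model has the classical tri-exponential closed form with
hybrid constants λ1, λ2 solving s² + (k12+k21+k10)s + k21·k10 = 0;
`analytic_uncoupled` implements it, including the algebraic cancellation of
the absorption exponential when k_abs = k21 (which the reference drug-X
parameters exercise) and the analytic t·e^{−λt} limit when k_abs coincides
with a hybrid constant to within 1e-8 relative.  Exactly repeated hybrid
roots raise rather than silently perturbing.  This closed form is the
independent oracle for the numerical integrator (agreement to 1e-6
absolute) — the two routes never share code.

Metrics are computed on the dense interpolant, not the output grid:

- **Cmax/Tmax** — grid argmax refined by bounded scalar minimisation.
- **AUC[0,T]** — composite Simpson quadrature on 8193 dense samples.
- **t1/2** — *time from dosing at which the post-peak central curve first
  falls to half of Cmax*, located by root finding.  This operational
  definition is deliberate: the terminal log-linear half-life ln2/λ1
  (≈ 3.63 h at the reference parameters) is inconsistent with the tabulated
  reference value 6.1715 h, which the crossing definition reproduces to
  four digits.  The two definitions answer different questions; ours tracks
  the duration of peak-level exposure.

## Synthetic study designs

`make_scenario` pins the reference conditions: doses 0.6 and 1.0
(10^3 mg), drug X rates all 0.5/h, drug Y rates 0.6/0.5/0.4/0.3/h,
interactions zero unless overridden (overrides are validated against the
feasibility bounds below).  `add_noise` emulates measurement error:
per sampling time, observed = amount + ε with ε ~ N(0, (0.1·amount)²),
truncated at zero, 100 replicates by default, on a 13-point 0.25–12 h
schedule mirroring clinical crossover sampling.  The proportional reading
of "noise scaled to the amount" is a deliberate interpretation: a constant
sd of 0.1 against a curve peaking near 0.165 would drown the signal and is
incompatible with replicate confidence intervals of width ~0.005; the sd
model is nevertheless switchable (`model='additive'`).  Truncation rather
than resampling keeps the observation model simple; at sd = 0.1·amount the
truncation bias is negligible (the mean over 10^4 replicates matches the
noiseless curve to 1%, enforced in tests).

What the generator does *not* emulate: between-subject variability (random
effects), sampling-time jitter, assay limits of quantification, or
multi-dose accumulation.  Passing recovery tests therefore demonstrate the
estimator's behaviour under measurement noise on a single profile, not
population-level performance.

## Two-stage estimation

The sixteen per-drug constants plus eight couplings are not jointly
identifiable from two concentration curves, so estimation is hierarchical:

**Stage 1 (monotherapy).** Each drug's four rates and Vc are fitted to its
single-administration curve by multi-start, log-parameterised nonlinear
least squares on the closed-form solution (12 seeded starts around a
curve-stripping heuristic).  *Identifiability caveat:* an oral
concentration curve determines three exponents and one amplitude ratio, so
with Vc free the parameter set is identified only up to exchanging k_abs
with a hybrid constant — the classical flip-flop — and at the reference
drug-X parameters (k_abs = k21) a one-parameter solution family exists.
The fitted curve, the exponent set and all downstream predictions are
invariant; `fit_single_drug(..., v_central=...)` fixes the amplitude and
restores uniqueness when the volume is known.

**Stage 2 (interactions).** With stage-1 rates and volumes fixed, the
eight-coefficient vector W minimises

    z(W) = SSE_x + SSE_y + λ · Σ W_i²

where SSE is the *mean* squared deviation of the central amounts at the
observation times (per-drug n) — the penalty is a plain sum of squares, no
square root.  Positivity of every effective rate yields one lower bound per
coefficient, −rate/(driving amount maximum); unobservable gut and
peripheral driving maxima are replaced by the partner's initial dose,
central ones by the maximum observed central amount.  Upper bounds are
10× the lower-bound magnitudes (promotion has no physical ceiling, but the
search needs a finite box; the factor is configurable).  W = 0 is feasible
by construction and is always injected into the initial swarm.

The search is a seeded global-best PSO with constriction-style settings
(inertia 0.729, cognitive = social = 1.494, swarm 50, ≤500 iterations,
clamp-to-bound handling, early stop after 60 stalled iterations), followed
by a bounded L-BFGS-B polish whose central-difference gradient is evaluated
as one batched ODE solve.  The studies in the test-suite and acceptance
script use a reduced budget (swarm 24, ≤120 iterations); across swarm
budgets and seeds the polished optimum agrees to ~1e-4, so the budget
choice is a runtime knob, not a results knob.  Candidate vectors whose
dynamics diverge (possible once an amount exceeds the observed maxima
behind the bounds) are detected by a terminal solver event, assigned a
penalty, and removed from the batch so they cannot stall the swarm.
Identical seeds give bit-identical fits.

### The λ scale

λ trades data misfit against coefficient shrinkage, so its meaning depends
on the scale on which residuals are squared.  On the canonical 10^3-mg
scale the mean-squared residuals of the reference noisy design are ~1e-4,
and any λ ≳ 0.01 would annihilate couplings of magnitude 0.1–1 (and a
fortiori the 10²–10⁴-magnitude couplings seen in clinical-scale fits).
Quoted λ values of order 0.1–1 are only workable when residuals are
evaluated in milligrams; `ObjectiveSpec(amount_scale=1000)` does exactly
that and is the setting used by the replicate, bootstrap and λ-scan
studies.  The default `amount_scale=1` keeps the objective formula verbatim
on canonical units for arithmetic transparency.  Users should expect the
*effective* shrinkage at a given λ to move with this choice; `lambda_scan`
exists to make the sensitivity visible.  Note that under a ridge-type
penalty the estimates can only move toward zero as λ grows (up to
correlated-parameter redistribution); with mg-scale residuals the quoted λ
grid produces nearly λ-independent estimates.

### Uncertainty and model comparison

- **Replicate summaries** report per-coefficient means with normal 95% CIs
  across independently fitted replicate datasets.
- **Bootstrap** resamples *replicate datasets* with replacement; the
  estimator of a resample is the mean of per-dataset estimates, so each
  distinct dataset is fitted once and cached — an exact, not approximate,
  shortcut.  Percentile 95% intervals; the optional p-value is the
  two-sided percentile position of a user-supplied null (e.g. the
  generating value).
- **Ablation** refits with the absorption couplings, the elimination
  couplings, or both pairs pinned to zero, reporting per-drug R² and the
  least-squares AIC, n·ln(SSE/n) + 2k with k the number of free
  coefficients (chosen because only SSE is available; any fixed Gaussian
  constant cancels in comparisons).
- **Interaction effects** are reported as g·(driving amount)/(baseline
  rate) × 100%: the maximum uses the initial partner dose; the
  time-resolved form offers both an instantaneous and a running-mean
  (default) variant, since "average effect at t" is ambiguous.

## Numerical choices and degenerate inputs

- Integration tolerances: simulation rtol 1e-9/atol 1e-12 (reference
  metrics stable to ≥5 significant digits under tightening); estimation
  batch solves rtol 1e-6/atol 1e-9 (objective differences far above that).
- Peak of an all-zero curve: (0, 0) with a warning; half-life of a curve
  that never falls to half its peak raises `UndefinedMetricError` rather
  than returning a silent number.
- Observed series must start strictly after t = 0 (t = 0 is dosing, where
  central amounts are identically zero and carry no information).
- Stage-1 requires ≥6 distinct sampling times (five free quantities).
- Repeated hybrid roots (measure-zero parameter set) raise.

## Problem sizes

The test suite and the acceptance script size the stochastic studies as
follows: the full 100-replicate design for the recovery and bootstrap
studies, 200 bootstrap resamples, 8 replicates per λ in the suite's scan,
single-replicate ablation and clinical-style fits.  These are the package's standard study
sizes; the per-fit optimum is budget-insensitive (see above), so larger
designs change only the width of the reported intervals.

## Known limitations

- Single oral dose per drug, two drugs, linear couplings only.
- Stage-1 flip-flop ambiguity when Vc is free (above); stage 2 conditions
  on whichever curve-equivalent parameterisation stage 1 returns.
- The bootstrap treats the replicate dataset as the exchangeable unit;
  within-curve residual resampling is not offered.
- Under the implemented ridge-type penalty, λ-scan trajectories can only
  flatten or shrink toward zero (up to correlated-parameter
  redistribution); a systematic *rise* of an estimate with λ is outside
  what this objective can produce.
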