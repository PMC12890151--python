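"""Hierarchical two-stage estimation of the coupled PK model.

Stage 1 fits each drug's monotherapy data with the closed-form uncoupled
two-compartment oral solution (nonlinear least squares on the analytic
curve, multi-start, log-parameterised), yielding the four rate constants
and the apparent central volume Vc.  Stage 2 fixes those and estimates the
eight interaction coefficients W = (gx_abs, gx_cp, gx_pc, gx_el, gy_abs,
gy_cp, gy_pc, gy_el) from combined-administration data by minimising

    z(W) = SSEx + SSEy + lambda * L2,

where SSEx/SSEy are *mean* squared deviations of the central-compartment
amounts at the observation times and L2 is the plain sum of squared
coefficients, over the feasibility box derived from positivity of the
effective rates.  The global search is a seeded, bounded particle swarm
with an optional deterministic local polish.

Scale note: residuals are squared after multiplication by ``amount_scale``.
The default (1.0) evaluates them on the canonical 10^3-mg scale, matching
the objective formula verbatim; the replicate-recovery and bootstrap studies
evaluate them in mg (scale 1000), the only reading under which the quoted
regularisation strengths (lambda ~ 0.1-1) leave interaction coefficients of
magnitude 0.1-10^4 estimable at all — see docs/methods.md for the analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize

from .model import (ConcentrationSeries, CoupledSystem, DrugRates,
                    analytic_uncoupled)
from .pso import PSOConfig, minimize_pso

__all__ = [
    "ObservedPair", "ObjectiveSpec", "ConstraintSet", "Stage1Fit", "FitResult",
    "AblationScheme", "W_LABELS",
    "objective_value", "objective_components", "build_constraints",
    "fit_single_drug", "fit_interactions_pso", "replicate_fits",
    "summarize_replicates", "lambda_scan", "bootstrap_fit", "ablation_study",
    "r_squared", "aic", "interaction_effect_max", "interaction_effect_at_time",
]

log = logging.getLogger(__name__)

#: Order of the stage-2 decision vector W.
W_LABELS = ("x_abs", "x_cp", "x_pc", "x_el", "y_abs", "y_cp", "y_pc", "y_el")

_PENALTY = 1e12  # sentinel objective for a failed candidate simulation


@dataclass(frozen=True)
class ObservedPair:
    """Observed central-compartment amount series of both drugs under
    combined administration (canonical 10^3-mg scale)."""

    times_x: np.ndarray
    obs_x: np.ndarray
    times_y: np.ndarray
    obs_y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times_x", "obs_x", "times_y", "obs_y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.times_x.shape != self.obs_x.shape or self.times_y.shape != self.obs_y.shape:
            raise ValueError("time and observation arrays must match in shape")
        if self.times_x.size < 1 or self.times_y.size < 1:
            raise ValueError("each drug needs at least one observation")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Observations plus regularisation strength for the stage-2 objective."""

    lambda_: float
    data: ObservedPair
    amount_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.amount_scale <= 0:
            raise ValueError("amount_scale must be > 0")


@dataclass(frozen=True)
class ConstraintSet:
    """Feasibility box for W from positivity of the effective rates.

    Each lower bound is ``-rate / (driving amount maximum)``, with the
    unobservable gut/peripheral driving maxima replaced by the partner's
    initial dose and the central ones by the maximum observed central
    amount.  Upper bounds are a symmetric multiple of the lower-bound
    magnitudes (the search needs a finite box; promotion has no physical
    ceiling).  W = 0 is always feasible.
    """

    lower: np.ndarray
    upper: np.ndarray
    scales: np.ndarray     # driving-amount maxima used per coefficient
    baseline: np.ndarray   # the uncoupled rates U
    labels: tuple = W_LABELS

    def violations(self, w) -> list[str]:
        w = np.asarray(w, dtype=float)
        bad = []
        for i, name in enumerate(self.labels):
            if not (self.lower[i] <= w[i] <= self.upper[i]):
                bad.append(f"{name}: {w[i]:.6g} outside [{self.lower[i]:.6g}, {self.upper[i]:.6g}]")
        return bad

    def contains(self, w) -> bool:
        return not self.violations(w)


def build_constraints(rates_x: DrugRates, rates_y: DrugRates,
                      dose_x: float, dose_y: float,
                      max_obs_x: float, max_obs_y: float,
                      upper_factor: float = 10.0) -> ConstraintSet:
    """Practical bounds for the eight interaction coefficients.

    ``max_obs_x``/``max_obs_y`` are the maxima of the observed central-amount
    series (the ``max`` terms of the practical constraints); the gut and
    peripheral driving maxima are the initial doses.
    """
    for name, v in (("dose_x", dose_x), ("dose_y", dose_y),
                    ("max_obs_x", max_obs_x), ("max_obs_y", max_obs_y)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite to build the bounds, got {v!r}")
    baseline = np.array([rates_x.k_abs, rates_x.k_cp, rates_x.k_pc, rates_x.k_el,
                         rates_y.k_abs, rates_y.k_cp, rates_y.k_pc, rates_y.k_el])
    scales = np.array([dose_y, max_obs_y, dose_y, max_obs_y,
                       dose_x, max_obs_x, dose_x, max_obs_x])
    lower = -baseline / scales
    upper = upper_factor * np.abs(lower)
    return ConstraintSet(lower=lower, upper=upper, scales=scales, baseline=baseline)


# ---------------------------------------------------------------------------
# stage-2 objective

#: Amount cap used to keep divergent candidate simulations finite.  Candidate
#: interaction vectors can make an effective rate negative once an amount
#: exceeds the observed maxima behind the feasibility bounds; the resulting
#: super-exponential growth would otherwise overflow and stall the solver.
#: Clipped candidates produce huge-but-finite residuals and are rejected by
#: the objective itself.  The cap sits many orders of magnitude above any
#: physically meaningful amount (total dose is O(1) on the canonical scale).
_AMOUNT_CAP = 1e6


def _batch_rhs_factory(system: CoupledSystem, w_batch: np.ndarray):
    """Vectorised RHS for S copies of the system differing only in W."""
    s = w_batch.shape[0]
    rx = system.drug_x.rates
    ry = system.drug_y.rates
    gx = w_batch[:, 0:4].T  # (4, S)
    gy = w_batch[:, 4:8].T

    def rhs(t, flat):
        st = np.clip(flat.reshape(s, 8).T, -_AMOUNT_CAP, _AMOUNT_CAP)  # (8, S)
        xg, xc, xp, _xe, yg, yc, yp, _ye = st
        with np.errstate(over="ignore", invalid="ignore"):
            ax_abs = (rx.k_abs + gx[0] * yg) * xg
            ax_cp = (rx.k_cp + gx[1] * yc) * xc
            ax_pc = (rx.k_pc + gx[2] * yp) * xp
            ax_el = (rx.k_el + gx[3] * yc) * xc
            ay_abs = (ry.k_abs + gy[0] * xg) * yg
            ay_cp = (ry.k_cp + gy[1] * xc) * yc
            ay_pc = (ry.k_pc + gy[2] * xp) * yp
            ay_el = (ry.k_el + gy[3] * xc) * yc
            out = np.empty_like(st)
            out[0] = -ax_abs
            out[1] = ax_abs - ax_cp + ax_pc - ax_el
            out[2] = ax_cp - ax_pc
            out[3] = ax_el
            out[4] = -ay_abs
            out[5] = ay_abs - ay_cp + ay_pc - ay_el
            out[6] = ay_cp - ay_pc
            out[7] = ay_el
        return np.nan_to_num(out, nan=0.0, posinf=_AMOUNT_CAP,
                             neginf=-_AMOUNT_CAP).T.ravel()

    return rhs


def _simulate_batch(system: CoupledSystem, w_batch: np.ndarray, t_eval: np.ndarray,
                    rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
    """Central amounts (S, n_times, 2) for a batch of candidate W vectors.

    Candidates whose dynamics diverge (amounts far outside the physically
    possible range, which infeasible interaction combinations can produce)
    are detected by a terminal solver event, NaN-filled — the objective
    assigns them the penalty — and the remaining candidates are re-solved,
    so one divergent particle cannot stall the whole swarm.
    """
    w_batch = np.atleast_2d(np.asarray(w_batch, dtype=float))
    s = w_batch.shape[0]
    t_end = float(t_eval[-1])
    total_dose = system.drug_x.dose + system.drug_y.dose
    limit = max(10.0 * total_dose, 1.0)
    out = np.full((s, t_eval.size, 2), np.nan)
    active = np.arange(s)
    for _round in range(s + 1):
        if active.size == 0:
            break
        rhs = _batch_rhs_factory(system, w_batch[active])
        y0 = np.tile(system.initial_state(), active.size)

        def diverged(t, y):
            return limit - float(np.max(np.abs(y)))
        diverged.terminal = True

        try:
            res = solve_ivp(rhs, (0.0, t_end), y0, method="RK45", t_eval=t_eval,
                            rtol=rtol, atol=atol, events=diverged)
        except (ValueError, FloatingPointError, OverflowError):
            res = None
        if res is not None and res.status == 0 and np.all(np.isfinite(res.y)):
            states = res.y.reshape(active.size, 8, t_eval.size)
            out[active, :, 0] = states[:, 1, :]
            out[active, :, 1] = states[:, 5, :]
            break
        if res is not None and res.status == 1 and res.y_events[0].size:
            # drop every candidate that is at (or near) the divergence limit
            final = np.abs(res.y_events[0][-1].reshape(active.size, 8))
            bad = np.nonzero(final.max(axis=1) >= 0.5 * limit)[0]
            if bad.size == 0:
                bad = np.array([int(np.argmax(final.max(axis=1)))])
            active = np.delete(active, bad)
            continue
        # unstructured failure: integrate one by one with a stiff-capable
        # solver; candidates that still fail stay NaN
        for i in active:
            rhs_i = _batch_rhs_factory(system, w_batch[i:i + 1])
            try:
                res_i = solve_ivp(rhs_i, (0.0, t_end), system.initial_state(),
                                  method="LSODA", t_eval=t_eval, rtol=rtol,
                                  atol=atol, events=diverged)
                if res_i.status == 0 and np.all(np.isfinite(res_i.y)):
                    out[i, :, 0] = res_i.y[1]
                    out[i, :, 1] = res_i.y[5]
            except (ValueError, FloatingPointError, OverflowError):
                pass
        break
    return out


def _objective_batch(w_batch: np.ndarray, system: CoupledSystem,
                     spec: ObjectiveSpec, rtol: float = 1e-6) -> np.ndarray:
    """Objective values for an (S, 8) batch of candidate W vectors."""
    d = spec.data
    t_eval = np.union1d(d.times_x, d.times_y)
    if t_eval[0] <= 0:
        raise ValueError("observation times must be strictly positive")
    ix = np.searchsorted(t_eval, d.times_x)
    iy = np.searchsorted(t_eval, d.times_y)
    central = _simulate_batch(system, np.asarray(w_batch, float), t_eval, rtol=rtol)
    mod_x = central[:, ix, 0] * spec.amount_scale
    mod_y = central[:, iy, 1] * spec.amount_scale
    rx = mod_x - d.obs_x[None, :] * spec.amount_scale
    ry = mod_y - d.obs_y[None, :] * spec.amount_scale
    sse_x = np.mean(rx ** 2, axis=1)
    sse_y = np.mean(ry ** 2, axis=1)
    l2 = np.sum(np.asarray(w_batch, float) ** 2, axis=1)
    z = sse_x + sse_y + spec.lambda_ * l2
    bad = ~np.isfinite(z)
    if np.any(bad):
        log.debug("objective: %d candidate(s) failed to integrate; assigning penalty",
                    int(bad.sum()))
        z = np.where(bad, _PENALTY, z)
    return z


def objective_components(w, system: CoupledSystem, spec: ObjectiveSpec,
                         rtol: float = 1e-6) -> dict:
    """SSEx, SSEy, L2 and z for a single candidate W."""
    w = np.asarray(w, dtype=float).reshape(1, 8)
    d = spec.data
    t_eval = np.union1d(d.times_x, d.times_y)
    ix = np.searchsorted(t_eval, d.times_x)
    iy = np.searchsorted(t_eval, d.times_y)
    central = _simulate_batch(system, w, t_eval)
    mod_x = central[0, ix, 0]
    mod_y = central[0, iy, 1]
    sse_x = float(np.mean(((mod_x - d.obs_x) * spec.amount_scale) ** 2))
    sse_y = float(np.mean(((mod_y - d.obs_y) * spec.amount_scale) ** 2))
    l2 = float(np.sum(w ** 2))
    z = sse_x + sse_y + spec.lambda_ * l2
    if not np.isfinite(z):
        log.debug("objective: candidate failed to integrate; assigning penalty")
        return {"sse_x": np.nan, "sse_y": np.nan, "l2": l2, "z": _PENALTY,
                "model_x": mod_x, "model_y": mod_y}
    return {"sse_x": sse_x, "sse_y": sse_y, "l2": l2, "z": z,
            "model_x": mod_x, "model_y": mod_y}


def objective_value(w, system: CoupledSystem, spec: ObjectiveSpec) -> float:
    """The stage-2 objective z = SSEx + SSEy + lambda * L2 at one candidate W."""
    return float(_objective_batch(np.asarray(w, float).reshape(1, 8), system, spec)[0])


# ---------------------------------------------------------------------------
# stage 1: monotherapy fit

@dataclass
class Stage1Fit:
    """Monotherapy fit of one drug: rates, Vc and diagnostics."""

    rates: DrugRates
    v_central: float
    sse: float
    r2: float
    n_starts: int
    stderr: np.ndarray | None = None  # (ka, kcp, kpc, kel, Vc) standard errors


def fit_single_drug(series: ConcentrationSeries, dose: float,
                    n_starts: int = 12, seed: int = 0,
                    v_central: float | None = None) -> Stage1Fit:
    """Least-squares fit of the closed-form uncoupled oral solution.

    The free quantities (four rates, plus Vc unless ``v_central`` fixes it)
    are log-parameterised and fitted with multi-start trust-region least
    squares against the observed concentrations; at least six distinct
    sampling times are required.

    Identifiability caveat: from oral concentration data alone the
    tri-exponential curve determines the three exponents and one amplitude
    ratio, so with Vc free the rate constants are only identified up to
    exchanging k_abs with a hybrid disposition constant (the classical
    flip-flop); the returned solution is the best-SSE fit among the starts
    and reproduces the curve regardless of which labelling it lands on.
    Fixing ``v_central`` pins the amplitude and removes the ambiguity.
    """
    times = np.asarray(series.times, dtype=float)
    if np.unique(times).size < 6:
        raise ValueError("stage-1 fit is under-determined: need at least 6 distinct "
                         f"sampling times, got {np.unique(times).size}")
    if dose <= 0:
        raise ValueError("dose must be positive")
    from .model import CONCENTRATION_UNITS
    conc = series.values * CONCENTRATION_UNITS[series.unit]  # g/ml

    fixed_vc = v_central

    def model_conc(theta, t):
        if fixed_vc is None:
            ka, kcp, kpc, kel, vc = np.exp(theta)
        else:
            ka, kcp, kpc, kel = np.exp(theta)
            vc = fixed_vc
        return analytic_uncoupled(DrugRates(ka, kcp, kpc, kel), dose, t) / vc

    def residuals(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            r = model_conc(theta, times) - conc
        return np.where(np.isfinite(r), r, 1e6)

    # data-driven starting heuristic: absorption from the observed peak time,
    # disposition from the terminal slope, Vc from peak height
    i_peak = int(np.argmax(conc))
    t_peak = max(times[i_peak], times[0])
    tail = slice(max(conc.size - 4, i_peak + 1), conc.size)
    tt, cc = times[tail], conc[tail]
    lam_z = 0.2
    if tt.size >= 2 and np.all(cc > 0):
        slope = np.polyfit(tt, np.log(cc), 1)[0]
        if slope < 0:
            lam_z = -float(slope)
    ka0 = max(1.0 / t_peak, 2.0 * lam_z)
    vc0 = 0.3 * dose / max(conc[i_peak], 1e-12)
    base = np.log([ka0, 2.0 * lam_z, 1.5 * lam_z, 2.0 * lam_z, vc0])
    if fixed_vc is not None:
        base = base[:4]

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        theta0 = base if k == 0 else base + rng.uniform(-1.5, 1.5, size=base.size)
        try:
            res = least_squares(residuals, theta0, method="trf",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000)
        except Exception:  # noqa: BLE001 - a diverged start is simply discarded
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("stage-1 fit failed to converge from every start")

    if fixed_vc is None:
        ka, kcp, kpc, kel, vc = np.exp(best.x)
    else:
        ka, kcp, kpc, kel = np.exp(best.x)
        vc = fixed_vc
    rates = DrugRates(ka, kcp, kpc, kel)
    sse = float(np.sum(best.fun ** 2))
    fitted = model_conc(best.x, times)
    r2 = r_squared(conc, fitted)
    stderr = None
    dof = times.size - best.x.size
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov_log = np.linalg.inv(jtj) * sse / dof
            # delta method: se(exp(theta)) = exp(theta) * se(theta)
            stderr = np.exp(best.x) * np.sqrt(np.diag(cov_log))
        except np.linalg.LinAlgError:
            stderr = None
    return Stage1Fit(rates=rates, v_central=float(vc), sse=sse, r2=r2,
                     n_starts=n_starts, stderr=stderr)


# ---------------------------------------------------------------------------
# stage 2: constrained PSO over the interaction coefficients

@dataclass
class FitResult:
    """Outcome of one stage-2 fit."""

    w: np.ndarray
    labels: tuple
    mask: np.ndarray            # True where the coefficient was free
    lower: np.ndarray
    upper: np.ndarray
    z: float
    sse_x: float
    sse_y: float
    l2: float
    lambda_: float
    amount_scale: float
    r2_x: float
    r2_y: float
    aic: float
    n_obs: int
    k_free: int
    seed: int
    n_iter: int
    converged: bool
    polished: bool
    history: list[float] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "w": {name: float(v) for name, v in zip(self.labels, self.w)},
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "mask_free": self.mask.astype(bool).tolist(),
            "z": self.z, "sse_x": self.sse_x, "sse_y": self.sse_y, "l2": self.l2,
            "lambda": self.lambda_, "amount_scale": self.amount_scale,
            "r2_x": self.r2_x, "r2_y": self.r2_y, "aic": self.aic,
            "n_obs": self.n_obs, "k_free": self.k_free,
            "seed": self.seed, "n_iter": self.n_iter,
            "converged": self.converged, "polished": self.polished,
        }


class AblationScheme(Enum):
    """Interaction-term ablation variants.

    FULL keeps all eight coefficients free; NO_ABSORPTION pins the two
    absorption coefficients to zero, NO_ELIMINATION the two elimination
    coefficients, and NO_ABS_ELIM both pairs.
    """

    FULL = "Model 1"
    NO_ABSORPTION = "Model 2"
    NO_ELIMINATION = "Model 3"
    NO_ABS_ELIM = "Model 4"

    @property
    def pinned_indices(self) -> tuple[int, ...]:
        return {
            AblationScheme.FULL: (),
            AblationScheme.NO_ABSORPTION: (0, 4),
            AblationScheme.NO_ELIMINATION: (3, 7),
            AblationScheme.NO_ABS_ELIM: (0, 3, 4, 7),
        }[self]


def fit_interactions_pso(spec: ObjectiveSpec, constraints: ConstraintSet,
                         config: PSOConfig, system: CoupledSystem,
                         mask: np.ndarray | None = None,
                         polish: bool = True) -> FitResult:
    """Global stage-2 fit of the interaction coefficients.

    ``system`` carries the stage-1 rates (its interaction coefficients are
    ignored).  ``mask`` marks the free coefficients (ablation pins the rest
    to zero).  The swarm always contains the all-zero candidate, which is
    feasible by construction; the best particle is optionally polished by
    bounded L-BFGS-B.  Identical seeds give identical results.
    """
    if mask is None:
        mask = np.ones(8, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    free = np.nonzero(mask)[0]
    if free.size == 0:
        raise ValueError("at least one interaction coefficient must be free")
    lower, upper = constraints.lower[free], constraints.upper[free]

    def expand(w_free_batch: np.ndarray) -> np.ndarray:
        full = np.zeros((w_free_batch.shape[0], 8))
        full[:, free] = w_free_batch
        return full

    def batch_fun(w_free_batch):
        return _objective_batch(expand(np.atleast_2d(w_free_batch)), system, spec)

    result = minimize_pso(batch_fun, lower, upper, config,
                          initial_points=np.zeros((1, free.size)))
    best = result.x
    polished = False
    if polish:
        d = free.size
        h = 1e-7 * np.maximum(1.0, upper - lower)

        def fun_and_grad(wf):
            # one batched solve evaluates the point and its central-difference
            # gradient stencil together
            pts = np.vstack([wf, wf + np.diag(h), wf - np.diag(h)])
            vals = batch_fun(pts)
            grad = (vals[1:1 + d] - vals[1 + d:]) / (2.0 * h)
            return float(vals[0]), grad

        loc = minimize(fun_and_grad, best, jac=True, method="L-BFGS-B",
                       bounds=list(zip(lower, upper)),
                       options={"maxiter": 60, "ftol": 1e-14, "gtol": 1e-12})
        if np.isfinite(loc.fun) and loc.fun <= result.fun:
            best = np.clip(loc.x, lower, upper)
            polished = True

    w_full = expand(best.reshape(1, -1))[0]
    comps = objective_components(w_full, system, spec)
    d = spec.data
    n_obs = d.obs_x.size + d.obs_y.size
    sse_total = comps["sse_x"] * d.obs_x.size + comps["sse_y"] * d.obs_y.size
    return FitResult(
        w=w_full, labels=constraints.labels, mask=mask,
        lower=constraints.lower, upper=constraints.upper,
        z=comps["z"], sse_x=comps["sse_x"], sse_y=comps["sse_y"], l2=comps["l2"],
        lambda_=spec.lambda_, amount_scale=spec.amount_scale,
        r2_x=r_squared(d.obs_x, comps["model_x"]),
        r2_y=r_squared(d.obs_y, comps["model_y"]),
        aic=aic(max(sse_total, 1e-300), n_obs, int(free.size)),
        n_obs=n_obs, k_free=int(free.size), seed=config.seed,
        n_iter=result.n_iter, converged=result.converged, polished=polished,
        history=result.history,
    )


# ---------------------------------------------------------------------------
# replicate studies: lambda scan, bootstrap, ablation

def _derived_seed(seed: int, i: int) -> int:
    return int((seed * 1000003 + 7919 * (i + 1)) % (2 ** 31 - 1))


def replicate_fits(datasets: list[ObservedPair], system: CoupledSystem,
                   constraints: ConstraintSet, config: PSOConfig,
                   lambda_: float, amount_scale: float = 1.0,
                   mask: np.ndarray | None = None) -> list[FitResult]:
    """Independent stage-2 fits of each replicate dataset (seeded per replicate)."""
    from dataclasses import replace as dc_replace

    fits = []
    for i, data in enumerate(datasets):
        spec = ObjectiveSpec(lambda_=lambda_, data=data, amount_scale=amount_scale)
        cfg = dc_replace(config, seed=_derived_seed(config.seed, i))
        fits.append(fit_interactions_pso(spec, constraints, cfg, system, mask=mask))
    return fits


def summarize_replicates(fits: list[FitResult]) -> pd.DataFrame:
    """Mean and normal-approximation 95% CI of each coefficient across fits."""
    w = np.array([f.w for f in fits])
    mean = w.mean(axis=0)
    if len(fits) > 1:
        half = 1.96 * w.std(axis=0, ddof=1) / np.sqrt(len(fits))
    else:
        half = np.zeros(8)
    return pd.DataFrame({
        "parameter": list(fits[0].labels),
        "mean": mean, "ci_lo": mean - half, "ci_hi": mean + half,
        "sd": w.std(axis=0, ddof=1) if len(fits) > 1 else np.zeros(8),
    })


def lambda_scan(datasets: list[ObservedPair], system: CoupledSystem,
                constraints: ConstraintSet, config: PSOConfig,
                grid, amount_scale: float = 1.0) -> pd.DataFrame:
    """Sensitivity of the stage-2 estimates to the regularisation strength.

    Repeats the replicate fits for every lambda in ``grid`` and reports the
    per-coefficient mean and 95% CI, in tidy long format.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    frames = []
    for lam in grid:
        fits = replicate_fits(datasets, system, constraints, config, lam, amount_scale)
        summary = summarize_replicates(fits)
        summary.insert(0, "lambda", lam)
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)


def bootstrap_fit(datasets: list[ObservedPair], system: CoupledSystem,
                  constraints: ConstraintSet, config: PSOConfig,
                  lambda_: float, n_boot: int = 200, seed: int = 0,
                  null_values=None, amount_scale: float = 1.0,
                  fits: list[FitResult] | None = None) -> pd.DataFrame:
    """Bootstrap over replicate datasets.

    Datasets are resampled with replacement; the estimate of a resample is
    the mean of the per-dataset stage-2 estimates (each distinct dataset is
    fitted once and cached — the estimator decomposes over datasets, so this
    is exact, not an approximation).  Reports the bootstrap mean, the 95%
    percentile CI and, when ``null_values`` is given, the two-sided
    percentile p-value of each null value in the bootstrap distribution.
    """
    if len(datasets) < 2:
        raise ValueError("bootstrap needs at least 2 replicate datasets")
    if fits is None:
        fits = replicate_fits(datasets, system, constraints, config,
                              lambda_, amount_scale)
    est = np.array([f.w for f in fits])         # (R, 8)
    if np.allclose(est, est[0]):
        warnings.warn("all replicate estimates are identical; bootstrap CI is degenerate",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(fits), size=(n_boot, len(fits)))
    boot = est[idx].mean(axis=1)                # (B, 8)
    mean = boot.mean(axis=0)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    out = pd.DataFrame({"parameter": list(fits[0].labels),
                        "mean": mean, "ci_lo": lo, "ci_hi": hi})
    if null_values is not None:
        null_values = np.asarray(null_values, dtype=float)
        p = np.empty(8)
        for j in range(8):
            below = np.mean(boot[:, j] <= null_values[j])
            above = np.mean(boot[:, j] >= null_values[j])
            p[j] = min(1.0, 2.0 * min(below, above))
        out["p_value"] = p
    return out


def ablation_study(spec: ObjectiveSpec, constraints: ConstraintSet,
                   config: PSOConfig, system: CoupledSystem,
                   schemes=tuple(AblationScheme)) -> pd.DataFrame:
    """Refit with absorption/elimination interaction terms pinned to zero.

    Returns one row per scheme with the free-parameter count, SSE components,
    per-drug R-squared and AIC (least-squares form, k = free coefficients).
    """
    rows = []
    for scheme in schemes:
        scheme = AblationScheme(scheme)
        mask = np.ones(8, dtype=bool)
        for i in scheme.pinned_indices:
            mask[i] = False
        fit = fit_interactions_pso(spec, constraints, config, system, mask=mask)
        rows.append({"scheme": scheme.value, "k_free": fit.k_free,
                     "sse_x": fit.sse_x, "sse_y": fit.sse_y,
                     "r2_x": fit.r2_x, "r2_y": fit.r2_y,
                     "aic": fit.aic, "z": fit.z})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fit statistics and interaction-effect reporting

def r_squared(observed, fitted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot about the observed mean."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape or observed.size < 2:
        raise ValueError("observed and fitted must match in shape with length >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed series has zero variance; R^2 undefined")
    ss_res = float(np.sum((observed - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def aic(sse: float, n: int, k: int) -> float:
    """Least-squares Akaike information criterion, n*ln(SSE/n) + 2k."""
    if n <= 0:
        raise ValueError("n must be positive")
    if sse <= 0:
        raise ValueError("SSE must be positive")
    return float(n * np.log(sse / n) + 2 * k)


def interaction_effect_max(g: float, driving_amount: float, baseline_rate: float) -> float:
    """Maximum fractional effect of a coupling on its rate, in percent.

    ``g * driving_amount / baseline_rate * 100``, signed: negative values
    quantify inhibition of the partner's rate process, positive promotion.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive")
    return float(g * driving_amount / baseline_rate * 100.0)


_DRIVING = {"abs": "gut", "cp": "central", "pc": "peripheral", "el": "central"}


def interaction_effect_at_time(traj, drug: str, process: str, g: float,
                               baseline_rate: float, t: float,
                               mode: str = "averaged") -> float:
    """Fractional effect of a coupling at (or averaged up to) time t, percent.

    ``instantaneous`` evaluates g * (partner driving amount at t) / baseline;
    ``averaged`` (default) is the running mean of that quantity over [0, t].
    """
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive")
    if process not in _DRIVING:
        raise ValueError(f"unknown process {process!r}; expected one of {sorted(_DRIVING)}")
    if t < 0 or t > traj.times[-1]:
        raise ValueError(f"time {t} outside the trajectory span [0, {traj.times[-1]}]")
    partner = "y" if drug == "x" else "x"
    comp = _DRIVING[process]

    def driving(ts):
        return traj.evaluate(np.atleast_1d(ts), partner, comp)

    if mode == "instantaneous" or t == 0:
        amount = float(driving(t)[0])
        return interaction_effect_max(g, amount, baseline_rate)
    if mode != "averaged":
        raise ValueError("mode must be 'instantaneous' or 'averaged'")
    from scipy.integrate import simpson

    ts = np.linspace(0.0, t, 2049)
    mean_amount = float(simpson(driving(ts), x=ts)) / t
    return interaction_effect_max(g, mean_amount, baseline_rate)
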