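"""Synthetic study designs: reference scenarios, noisy replicates, datasets.

The baseline scenario is the reference parameter set used throughout the
package's simulation studies: doses 0.6 and 1.0 (10^3 mg), drug X rates all
0.5 1/h, drug Y rates 0.6/0.5/0.4/0.3 1/h, no interactions.  Noisy replicate
sets emulate a measurement-noise design: per sampling time, a zero-mean
Gaussian perturbation with standard deviation proportional to the amount
(sd_frac * amount, default 0.1), truncated at zero, with 100 replicates by
default.  The alternative constant-sd reading of "noise scaled to the
amount" would drown a curve peaking at ~0.165 and is inconsistent with the
tight replicate CIs the design is meant to produce; the sd model is
nevertheless switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .estimate import ObservedPair
from .metrics import _sweep_lower_bound
from .model import (CoupledSystem, DrugInteractions, DrugRates, DrugSpec,
                    Trajectory, simulate)

__all__ = ["NoiseSpec", "BASELINE", "make_scenario", "add_noise",
           "make_dataset", "observed_pairs", "DEFAULT_SAMPLING_TIMES"]

#: Default sampling schedule (h): the 13-point 0.25-12 h clinical-style grid.
DEFAULT_SAMPLING_TIMES = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5,
                          3.0, 4.0, 6.0, 8.0, 12.0)

BASELINE = {
    "dose_x": 0.6, "dose_y": 1.0,
    "rates_x": (0.5, 0.5, 0.5, 0.5),
    "rates_y": (0.6, 0.5, 0.4, 0.3),
}

_INTERACTION_FIELDS = ("g_abs", "g_cp", "g_pc", "g_el")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise design for replicate generation.

    sd_frac : noise sd as a fraction of the amount at each sampling time
        (``model='proportional'``) or an absolute sd on the amount scale
        (``model='additive'``).
    n_reps : number of replicate observation sets.
    seed : RNG seed; identical seeds give identical replicates.
    times : sampling schedule in hours.
    """

    sd_frac: float = 0.1
    n_reps: int = 100
    seed: int = 0
    times: tuple = DEFAULT_SAMPLING_TIMES
    model: str = "proportional"

    def __post_init__(self) -> None:
        if self.sd_frac < 0:
            raise ValueError("sd_frac must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.model not in ("proportional", "additive"):
            raise ValueError("noise model must be 'proportional' or 'additive'")


def make_scenario(**overrides) -> CoupledSystem:
    """The baseline two-drug scenario, with optional interaction overrides.

    Overrides are named ``<coef>_<drug>``, e.g. ``g_abs_x=0.4`` sets drug X's
    absorption interaction coefficient.  Doses and rates can be overridden
    with ``dose_x``/``dose_y``/``rates_x``/``rates_y`` (4-tuples).  An
    interaction override below its feasibility bound (the effective rate
    could turn negative) is rejected with the violated bound named.
    """
    params = dict(BASELINE)
    g = {f"{f}_{d}": 0.0 for f in _INTERACTION_FIELDS for d in ("x", "y")}
    for key, value in overrides.items():
        if key in params:
            params[key] = value
        elif key in g:
            g[key] = float(value)
        else:
            raise TypeError(f"unknown scenario override {key!r}")
    system = CoupledSystem(
        drug_x=DrugSpec(dose=params["dose_x"], rates=DrugRates(*params["rates_x"]),
                        interactions=DrugInteractions(
                            *(g[f"{f}_x"] for f in _INTERACTION_FIELDS))),
        drug_y=DrugSpec(dose=params["dose_y"], rates=DrugRates(*params["rates_y"]),
                        interactions=DrugInteractions(
                            *(g[f"{f}_y"] for f in _INTERACTION_FIELDS))),
    )
    for drug in ("x", "y"):
        for f in _INTERACTION_FIELDS:
            value = g[f"{f}_{drug}"]
            if value == 0.0:
                continue
            bound = _sweep_lower_bound(system.uncoupled(), drug, f)
            if value <= bound:
                raise ValueError(
                    f"interaction override {f}_{drug}={value} violates the "
                    f"feasibility bound {f}_{drug} > {bound:.6g}")
    return system


def add_noise(traj: Trajectory, spec: NoiseSpec) -> list[ObservedPair]:
    """Noisy replicate observation sets of both drugs' central amounts.

    Per replicate and sampling time: observed = amount + eps with
    eps ~ N(0, (sd_frac * amount)^2) (or constant sd for the additive
    model), truncated at zero.  Seeded and reproducible.
    """
    times = np.asarray(spec.times, dtype=float)
    if times.size and (times[0] < traj.times[0] or times[-1] > traj.times[-1]):
        raise ValueError("sampling times fall outside the trajectory span")
    if traj.sol is not None:
        x = traj.evaluate(times, "x", "central")
        y = traj.evaluate(times, "y", "central")
    else:
        x = np.interp(times, traj.times, traj.central("x"))
        y = np.interp(times, traj.times, traj.central("y"))
    if spec.model == "proportional":
        sd_x, sd_y = spec.sd_frac * x, spec.sd_frac * y
    else:
        sd_x = np.full_like(x, spec.sd_frac)
        sd_y = np.full_like(y, spec.sd_frac)
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_reps):
        ox = np.maximum(x + rng.normal(0.0, 1.0, size=x.shape) * sd_x, 0.0)
        oy = np.maximum(y + rng.normal(0.0, 1.0, size=y.shape) * sd_y, 0.0)
        out.append(ObservedPair(times_x=times, obs_x=ox, times_y=times, obs_y=oy))
    return out


def _single_regimen(system: CoupledSystem, drug: str) -> CoupledSystem:
    """Monotherapy version: partner dose zero (interactions then inert)."""
    if drug == "x":
        return CoupledSystem(drug_x=system.drug_x,
                             drug_y=replace(system.drug_y, dose=0.0))
    return CoupledSystem(drug_x=replace(system.drug_x, dose=0.0),
                         drug_y=system.drug_y)


def make_dataset(system: CoupledSystem, regimen: str, noise: NoiseSpec,
                 horizon: float | None = None) -> pd.DataFrame:
    """Long-format observation table for one regimen.

    ``regimen`` is ``single-x``, ``single-y`` or ``combined``; single
    regimens zero the partner's dose, so with no coupling the combined
    series equals the single ones.  Output columns follow the package's
    canonical observation schema (one row per replicate, drug and time);
    concentrations are reported against each drug's Vc when present,
    otherwise against a unit reference volume of 1 ml, in g/ml either way.
    """
    regimens = {"single-x": ("x",), "single-y": ("y",), "combined": ("x", "y")}
    if regimen not in regimens:
        raise ValueError(f"unknown regimen {regimen!r}; expected one of {sorted(regimens)}")
    sim_system = system if regimen == "combined" else \
        _single_regimen(system, regimens[regimen][0])
    end = horizon if horizon is not None else max(noise.times) * 1.05
    traj = simulate(sim_system, horizon=end, output_step=min(0.01, end / 100))
    pairs = add_noise(traj, noise)
    label = "single" if regimen.startswith("single") else "combined"
    rows = []
    for rep, pair in enumerate(pairs):
        for drug in regimens[regimen]:
            spec_d = sim_system.drug_x if drug == "x" else sim_system.drug_y
            vc = spec_d.v_central if spec_d.v_central is not None else 1.0
            amounts = pair.obs_x if drug == "x" else pair.obs_y
            times = pair.times_x if drug == "x" else pair.times_y
            rows.append(pd.DataFrame({
                "subject_id": rep,
                "drug": drug,
                "regimen": label,
                "time_h": times,
                "concentration": amounts / vc,
                "conc_unit": "g/ml",
                "dose_mg": spec_d.dose * 1000.0,
                "v_central_ml": vc,
            }))
    return pd.concat(rows, ignore_index=True)


def observed_pairs(table: pd.DataFrame) -> list[ObservedPair]:
    """Rebuild per-subject ObservedPair amount series from a long-format
    combined-regimen table (inverse of :func:`make_dataset`)."""
    if "v_central_ml" not in table.columns:
        raise ValueError("table lacks a v_central_ml column; concentrations "
                         "cannot be converted back to central amounts")
    out = []
    for _, group in table[table["regimen"] == "combined"].groupby("subject_id"):
        gx = group[group["drug"] == "x"].sort_values("time_h")
        gy = group[group["drug"] == "y"].sort_values("time_h")
        if gx.empty or gy.empty:
            raise ValueError("combined regimen requires both drugs per subject")
        out.append(ObservedPair(
            times_x=gx["time_h"].to_numpy(),
            obs_x=gx["concentration"].to_numpy() * gx["v_central_ml"].to_numpy(),
            times_y=gy["time_h"].to_numpy(),
            obs_y=gy["concentration"].to_numpy() * gy["v_central_ml"].to_numpy(),
        ))
    return out
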