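"""File formats: observation tables, scenario configs, result serialisation.

Canonical internal units are 10^3 mg for amounts and hours for time;
concentrations are converted once at ingest using the per-file unit column
and each drug's apparent central volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .estimate import FitResult
from .model import (CONCENTRATION_UNITS, CoupledSystem, DrugInteractions,
                    DrugRates, DrugSpec, Trajectory)

__all__ = ["read_observations", "write_results", "read_results",
           "load_scenario_config", "save_scenario_config", "write_trajectory"]

REQUIRED_COLUMNS = ("subject_id", "drug", "regimen", "time_h",
                    "concentration", "conc_unit", "dose_mg")


class ObservationError(ValueError):
    """Malformed observation table; the message names the offending rows."""


def read_observations(path, fmt: str | None = None, sheet=0,
                      column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-format observation table (CSV or XLSX sheet).

    Required columns: subject_id, drug, regimen ('single'|'combined'),
    time_h, concentration, conc_unit, dose_mg.  ``column_map`` renames
    source headers to the canonical ones.  Times must be non-negative and
    strictly increasing within each (subject, drug, regimen) group; the dose
    must be constant within a group.  Violations are reported with the
    offending file rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        table = pd.read_excel(path, sheet_name=sheet)
    elif fmt == "csv":
        table = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if column_map:
        table = table.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ObservationError(f"missing required column(s): {', '.join(missing)}")

    bad = table.index[table["time_h"] < 0].tolist()
    if bad:
        raise ObservationError(f"negative time_h at row(s) {bad}")
    bad = table.index[table["concentration"] < 0].tolist()
    if bad:
        raise ObservationError(f"negative concentration at row(s) {bad}")
    unknown = sorted(set(table["conc_unit"]) - set(CONCENTRATION_UNITS))
    if unknown:
        raise ObservationError(f"unknown concentration unit(s): {unknown}")
    bad_reg = sorted(set(table["regimen"]) - {"single", "combined"})
    if bad_reg:
        raise ObservationError(f"unknown regimen value(s): {bad_reg}")
    for key, group in table.groupby(["subject_id", "drug", "regimen"]):
        t = group["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ObservationError(f"non-increasing times within group {key} "
                                   f"(rows {group.index.tolist()})")
        if group["dose_mg"].nunique() > 1:
            raise ObservationError(f"dose_mg not constant within group {key}")
    return table


def write_results(result, path, fmt: str | None = None,
                  provenance: dict | None = None) -> None:
    """Write a FitResult (JSON) or a metrics/summary table (CSV/JSON).

    JSON output of a FitResult embeds a provenance block (package version,
    seed, bounds, lambda, scale) plus any extra entries supplied by the
    caller, so a run can be reproduced from its result file alone.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "json"
    if isinstance(result, FitResult):
        payload = result.to_dict()
        payload["provenance"] = {"package_version": _pkg_version,
                                 "seed": result.seed,
                                 "lambda": result.lambda_,
                                 "amount_scale": result.amount_scale,
                                 **(provenance or {})}
        if fmt != "json":
            raise ValueError("FitResult serialises to JSON")
        path.write_text(json.dumps(payload, indent=2))
        return
    if isinstance(result, pd.DataFrame):
        if fmt == "csv":
            result.to_csv(path, index=False)
        elif fmt == "json":
            payload = {"table": result.to_dict(orient="records")}
            if provenance:
                payload["provenance"] = {"package_version": _pkg_version, **provenance}
            path.write_text(json.dumps(payload, indent=2))
        else:
            raise ValueError(f"unknown format {fmt!r}")
        return
    raise TypeError(f"cannot serialise {type(result).__name__}")


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())


def write_trajectory(traj: Trajectory, path) -> None:
    """Tidy CSV with columns time_h, drug, compartment, amount."""
    traj.to_frame().to_csv(path, index=False)


# --- scenario configuration -------------------------------------------------

def save_scenario_config(system: CoupledSystem, path, horizon: float = 40.0,
                         output_step: float = 0.001, seed: int | None = None) -> None:
    cfg = {
        "doses": {"x": float(system.drug_x.dose), "y": float(system.drug_y.dose)},
        "rates": {d: [float(v) for v in spec.rates.as_array()]
                  for d, spec in (("x", system.drug_x), ("y", system.drug_y))},
        "interactions": {d: [float(v) for v in spec.interactions.as_array()]
                         for d, spec in (("x", system.drug_x), ("y", system.drug_y))},
        "v_central": {"x": None if system.drug_x.v_central is None else float(system.drug_x.v_central),
                      "y": None if system.drug_y.v_central is None else float(system.drug_y.v_central)},
        "horizon": horizon, "output_step": output_step, "seed": seed,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_scenario_config(path) -> tuple[CoupledSystem, dict]:
    """Read a scenario YAML; returns the system and the run settings dict
    (horizon, output_step, seed)."""
    cfg = yaml.safe_load(Path(path).read_text())
    for key in ("doses", "rates", "interactions"):
        if key not in cfg:
            raise ValueError(f"scenario config is missing {key!r}")
    vc = cfg.get("v_central", {}) or {}
    drugs = {}
    for d in ("x", "y"):
        drugs[d] = DrugSpec(
            dose=float(cfg["doses"][d]),
            rates=DrugRates(*[float(v) for v in cfg["rates"][d]]),
            interactions=DrugInteractions(*[float(v) for v in cfg["interactions"][d]]),
            v_central=None if vc.get(d) is None else float(vc[d]),
        )
    system = CoupledSystem(drug_x=drugs["x"], drug_y=drugs["y"])
    settings = {"horizon": float(cfg.get("horizon", 40.0)),
                "output_step": float(cfg.get("output_step", 0.001)),
                "seed": cfg.get("seed")}
    return system, settings
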