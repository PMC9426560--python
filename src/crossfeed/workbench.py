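"""Reproduction drivers chaining the analysis stages end to end.

Four named computational experiments cover the package's headline results:

* ``kinetics-refit``   -- regenerate dose-response data from the bundled
  wild-type rate laws, refit every form, and report parameter recovery plus
  the peak-growth analytics.
* ``energetics``       -- the per-guild ATP yields and producer opportunity
  costs from the stoichiometric ledger.
* ``buffer-context``   -- generalist vs acetate-exchanging consortium batch
  simulations at weak (6.3 mM) and conventional (64 mM) phosphate buffering.
* ``push-pull``        -- the consortium secretion-yield sweep from pull-like
  (0.26 g acid / g biomass) to push-like (1.0 g/g).

Every run is deterministic given the seed; each stage writes plain CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .energetics import default_ledger
from .fitting import fit
from .kinetics import WILDTYPE_MODELS, peak_growth
from .presets import scenario
from .simulation import compare_contexts, sweep_secretion
from .synthdata import gen_dose_response

EXPERIMENTS = ("kinetics-refit", "energetics", "buffer-context", "push-pull")

PUSH_PULL_YIELDS = (0.26, 0.38, 0.5, 1.0)
BUFFER_LEVELS_MM = (6.3, 64.0)


class UnknownExperimentError(KeyError):
    def __init__(self, name: str):
        super().__init__(f"unknown experiment {name!r}; available: {EXPERIMENTS}")


def reproduce(experiment: str, seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Run a named experiment and return (and optionally write) its bundle."""
    if experiment == "kinetics-refit":
        bundle = _kinetics_refit(seed)
    elif experiment == "energetics":
        bundle = _energetics()
    elif experiment == "buffer-context":
        bundle = _buffer_context()
    elif experiment == "push-pull":
        bundle = _push_pull()
    else:
        raise UnknownExperimentError(experiment)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), experiment, seed)
    return bundle


REFIT_GLUCOSE_LEVELS = (0.01, 1.0, 56.0)  # mM; kg is unidentifiable at one level


def _log_grid(lo: float, hi: float, n: int = 24) -> np.ndarray:
    """Dose grid with log-spaced dilutions plus a zero-dose control, matching
    how dose-response experiments resolve sub-mM half-saturation constants."""
    return np.concatenate([[0.0], np.geomspace(lo, hi, n)])


def refit_dataset(name: str, noise_sd: float = 0.0, replicates: int = 1,
                  seed: int = 0):
    """Self-generated dose-response dataset for one bundled wild-type law.

    Sole-acid laws get a log-spaced acid grid; glucose-coupled laws
    additionally vary the glucose co-substrate across three levels, without
    which the glucose half-saturation cannot be estimated.
    """
    from .fitting import DoseResponseDataset

    model = WILDTYPE_MODELS[name]
    grids = {
        "acetic_sole": _log_grid(0.01, 2.5),
        "lactic_sole": _log_grid(0.001, 1.2),
        "acetic_glucose": _log_grid(0.01, 3.0),
        "lactic_glucose": _log_grid(0.001, 1.0),
    }
    grid = grids[name]
    if name.endswith("_glucose"):
        parts = [
            gen_dose_response(model, grid, noise_sd, replicates=replicates,
                              seed=seed + 1000 * i, co_substrate_mM=g).data
            for i, g in enumerate(REFIT_GLUCOSE_LEVELS)
        ]
        return DoseResponseDataset(data=pd.concat(parts, ignore_index=True))
    return gen_dose_response(model, grid, noise_sd, replicates=replicates, seed=seed)


def _kinetics_refit(seed: int) -> dict:
    rows = []
    for name in ("acetic_sole", "lactic_sole", "acetic_glucose", "lactic_glucose"):
        model = WILDTYPE_MODELS[name]
        data = refit_dataset(name, noise_sd=0.0, replicates=1, seed=seed)
        res = fit(data, model.form_id)
        for pname, true in model.params.items():
            rows.append(
                {
                    "dataset": name,
                    "param": pname,
                    "true": true,
                    "fitted": res.model.params[pname],
                    "rel_err": abs(res.model.params[pname] - true) / true,
                    "r_squared": res.r_squared,
                }
            )
    peaks = []
    for name, co in (("acetic_sole", None), ("lactic_sole", None),
                     ("lactic_glucose", {"G": 56.0})):
        pk = peak_growth(WILDTYPE_MODELS[name], co_state=co)
        peaks.append({"model": name, "argmax_mM": pk.argmax, "mu_peak": pk.mu_max})
    return {"recovery": pd.DataFrame(rows), "peaks": pd.DataFrame(peaks)}


def _energetics() -> dict:
    ledger = default_ledger()
    values = {
        "WT": ledger.atp_yield("wt"),
        "ProdA": ledger.atp_yield("prodA"),
        "ProdL": ledger.atp_yield("prodL"),
        "ConsA": ledger.atp_yield("consA"),
        "ConsL": ledger.atp_yield("consL"),
        "opp_A": ledger.opportunity_cost("prodA", "wt"),
        "opp_L": ledger.opportunity_cost("prodL", "wt"),
    }
    return {"atp": values}


def _buffer_context() -> dict:
    cons = scenario("aae")
    wt = scenario("wt")
    result = compare_contexts(cons, wt, BUFFER_LEVELS_MM)
    rows = []
    for level, entry in result.items():
        for kind in ("consortium", "generalist"):
            rep = entry[kind]["report"]
            rows.append({"phosphate_mM": level, "culture": kind, **rep.as_dict()})
    return {"metrics": pd.DataFrame(rows), "detail": result}


def _push_pull() -> dict:
    base = scenario("aae")
    table = sweep_secretion(base, PUSH_PULL_YIELDS)
    return {"sweep": table}


def _write_bundle(bundle: dict, out_dir: Path, experiment: str, seed: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, value in bundle.items():
        if isinstance(value, pd.DataFrame):
            path = out_dir / f"{experiment}-{key}.csv"
            value.to_csv(path, index=False)
            written.append(path.name)
        elif isinstance(value, dict) and key != "detail":
            path = out_dir / f"{experiment}-{key}.json"
            path.write_text(json.dumps(value, indent=2, default=float))
            written.append(path.name)
    manifest = {
        "experiment": experiment,
        "seed": seed,
        "package_version": __version__,
        "files": written,
        "config_hash": hashlib.sha256(
            json.dumps({"experiment": experiment, "seed": seed}).encode()
        ).hexdigest()[:16],
    }
    (out_dir / f"{experiment}-manifest.json").write_text(json.dumps(manifest, indent=2))
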