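"""Specific-growth-rate laws for organic-acid and pH inhibition.

Six closed forms cover the wild-type E. coli dose-response behavior on acetic
and lactic acid, with and without glucose, plus pH alone and a combined
multi-stress law:

======================  ======================================================
form_id                 mu(state)
======================  ======================================================
monod_haldane_exp       mu_max * S/(ks+S) * exp(-S/ki)
monod_product_exp       mu_max * G/(kg+G) * exp(-k*A)
dual_substrate_exp      mu_max * [G/(kg+G) + L/(kl+L)] * exp(-alpha*L)
linear_pH               mu_max * (1 - H/h_star)
ghose_tyagi             mu_max * S/(ks+S) * (1 - P/p_star)
combined_stress         mu_max * G/(kg+G) * (1 - H/h_star) * exp(-k*A)
======================  ======================================================

Organic-acid concentrations (S, A, L, P) are the PROTONATED species in mM --
the uncharged form crosses membranes and mediates inhibition -- and are
obtained from totals via :mod:`crossfeed.acidbase`.  H is mol/L.  ``alpha`` is
per mM protonated lactate (the printed "mmol^-1" read on the same mM basis as
every other concentration in the parameter table).  Negative values of the
linear terms are clamped to zero: the laws model growth arrest, not death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .constants import load_constants

__all__ = [
    "InhibitionModel",
    "PeakResult",
    "FORM_PARAMS",
    "FORM_STATE_VARS",
    "evaluate",
    "peak_growth",
    "rate_surface",
    "wildtype_model",
    "WILDTYPE_MODELS",
]

# parameter names per form (mu_max first by convention)
FORM_PARAMS: dict[str, tuple[str, ...]] = {
    "monod_haldane_exp": ("mu_max", "ks", "ki"),
    "monod_product_exp": ("mu_max", "kg", "k"),
    "dual_substrate_exp": ("mu_max", "kg", "kl", "alpha"),
    "linear_pH": ("mu_max", "h_star"),
    "ghose_tyagi": ("mu_max", "ks", "p_star"),
    "combined_stress": ("mu_max", "kg", "k", "h_star"),
}

# state variables each form reads
FORM_STATE_VARS: dict[str, tuple[str, ...]] = {
    "monod_haldane_exp": ("S",),
    "monod_product_exp": ("G", "A"),
    "dual_substrate_exp": ("G", "L"),
    "linear_pH": ("H",),
    "ghose_tyagi": ("S", "P"),
    "combined_stress": ("G", "H", "A"),
}

# the inhibitor variable a form has an interior optimum in (None if monotone)
_PEAK_VAR: dict[str, str | None] = {
    "monod_haldane_exp": "S",
    "monod_product_exp": None,
    "dual_substrate_exp": "L",
    "linear_pH": None,
    "ghose_tyagi": None,
    "combined_stress": None,
}


class KineticsConfigError(KeyError):
    """A model form was asked to evaluate without a required state variable."""


@dataclass(frozen=True)
class InhibitionModel:
    """A growth-rate law: closed-form identifier plus parameter values."""

    form_id: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.form_id not in FORM_PARAMS:
            raise ValueError(
                f"unknown form {self.form_id!r}; choose from {sorted(FORM_PARAMS)}"
            )
        missing = set(FORM_PARAMS[self.form_id]) - set(self.params)
        if missing:
            raise ValueError(f"{self.form_id} missing params {sorted(missing)}")
        for name in FORM_PARAMS[self.form_id]:
            if self.params[name] <= 0:
                raise ValueError(f"{self.form_id} param {name} must be > 0")

    def __call__(self, **state: float) -> float:
        return evaluate(self, state)


def _require(state: Mapping[str, float], form_id: str) -> tuple[float, ...]:
    vals = []
    for var in FORM_STATE_VARS[form_id]:
        if var not in state:
            raise KineticsConfigError(
                f"form {form_id!r} requires state variable {var!r}"
            )
        v = state[var]
        if v < 0:
            raise ValueError(f"state variable {var} must be >= 0, got {v}")
        vals.append(float(v))
    return tuple(vals)


def evaluate(model: InhibitionModel, state: Mapping[str, float]) -> float:
    """Evaluate a growth-rate law; the result is clamped at zero."""
    p = model.params
    fid = model.form_id
    if fid == "monod_haldane_exp":
        (s,) = _require(state, fid)
        mu = p["mu_max"] * (s / (p["ks"] + s)) * math.exp(-s / p["ki"]) if s > 0 else 0.0
    elif fid == "monod_product_exp":
        g, a = _require(state, fid)
        mu = p["mu_max"] * (g / (p["kg"] + g)) * math.exp(-p["k"] * a)
    elif fid == "dual_substrate_exp":
        g, l = _require(state, fid)
        mu = (
            p["mu_max"]
            * (g / (p["kg"] + g) + l / (p["kl"] + l))
            * math.exp(-p["alpha"] * l)
        )
    elif fid == "linear_pH":
        (h,) = _require(state, fid)
        mu = p["mu_max"] * (1.0 - h / p["h_star"])
    elif fid == "ghose_tyagi":
        s, prod = _require(state, fid)
        mu = p["mu_max"] * (s / (p["ks"] + s)) * (1.0 - prod / p["p_star"])
    elif fid == "combined_stress":
        g, h, a = _require(state, fid)
        mu = (
            p["mu_max"]
            * (g / (p["kg"] + g))
            * (1.0 - h / p["h_star"])
            * math.exp(-p["k"] * a)
        )
    else:  # pragma: no cover - guarded in __post_init__
        raise AssertionError(fid)
    return max(mu, 0.0)


@dataclass(frozen=True)
class PeakResult:
    """Location and value of the growth-rate optimum in the inhibitor variable."""

    argmax: float  # mM (protonated acid)
    mu_max: float  # 1/h
    interior: bool  # False when the form is monotone and a boundary was returned
    closed_form: float | None = None  # analytic argmax where one exists


def haldane_argmax(ks: float, ki: float) -> float:
    """Analytic optimum of S/(ks+S)*exp(-S/ki): root of S^2 + ks*S - ks*ki."""
    return 0.5 * (-ks + math.sqrt(ks * ks + 4.0 * ks * ki))


def peak_growth(
    model: InhibitionModel,
    co_state: Mapping[str, float] | None = None,
    upper: float | None = None,
    xatol: float = 1e-12,
) -> PeakResult:
    """Maximize the rate law over its inhibitor concentration.

    ``co_state`` supplies the fixed non-optimized variables (e.g. G for the
    dual-substrate form).  For the Haldane-exponential form the numeric
    optimum is cross-checked against the closed form.  Monotone forms have no
    interior optimum; the boundary value at concentration 0 is returned with
    ``interior=False``.
    """
    var = _PEAK_VAR[model.form_id]
    co = dict(co_state or {})
    if var is None:
        state = dict(co)
        state.setdefault("S", 0.0)
        state.setdefault("A", 0.0)
        state.setdefault("P", 0.0)
        state.setdefault("H", 0.0)
        return PeakResult(argmax=0.0, mu_max=evaluate(model, state), interior=False)

    if model.form_id == "monod_haldane_exp":
        scale = model.params["ki"]
        closed = haldane_argmax(model.params["ks"], model.params["ki"])
    else:
        scale = 1.0 / model.params["alpha"]
        closed = None
    hi = upper if upper is not None else 50.0 * scale

    def neg(x: float) -> float:
        return -evaluate(model, {**co, var: x})

    res = minimize_scalar(neg, bounds=(0.0, hi), method="bounded",
                          options={"xatol": xatol})
    argmax = float(res.x)
    # Function-value-only minimizers locate a quadratic optimum no better
    # than sqrt(machine eps) in x; polish by root-finding the central-
    # difference derivative, which is accurate to ~eps^(2/3).
    if 0.0 < argmax < hi:
        h = 6e-6 * argmax

        def dneg(x: float) -> float:
            return (neg(x + h) - neg(x - h)) / (2.0 * h)

        lo_b = max(argmax - 8.0 * h, h)
        hi_b = min(argmax + 8.0 * h, hi - h)
        if lo_b < hi_b and dneg(lo_b) < 0.0 < dneg(hi_b):
            argmax = float(brentq(dneg, lo_b, hi_b, xtol=1e-15, rtol=1e-15))
    return PeakResult(
        argmax=argmax,
        mu_max=evaluate(model, {**co, var: argmax}),
        interior=True,
        closed_form=closed,
    )


def rate_surface(
    model: InhibitionModel,
    grids: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Tabulate mu over the cartesian product of the supplied state grids.

    ``grids`` maps state-variable names (a ``pH`` key is converted to H) to
    1-D arrays.  Returns a long-format DataFrame with one row per grid point.
    """
    names = list(grids)
    if not names or any(len(np.atleast_1d(grids[n])) == 0 for n in names):
        raise ValueError("grids must be non-empty")
    arrays = [np.atleast_1d(np.asarray(grids[n], dtype=float)) for n in names]
    mesh = np.meshgrid(*arrays, indexing="ij")
    flat = [m.ravel() for m in mesh]
    rows = []
    for point in zip(*flat):
        state = dict(zip(names, point))
        if "pH" in state:
            state["H"] = 10.0 ** (-state.pop("pH"))
        rows.append(evaluate(model, state))
    out = pd.DataFrame({n: f for n, f in zip(names, flat)})
    out["mu"] = rows
    return out


def _bundled_models() -> dict[str, InhibitionModel]:
    consts = load_constants()
    return {
        name: InhibitionModel(form_id=row["form_id"], params=dict(row["params"]))
        for name, row in consts["inhibition_models"].items()
    }


WILDTYPE_MODELS: dict[str, InhibitionModel] = _bundled_models()


def wildtype_model(name: str) -> InhibitionModel:
    """Fetch a bundled wild-type parameterization by name
    (``acetic_sole``, ``lactic_sole``, ``acetic_glucose``, ``lactic_glucose``,
    ``ph``, ``combined_acetic``)."""
    try:
        return WILDTYPE_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(WILDTYPE_MODELS)}"
        ) from None
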