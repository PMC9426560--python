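"""Nonlinear least-squares fitting of inhibition models to dose-response data.

Datasets are tables of specific growth rate versus inhibitor/substrate
concentration (one row per measured condition).  Fitting uses the
Levenberg-Marquardt algorithm (via lmfit); goodness of fit is reported as
R^2 against the mean model and as the chi-square statistic.  Unweighted
least squares is the default; supply ``weighted=True`` to use 1/sd^2 weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .kinetics import (
    FORM_PARAMS,
    FORM_STATE_VARS,
    InhibitionModel,
    evaluate,
)

__all__ = [
    "DoseResponseDataset",
    "FitResult",
    "fit",
    "fit_all_forms",
    "IncompatibleFormError",
]

MAX_ITER = 500


class IncompatibleFormError(ValueError):
    """The dataset lacks columns a model form requires."""


@dataclass(frozen=True)
class DoseResponseDataset:
    """Growth-rate dose-response table.

    ``data`` columns: ``conc_mM`` (the organic-acid variable), ``mu`` (1/h);
    optional ``co_substrate_mM`` (glucose), ``pH``, ``sd``, ``n``.
    ``basis`` records whether ``conc_mM`` is the protonated or the total acid
    concentration; fitting is agnostic but the flag travels with the data.
    """

    data: pd.DataFrame
    basis: str = "protonated"  # or "total"

    def __post_init__(self) -> None:
        df = self.data
        if "conc_mM" not in df or "mu" not in df:
            raise ValueError("dataset needs conc_mM and mu columns")
        if (df["mu"] < 0).any() or (df["conc_mM"] < 0).any():
            raise ValueError("concentrations and growth rates must be >= 0")
        if self.basis not in ("protonated", "total"):
            raise ValueError("basis must be 'protonated' or 'total'")

    @classmethod
    def from_csv(cls, path, basis: str | None = None) -> "DoseResponseDataset":
        df = pd.read_csv(path)
        b = basis or (df["basis"].iloc[0] if "basis" in df else "protonated")
        return cls(data=df.drop(columns=["basis"], errors="ignore"), basis=b)

    def state_rows(self, form_id: str) -> list[dict[str, float]]:
        """Translate table rows into the state mapping a form evaluates."""
        needed = FORM_STATE_VARS[form_id]
        df = self.data
        rows = []
        for _, r in df.iterrows():
            state: dict[str, float] = {}
            for var in needed:
                if var in ("S", "A", "L", "P"):
                    state[var] = float(r["conc_mM"])
                elif var == "G":
                    if "co_substrate_mM" not in df:
                        raise IncompatibleFormError(
                            f"form {form_id!r} needs a co_substrate_mM column"
                        )
                    state[var] = float(r["co_substrate_mM"])
                elif var == "H":
                    if "pH" not in df:
                        raise IncompatibleFormError(
                            f"form {form_id!r} needs a pH column"
                        )
                    state[var] = 10.0 ** (-float(r["pH"]))
            rows.append(state)
        return rows


@dataclass(frozen=True)
class FitResult:
    model: InhibitionModel
    r_squared: float
    chi_square: float
    param_uncertainties: Mapping[str, float | None]
    converged: bool
    n_iterations: int
    rss: float
    tss_defined: bool = True

    @property
    def n_params(self) -> int:
        return len(FORM_PARAMS[self.model.form_id])


def _default_initials(dataset: DoseResponseDataset, form_id: str) -> dict[str, float]:
    """Deterministic, data-driven starting values.

    mu_max starts at the largest observed rate, half-saturations at the
    smallest nonzero concentration, inhibition constants at the concentration
    of the rate maximum; this avoids any dependence on random seeds.
    """
    df = dataset.data
    mu_max0 = float(df["mu"].max())
    nonzero = df.loc[df["conc_mM"] > 0, "conc_mM"]
    ks0 = float(nonzero.min()) if len(nonzero) else 0.1
    conc_at_peak = float(df.loc[df["mu"].idxmax(), "conc_mM"])
    ki0 = conc_at_peak if conc_at_peak > 0 else max(float(df["conc_mM"].max()), 1.0)
    # the observed peak understates mu_max whenever inhibition is active, and
    # a start exactly midway between the bounds stalls the bounded optimizer
    init = {"mu_max": max(1.2 * mu_max0, 1e-6)}
    for name in FORM_PARAMS[form_id]:
        if name == "mu_max":
            continue
        if name in ("ks", "kg", "kl"):
            init[name] = max(ks0, 1e-6)
        elif name in ("ki", "p_star"):
            init[name] = max(ki0, 1e-6)
        elif name in ("k", "alpha"):
            span = float(df["conc_mM"].max())
            init[name] = 1.0 / span if span > 0 else 1.0
        elif name == "h_star":
            init[name] = 10.0 ** -4.5
    return init


def fit(
    dataset: DoseResponseDataset,
    form_id: str,
    initial_params: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    weighted: bool = False,
) -> FitResult:
    """Levenberg-Marquardt fit of one model form to a dose-response table.

    When no ``initial_params`` are supplied, a deterministic multi-start is
    used: the data-driven initials plus a small grid of scale factors on the
    inhibition/half-saturation parameters, keeping the start with the lowest
    residual sum of squares.  The correlated parameter ridges of the
    substrate-inhibition forms otherwise trap the local optimizer.
    """
    if form_id not in FORM_PARAMS:
        raise KeyError(f"unknown form {form_id!r}")
    df = dataset.data
    n_par = len(FORM_PARAMS[form_id])
    if len(df) < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} rows to fit {form_id}")
    states = dataset.state_rows(form_id)
    mu_obs = df["mu"].to_numpy(dtype=float)

    init = _default_initials(dataset, form_id)
    if initial_params:
        init.update(initial_params)
    mu_cap = 2.0 * max(float(df["mu"].max()), 1e-6)

    if weighted:
        if "sd" not in df:
            raise ValueError("weighted fit requires an sd column")
        w = 1.0 / df["sd"].to_numpy(dtype=float)
    else:
        w = None

    def residual(p: lmfit.Parameters) -> np.ndarray:
        vals = {k: p[k].value for k in p}
        model = InhibitionModel(form_id=form_id, params=vals)
        pred = np.array([evaluate(model, s) for s in states])
        r = pred - mu_obs
        return r * w if w is not None else r

    def make_params(start: Mapping[str, float]) -> lmfit.Parameters:
        params = lmfit.Parameters()
        for name in FORM_PARAMS[form_id]:
            lo, hi = 1e-12, np.inf
            if name == "mu_max":
                hi = mu_cap
            if bounds and name in bounds:
                lo, hi = bounds[name]
            value = start[name]
            # keep starts strictly inside the bounds: a start on (or clipped
            # to) a bound has zero gradient under the optimizer's transform
            if np.isfinite(hi):
                span = hi - lo
                value = min(max(value, lo + 0.02 * span), hi - 0.02 * span)
            else:
                value = max(value, lo * 1.05 if lo > 0 else 1e-12)
            params.add(name, value=value, min=lo, max=hi)
        return params

    scaled = [n for n in FORM_PARAMS[form_id] if n != "mu_max"]
    if initial_params:
        starts = [dict(init)]
    else:
        starts = []
        for factors in product((0.2, 1.0, 5.0), repeat=len(scaled)):
            s = dict(init)
            for name, f in zip(scaled, factors):
                s[name] = init[name] * f
            starts.append(s)

    result = None
    for start in starts:
        res = lmfit.minimize(
            residual, make_params(start), method="leastsq",
            max_nfev=MAX_ITER * (n_par + 1), xtol=1e-12, ftol=1e-12,
        )
        if result is None or res.chisqr < result.chisqr:
            result = res

    fitted = {k: result.params[k].value for k in result.params}
    model = InhibitionModel(form_id=form_id, params=fitted)
    pred = np.array([evaluate(model, s) for s in states])
    rss = float(np.sum((pred - mu_obs) ** 2))
    tss = float(np.sum((mu_obs - mu_obs.mean()) ** 2))
    tss_defined = tss > 0
    r2 = 1.0 - rss / tss if tss_defined else float("nan")
    uncert = {
        k: (float(result.params[k].stderr) if result.params[k].stderr else None)
        for k in result.params
    }
    return FitResult(
        model=model,
        r_squared=r2,
        chi_square=float(result.chisqr),
        param_uncertainties=uncert,
        converged=bool(result.success),
        n_iterations=int(result.nfev),
        rss=rss,
        tss_defined=tss_defined,
    )


def fit_all_forms(
    dataset: DoseResponseDataset,
    forms: Sequence[str],
    **fit_kw,
) -> list[FitResult]:
    """Fit candidate forms and rank them: R^2 descending, then fewer
    parameters, then form_id lexicographic (fully deterministic)."""
    results = []
    missing: list[str] = []
    for form_id in forms:
        try:
            results.append(fit(dataset, form_id, **fit_kw))
        except IncompatibleFormError as err:
            missing.append(f"{form_id}: {err}")
    if not results:
        raise IncompatibleFormError(
            "no candidate form is compatible with the dataset columns: "
            + "; ".join(missing)
        )
    results.sort(key=lambda r: (-round(r.r_squared, 12), r.n_params, r.model.form_id))
    return results
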