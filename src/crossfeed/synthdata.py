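"""Seeded generators emulating the study's observables.

Two generators cover everything the analysis stages consume:

* dose-response tables (growth rate vs concentration with additive Gaussian
  noise) feeding :mod:`crossfeed.fitting`;
* batch observation tables sampled from a simulated trajectory roughly once
  per biomass doubling, with multiplicative log-normal OD noise, HPLC readouts
  censored below a 0.1 mM detection limit, and guild ratios measured by
  Poisson drop-plate counting (3-30 colonies per 10-uL drop) with the producer
  back-calculated as total-on-glucose minus consumer-on-acid counts.

Every generator is a pure function of its inputs and the integer seed.
Censored cells carry NaN in the value column plus a boolean flag, so they are
distinguishable from true zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import DoseResponseDataset
from .kinetics import FORM_STATE_VARS, InhibitionModel, evaluate
from .metrics import reconstruct_proton_load
from .simulation import Trajectory

__all__ = [
    "ObservationSpec",
    "gen_dose_response",
    "gen_batch_observations",
    "observations_to_trajectory",
]


@dataclass(frozen=True)
class ObservationSpec:
    """How a batch trajectory is turned into noisy observations."""

    sampling: str | Sequence[float] = "doubling"  # or explicit time grid (h)
    od_noise_cv: float = 0.03  # multiplicative log-normal, mean 1
    hplc_noise_sd: float = 0.0  # mM additive
    hplc_lod: float = 0.1  # mM detection limit
    ph_noise_sd: float = 0.0
    od_to_cdw: float = 0.4  # g cdw/L per OD600
    count_drops: int = 10
    drop_volume_ml: float = 0.01
    cfu_per_g: float = 2.5e12  # CFU per g cdw (so g/L -> CFU/mL via /1000)
    countable_range: tuple[float, float] = (3.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.od_noise_cv, self.hplc_noise_sd, self.hplc_lod,
               self.ph_noise_sd) < 0:
            raise ValueError("noise parameters and lod must be >= 0")


def gen_dose_response(
    model: InhibitionModel,
    grid: Sequence[float],
    noise_sd: float,
    replicates: int = 3,
    seed: int = 0,
    co_substrate_mM: float | None = None,
    pH: float | None = None,
    basis: str = "protonated",
) -> DoseResponseDataset:
    """Noisy growth-rate dose-response table from a known rate law.

    Each grid concentration yields one row: the mean of ``replicates``
    independent draws mu = max(0, mu_true + N(0, noise_sd)), with the sample
    sd and replicate count recorded.
    """
    grid = np.asarray(grid, dtype=float)
    if (grid < 0).any():
        raise ValueError("grid concentrations must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    needs = FORM_STATE_VARS[model.form_id]
    rows = []
    for conc in grid:
        state: dict[str, float] = {}
        for var in needs:
            if var in ("S", "A", "L", "P"):
                state[var] = conc
            elif var == "G":
                if co_substrate_mM is None:
                    raise ValueError(f"form {model.form_id!r} needs co_substrate_mM")
                state[var] = co_substrate_mM
            elif var == "H":
                if pH is None:
                    raise ValueError(f"form {model.form_id!r} needs pH")
                state[var] = 10.0 ** (-pH)
        mu_true = evaluate(model, state)
        draws = np.maximum(mu_true + rng.normal(0.0, noise_sd, size=replicates), 0.0)
        row = {
            "conc_mM": conc,
            "mu": float(draws.mean()),
            "sd": float(draws.std(ddof=1)) if replicates > 1 else noise_sd,
            "n": replicates,
        }
        if co_substrate_mM is not None:
            row["co_substrate_mM"] = co_substrate_mM
        if pH is not None:
            row["pH"] = pH
        rows.append(row)
    return DoseResponseDataset(data=pd.DataFrame(rows), basis=basis)


def _doubling_sample_indices(time: np.ndarray, biomass: np.ndarray) -> np.ndarray:
    """Indices sampling the trajectory once per doubling of total biomass,
    always including the first and last point."""
    idx = [0]
    ref = biomass[0]
    for i in range(1, len(time)):
        if ref > 0 and biomass[i] >= 2.0 * ref:
            idx.append(i)
            ref = biomass[i]
    if idx[-1] != len(time) - 1:
        idx.append(len(time) - 1)
    return np.array(idx)


def _plate_counts(
    density_cfu_ml: float, rng: np.random.Generator, spec: ObservationSpec
) -> tuple[int, int, float]:
    """Simulate drop plating at the dilution whose expected per-drop count
    falls in the countable range; returns (total colonies, dilution exponent,
    back-calculated CFU/mL)."""
    lo, hi = spec.countable_range
    expected0 = density_cfu_ml * spec.drop_volume_ml
    if expected0 <= 0:
        return 0, 0, 0.0
    # smallest dilution bringing the expectation at or below the upper bound
    d = max(0, math.ceil(math.log10(expected0 / hi))) if expected0 > hi else 0
    counts = int(rng.poisson(10.0 ** (-d) * expected0 * spec.count_drops))
    back = counts / (spec.count_drops * spec.drop_volume_ml) * 10.0 ** d
    return counts, d, back


def gen_batch_observations(
    trajectory: Trajectory,
    spec: ObservationSpec,
) -> pd.DataFrame:
    """Noisy observation table (OD, metabolites, pH, plate counts) from a
    simulated trajectory."""
    t = trajectory.time
    xtot = trajectory.total_biomass
    if isinstance(spec.sampling, str):
        if spec.sampling != "doubling":
            raise ValueError("sampling must be 'doubling' or an explicit grid")
        idx = _doubling_sample_indices(t, xtot)
        times = t[idx]
    else:
        times = np.asarray(spec.sampling, dtype=float)
        if times.min() < t[0] or times.max() > t[-1]:
            raise ValueError("requested samples fall outside the trajectory span")
        idx = None

    def at(series: np.ndarray) -> np.ndarray:
        return series[idx] if idx is not None else np.interp(times, t, series)

    rng = np.random.default_rng(spec.seed)
    x = at(xtot)
    glc = at(trajectory.glucose)
    acid = at(trajectory.acid_total)
    ph = at(trajectory.pH)

    if spec.od_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.od_noise_cv**2))
        od_factor = rng.lognormal(-0.5 * sigma * sigma, sigma, size=len(times))
    else:
        od_factor = np.ones(len(times))
    od = x / spec.od_to_cdw * od_factor

    def hplc(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        noisy = series + (
            rng.normal(0.0, spec.hplc_noise_sd, size=len(series))
            if spec.hplc_noise_sd > 0 else 0.0
        )
        censored = noisy < spec.hplc_lod
        vals = np.where(censored, np.nan, noisy)
        return vals, censored

    glc_obs, glc_cens = hplc(glc)
    acid_obs, acid_cens = hplc(acid)
    ph_obs = ph + (
        rng.normal(0.0, spec.ph_noise_sd, size=len(times))
        if spec.ph_noise_sd > 0 else 0.0
    )

    out = pd.DataFrame(
        {
            "time_h": times,
            "od600": od,
            "glucose_mM": glc_obs,
            "glucose_censored": glc_cens,
            "acid_mM": acid_obs,
            "acid_censored": acid_cens,
            "pH": ph_obs,
        }
    )

    if len(trajectory.biomass) == 2:
        names = list(trajectory.biomass)
        prod_true = at(trajectory.biomass[names[0]])
        cons_true = at(trajectory.biomass[names[1]])
        total_cfu, cons_cfu, prod_back = [], [], []
        for xp, xc in zip(prod_true, cons_true):
            dens_tot = (xp + xc) * spec.cfu_per_g / 1000.0  # CFU/mL
            dens_cons = xc * spec.cfu_per_g / 1000.0
            _, _, tot_b = _plate_counts(dens_tot, rng, spec)
            _, _, con_b = _plate_counts(dens_cons, rng, spec)
            total_cfu.append(tot_b)
            cons_cfu.append(con_b)
            prod_back.append(max(tot_b - con_b, 0.0))
        out["total_cfu_ml"] = total_cfu
        out["consumer_cfu_ml"] = cons_cfu
        out["producer_cfu_ml"] = prod_back
        with np.errstate(invalid="ignore", divide="ignore"):
            out["producer_fraction"] = np.where(
                np.asarray(total_cfu) > 0,
                np.asarray(prod_back) / np.asarray(total_cfu),
                np.nan,
            )
    return out


def observations_to_trajectory(
    observations: pd.DataFrame,
    scenario,
    censored_value: float = 0.0,
    od_to_cdw: float = 0.4,
) -> Trajectory:
    """Rebuild a metrics-ready trajectory from an observation table.

    Biomass is OD times the cdw conversion; the proton load is reconstructed
    from measured pH and acid through the charge-balance inversion.  Censored
    metabolite cells are replaced by ``censored_value`` (default 0, i.e. below
    detection treated as absent).
    """
    medium = scenario.initialized_medium()
    df = observations
    glc = df["glucose_mM"].to_numpy(dtype=float)
    acid = df["acid_mM"].to_numpy(dtype=float)
    glc = np.where(df["glucose_censored"].to_numpy(bool), censored_value, glc)
    acid = np.where(df["acid_censored"].to_numpy(bool), censored_value, acid)
    load = reconstruct_proton_load(
        df["pH"].to_numpy(dtype=float), acid, scenario.acid, medium
    )
    return Trajectory(
        time=df["time_h"].to_numpy(dtype=float),
        biomass={"observed": df["od600"].to_numpy(dtype=float) * od_to_cdw},
        glucose=glc,
        acid_total=acid,
        proton_load=np.maximum(load, 0.0),
        pH=df["pH"].to_numpy(dtype=float),
        scenario=scenario,
    )
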