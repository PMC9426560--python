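"""Batch simulation of glucose-fed monocultures and two-guild consortia.

State variables: biomass of each guild (g cdw/L), glucose (mM), total organic
acid (mM), and the cumulative strong-acid-equivalent proton load (mol/L).
Medium pH is not integrated as a state; it is solved algebraically inside the
right-hand side from the current acid total and proton load through the
charge balance (:func:`crossfeed.acidbase.solve_pH`), which keeps pH exactly
consistent with the phosphate buffer at all times.

Rate laws
---------
Producer guilds (and the generalist) grow on glucose with Monod saturation,
a Ghose-Tyagi linear product term in the protonated acid, and a linear pH
term, all multiplied (the simplest interaction-free composition)::

    mu_p = mu_max * G/(ks+G) * (1 - HA/p_star)_+ * (1 - H/h_star)_+

Consumer guilds grow on the protonated organic acid with the
Haldane-exponential (Aiba-type) substrate-inhibition law times the pH term::

    mu_c = mu_max * HA/(ks+HA) * exp(-HA/ki) * (1 - H/h_star)_+

Mass balances (per liter)::

    dX_i/dt  = mu_i X_i
    dG/dt    = - sum_p (mu_p / Y_XG) X_p / MW_glc * 1000   [mM/h]
    dA/dt    = + sum_p Y_PX mu_p X_p / MW_acid * 1000
               - sum_c (mu_c / Y_XA) X_c / MW_acid * 1000  [mM/h]
    dL/dt    = + sum_i Y_H mu_i X_i                        [mol/L/h]

There is no death term, so biomass is non-decreasing; growth arrests when the
proton concentration reaches the critical threshold h_star, but integration
continues so that stationary-phase acid consumption by the consumer (which
raises pH again) is captured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .acidbase import AcidSpec, MediumSpec, solve_pH

GLUCOSE_MOLAR_MASS = 180.0  # g/mol
H_STAR_DEFAULT = 10.0 ** -4.4  # mol/L; growth impossible above this [H+]

__all__ = [
    "GuildSpec",
    "Scenario",
    "Trajectory",
    "SolverFailure",
    "simulate_batch",
    "sweep_secretion",
    "compare_contexts",
]


class SolverFailure(RuntimeError):
    """ODE integration failed; carries the partial trajectory if available."""

    def __init__(self, message: str, partial: "Trajectory | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class GuildSpec:
    """Kinetic and yield parameters of one guild.

    For producers ``ks`` is the glucose half-saturation (mM), ``product_yield``
    the g organic acid secreted per g biomass, and ``p_star`` the critical
    protonated-acid concentration of the Ghose-Tyagi term.  For consumers
    ``ks``/``ki`` parameterize the Haldane-exponential law on the protonated
    acid and ``biomass_yield`` is g biomass per g acid.
    """

    name: str
    role: Literal["producer", "consumer"]
    mu_max: float  # 1/h
    ks: float  # mM (glucose for producers, protonated acid for consumers)
    biomass_yield: float  # g cdw per g substrate
    proton_yield: float = 0.009  # mol H+ per g cdw (ammonium assimilation)
    product_yield: float = 0.0  # g acid per g cdw (producers only)
    p_star: float | None = None  # mM protonated acid (producers)
    ki: float | None = None  # mM protonated acid (consumers)
    h_star: float | None = H_STAR_DEFAULT  # None disables the pH factor
    glucose_leak_rate: float = 0.0  # 1/h, slow consumer growth on glucose

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.ks <= 0 or self.biomass_yield <= 0:
            raise ValueError(f"{self.name}: mu_max, ks, biomass_yield must be > 0")
        if self.product_yield < 0 or self.proton_yield < 0:
            raise ValueError(f"{self.name}: yields must be >= 0")
        if self.role == "producer" and self.p_star is None:
            raise ValueError(f"{self.name}: producers need p_star")
        if self.role == "consumer" and self.ki is None:
            raise ValueError(f"{self.name}: consumers need ki")

    def growth_rate(self, glucose: float, ha: float, h: float) -> float:
        """Specific growth rate (1/h) at glucose/protonated-acid/[H+] state."""
        ph_factor = 1.0
        if self.h_star is not None:
            ph_factor = max(0.0, 1.0 - h / self.h_star)
        if self.role == "producer":
            mu = (
                self.mu_max
                * glucose / (self.ks + glucose)
                * max(0.0, 1.0 - ha / self.p_star)
                * ph_factor
            )
        else:
            mu = (
                self.mu_max
                * ha / (self.ks + ha)
                * math.exp(-ha / self.ki)
                * ph_factor
            )
        return max(mu, 0.0)


@dataclass(frozen=True)
class Scenario:
    """A batch-culture setup: guilds with inocula, medium, exchanged acid."""

    guilds: tuple[GuildSpec, ...]
    inocula: tuple[float, ...]  # g cdw/L
    medium: MediumSpec
    acid: AcidSpec
    t_end: float = 80.0  # h
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = np.inf
    n_out: int = 400

    def __post_init__(self) -> None:
        if not 1 <= len(self.guilds) <= 2:
            raise ValueError("scenario supports 1 or 2 guilds")
        if len(self.inocula) != len(self.guilds):
            raise ValueError("one inoculum per guild required")
        if any(x0 < 0 for x0 in self.inocula):
            raise ValueError("inocula must be >= 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")

    def initialized_medium(self) -> MediumSpec:
        med = self.medium
        if med.fixed_cation_offset is None:
            med = med.initialize(acids=[(self.acid, med.acid_0)])
        return med


@dataclass
class Trajectory:
    """Simulated batch time courses including the algebraic pH."""

    time: np.ndarray  # h
    biomass: dict[str, np.ndarray]  # g cdw/L per guild
    glucose: np.ndarray  # mM
    acid_total: np.ndarray  # mM
    proton_load: np.ndarray  # mol/L, cumulative
    pH: np.ndarray
    events: list[tuple[str, float]] = field(default_factory=list)
    scenario: Scenario | None = None

    @property
    def total_biomass(self) -> np.ndarray:
        return np.sum(list(self.biomass.values()), axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_h": self.time}
        for name, x in self.biomass.items():
            cols[f"biomass_{name}_g_L"] = x
        cols["glucose_mM"] = self.glucose
        cols["acid_mM"] = self.acid_total
        cols["proton_load_mol_L"] = self.proton_load
        cols["pH"] = self.pH
        return pd.DataFrame(cols)


def _ph_of_state(acid_mM: float, load: float, acid: AcidSpec, medium: MediumSpec) -> float:
    return solve_pH(max(load, 0.0), [(acid, max(acid_mM, 0.0))], medium)


def simulate_batch(scenario: Scenario) -> Trajectory:
    """Integrate a batch culture to ``t_end``.

    Uses the stiff-capable LSODA integrator.  Events are logged (growth arrest
    of all guilds, glucose exhaustion) but not terminal: stationary-phase acid
    consumption continues after arrest of glucose growth.
    """
    guilds = scenario.guilds
    n = len(guilds)
    medium = scenario.initialized_medium()
    acid = scenario.acid
    mw = acid.molar_mass

    y0 = np.array(
        list(scenario.inocula) + [medium.glucose_0, medium.acid_0, 0.0], dtype=float
    )

    def rates(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Per-guild volumetric growth on the main substrate and on leaked
        glucose (g cdw/L/h each), plus the algebraic pH."""
        x = np.maximum(y[:n], 0.0)
        g = max(y[n], 0.0)
        a = max(y[n + 1], 0.0)
        load = max(y[n + 2], 0.0)
        ph = _ph_of_state(a, load, acid, medium)
        h = 10.0 ** (-ph)
        ha = a / (1.0 + 10.0 ** (ph - acid.pKa))
        main = np.array([gld.growth_rate(g, ha, h) for gld in guilds]) * x
        leak = np.zeros(n)
        for i, gld in enumerate(guilds):
            if gld.role == "consumer" and gld.glucose_leak_rate > 0.0:
                ph_factor = max(0.0, 1.0 - h / gld.h_star) if gld.h_star else 1.0
                leak[i] = gld.glucose_leak_rate * g / (g + 0.005) * ph_factor * x[i]
        return main, leak, ph

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        main, leak, _ = rates(y)
        dy = np.zeros_like(y)
        dy[:n] = main + leak
        dg = 0.0
        da = 0.0
        dload = 0.0
        for i, gld in enumerate(guilds):
            dload += gld.proton_yield * (main[i] + leak[i])
            if gld.role == "producer":
                dg -= main[i] / gld.biomass_yield / GLUCOSE_MOLAR_MASS * 1000.0
                da += gld.product_yield * main[i] / mw * 1000.0
            else:
                da -= main[i] / gld.biomass_yield / mw * 1000.0
                # leaked glucose consumed at the guild's biomass yield
                dg -= leak[i] / gld.biomass_yield / GLUCOSE_MOLAR_MASS * 1000.0
        dy[n] = dg
        dy[n + 1] = da
        dy[n + 2] = dload
        return dy

    def ev_exhaustion(t, y):
        return y[n] - 1e-6

    def ev_arrest(t, y):
        main, leak, _ = rates(y)
        return float(np.sum(main + leak)) - 1e-9

    ev_exhaustion.direction = -1
    ev_arrest.direction = -1

    t_eval = np.linspace(0.0, scenario.t_end, scenario.n_out)
    sol = solve_ivp(
        rhs,
        (0.0, scenario.t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=scenario.rel_tol,
        atol=scenario.abs_tol,
        max_step=scenario.max_step,
        events=[ev_exhaustion, ev_arrest],
    )
    if not sol.success:
        partial = None
        if sol.t.size:
            partial = _package(sol.t, sol.y, guilds, acid, medium, [], scenario)
        raise SolverFailure(f"integration failed: {sol.message}", partial)

    events: list[tuple[str, float]] = []
    for label, times in zip(("glucose_exhausted", "growth_arrest"), sol.t_events):
        for te in times:
            events.append((label, float(te)))
    events.sort(key=lambda e: e[1])
    return _package(sol.t, sol.y, guilds, acid, medium, events, scenario)


def _package(t, y, guilds, acid, medium, events, scenario) -> Trajectory:
    n = len(guilds)
    # tolerate solver wiggle below zero, then clamp for reporting
    floor = -1e-6
    if np.min(y) < floor:
        raise SolverFailure(f"state went below tolerance ({np.min(y):.3e})")
    y = np.maximum(y, 0.0)
    ph = np.array(
        [_ph_of_state(a, load, acid, medium) for a, load in zip(y[n + 1], y[n + 2])]
    )
    return Trajectory(
        time=np.asarray(t, dtype=float),
        biomass={g.name: y[i] for i, g in enumerate(guilds)},
        glucose=y[n],
        acid_total=y[n + 1],
        proton_load=y[n + 2],
        pH=ph,
        events=events,
        scenario=scenario,
    )


def sweep_secretion(base: Scenario, product_yields: Sequence[float]) -> pd.DataFrame:
    """Re-simulate ``base`` across producer secretion yields (g acid / g cdw).

    Returns one summary row per yield value, in input order: final consortium
    biomass, glucose consumed, peak acid, final pH.
    """
    producers = [i for i, g in enumerate(base.guilds) if g.role == "producer"]
    if not producers:
        raise ValueError("base scenario has no producer guild")
    rows = []
    for ypx in product_yields:
        guilds = tuple(
            replace(g, product_yield=ypx) if i in producers else g
            for i, g in enumerate(base.guilds)
        )
        traj = simulate_batch(replace(base, guilds=guilds))
        rows.append(
            {
                "product_yield_g_g": ypx,
                "final_biomass_g_L": float(traj.total_biomass[-1]),
                "glucose_consumed_mM": float(traj.glucose[0] - traj.glucose[-1]),
                "peak_acid_mM": float(traj.acid_total.max()),
                "final_pH": float(traj.pH[-1]),
            }
        )
    return pd.DataFrame(rows)


def compare_contexts(
    consortium: Scenario,
    generalist: Scenario,
    buffer_levels_mM: Sequence[float],
) -> dict[float, dict]:
    """Simulate consortium and generalist at each phosphate buffer strength.

    Both scenarios must share glucose_0 and t_end; per level the two
    trajectories and their performance metrics are returned.
    """
    from .metrics import performance_report

    if consortium.medium.glucose_0 != generalist.medium.glucose_0:
        raise ValueError("scenarios must share glucose_0")
    if consortium.t_end != generalist.t_end:
        raise ValueError("scenarios must share t_end")
    out: dict[float, dict] = {}
    for level in buffer_levels_mM:
        entry = {}
        for key, scen in (("consortium", consortium), ("generalist", generalist)):
            med = replace(scen.medium, phosphate_total=level, fixed_cation_offset=None)
            traj = simulate_batch(replace(scen, medium=med))
            entry[key] = {
                "trajectory": traj,
                "report": performance_report(traj),
            }
        out[level] = entry
    return out
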