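"""Weak-acid speciation and medium pH from a proton inventory.

The batch cultures studied here acidify themselves: growth releases strong-acid
equivalents (ammonium assimilation leaves one H+ per nitrogen incorporated) and
secreted organic acids partially dissociate.  Medium pH is obtained by closing
an electroneutrality balance over the phosphate buffer, the organic-acid pool,
water, and a fixed cation offset representing the NaOH/HCl adjustment made when
the medium was prepared.

Units: all concentrations are mM except proton quantities ([H+], proton load,
charge residuals), which are mol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .constants import load_constants

KW = 1e-14  # water ion product at 25 C; concentrations, not activities

__all__ = [
    "AcidSpec",
    "MediumSpec",
    "InfeasibleMediumError",
    "protonated_fraction",
    "speciate",
    "charge_imbalance",
    "solve_pH",
    "ACETIC",
    "LACTIC",
    "medium_preset",
]


class InfeasibleMediumError(ValueError):
    """Charge balance has no root in the admissible pH interval."""


@dataclass(frozen=True)
class AcidSpec:
    """Physicochemical constants of an exchangeable organic acid."""

    name: str
    pKa: float
    molar_mass: float  # g/mol
    combustion_enthalpy: float  # kJ/mol
    formula: dict[str, int]

    def __post_init__(self) -> None:
        if not 0.0 < self.pKa < 14.0:
            raise ValueError(f"pKa must be in (0, 14), got {self.pKa}")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if self.formula.get("C", 0) <= 0:
            raise ValueError("formula must contain carbon")


@dataclass(frozen=True)
class MediumSpec:
    """Phosphate-buffered defined medium.

    ``fixed_cation_offset`` (mol charge / L) absorbs the strong ions (Na+,
    Cl-, ...) that set the configured initial pH; it is computed once by
    :meth:`initialize` so that the charge balance closes exactly at
    ``initial_pH`` with zero proton load, and is held constant thereafter.

    The single-pKa phosphate treatment (H2PO4-/HPO4^2-) is the default: the
    experimentally relevant pH window (4-7.5) lies between pKa1 (~2.15) and
    pKa3 (~12.37), so only the second dissociation buffers appreciably.  Set
    ``full_phosphate=True`` for the triprotic treatment.
    """

    phosphate_total: float  # mM
    initial_pH: float
    phosphate_pKa2: float = 7.20
    glucose_0: float = 0.0  # mM
    acid_0: float = 0.0  # mM total organic acid at t=0
    full_phosphate: bool = False
    phosphate_pKa1: float = 2.15
    phosphate_pKa3: float = 12.37
    fixed_cation_offset: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.phosphate_total < 0:
            raise ValueError("phosphate_total must be >= 0")
        if not 0.0 < self.initial_pH < 14.0:
            raise ValueError("initial_pH must be in (0, 14)")

    def initialize(self, acids: Sequence[tuple[AcidSpec, float]] = ()) -> "MediumSpec":
        """Return a copy with ``fixed_cation_offset`` set.

        ``acids`` are the (spec, total mM) pairs present at t=0; by default the
        medium starts acid-free (``acid_0`` is then carried by the caller).
        """
        offset = _offset_closing_balance(self, self.initial_pH, acids)
        return replace(self, fixed_cation_offset=offset)

    def phosphate_anion_charge(self, pH: float) -> float:
        """mol negative charge per L carried by the phosphate pool at ``pH``."""
        pt = self.phosphate_total * 1e-3  # mol/L
        if pt == 0.0:
            return 0.0
        h = 10.0 ** (-pH)
        if not self.full_phosphate:
            # H2PO4- (charge 1) vs HPO4^2- (charge 2)
            f2 = 1.0 / (1.0 + 10.0 ** (self.phosphate_pKa2 - pH))
            return pt * (1.0 + f2)
        k1 = 10.0 ** (-self.phosphate_pKa1)
        k2 = 10.0 ** (-self.phosphate_pKa2)
        k3 = 10.0 ** (-self.phosphate_pKa3)
        d = h**3 + k1 * h**2 + k1 * k2 * h + k1 * k2 * k3
        a1 = k1 * h**2 / d
        a2 = k1 * k2 * h / d
        a3 = k1 * k2 * k3 / d
        return pt * (a1 + 2.0 * a2 + 3.0 * a3)


def protonated_fraction(pH: float, acid: AcidSpec) -> float:
    """Henderson-Hasselbalch fraction of the acid in the uncharged HA form."""
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH must be in (0, 14), got {pH}")
    return 1.0 / (1.0 + 10.0 ** (pH - acid.pKa))


def speciate(total: float, pH: float, acid: AcidSpec) -> tuple[float, float]:
    """Split a total acid concentration into (HA, A-), conserving the total."""
    ha = total * protonated_fraction(pH, acid)
    return ha, total - ha


def charge_imbalance(
    pH: float,
    proton_load: float,
    acids: Iterable[tuple[AcidSpec, float]],
    medium: MediumSpec,
) -> float:
    """Electroneutrality residual (mol charge / L) at a candidate pH.

    Cations minus anions:

        [H+] + offset - [OH-] - sum_i [A-]_i - phosphate charge - load

    ``proton_load`` enters as the conjugate strong-base-free anion of the
    strong-acid equivalents added (biomass-linked H+ release).  The residual is
    strictly decreasing in pH, so the balance has at most one root.
    """
    if medium.fixed_cation_offset is None:
        raise ValueError("medium must be initialized (fixed_cation_offset unset)")
    h = 10.0 ** (-pH)
    res = h + medium.fixed_cation_offset - KW / h - proton_load
    res -= medium.phosphate_anion_charge(pH)
    for acid, total in acids:
        if total < 0:
            raise ValueError(f"negative total for {acid.name}")
        res -= (total * 1e-3) * (1.0 - 1.0 / (1.0 + 10.0 ** (pH - acid.pKa)))
    return res


def _offset_closing_balance(
    medium: MediumSpec, pH: float, acids: Sequence[tuple[AcidSpec, float]]
) -> float:
    h = 10.0 ** (-pH)
    off = KW / h - h + medium.phosphate_anion_charge(pH)
    for acid, total in acids:
        off += (total * 1e-3) * (1.0 - 1.0 / (1.0 + 10.0 ** (pH - acid.pKa)))
    return off


def solve_pH(
    proton_load: float,
    acids: Sequence[tuple[AcidSpec, float]],
    medium: MediumSpec,
    lo: float = 1.0,
    hi: float = 13.0,
    tol: float = 1e-12,
) -> float:
    """Solve the charge balance for pH by bisection on (lo, hi).

    Bisection is retained over faster root finders because the residual is
    monotone and the guaranteed convergence keeps the ODE right-hand side
    robust near buffer exhaustion.
    """
    if proton_load < 0:
        raise ValueError("proton_load must be >= 0")
    f_lo = charge_imbalance(lo, proton_load, acids, medium)
    f_hi = charge_imbalance(hi, proton_load, acids, medium)
    if f_lo < 0.0 or f_hi > 0.0:
        raise InfeasibleMediumError(
            f"no charge-balance root in pH ({lo}, {hi}); "
            f"residuals {f_lo:.3e} / {f_hi:.3e}"
        )
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if charge_imbalance(mid, proton_load, acids, medium) >= 0.0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def _load_bundled() -> dict[str, AcidSpec]:
    consts = load_constants()
    out = {}
    for name, row in consts["acids"].items():
        out[name] = AcidSpec(
            name=name,
            pKa=row["pKa"],
            molar_mass=row["molar_mass"],
            combustion_enthalpy=row["combustion_enthalpy"],
            formula=dict(row["formula"]),
        )
    return out


_BUNDLED_ACIDS = _load_bundled()
ACETIC: AcidSpec = _BUNDLED_ACIDS["acetic"]
LACTIC: AcidSpec = _BUNDLED_ACIDS["lactic"]


def medium_preset(name: str, initial_pH: float | None = None) -> MediumSpec:
    """Return a bundled medium (``low_phosphate`` 6.3 mM or ``conventional``
    64 mM phosphate), uninitialized so the caller can attach the acid pool."""
    presets = load_constants()["media"]
    if name not in presets:
        raise KeyError(f"unknown medium preset {name!r}; choose from {sorted(presets)}")
    row = presets[name]
    return MediumSpec(
        phosphate_total=row["phosphate_total"],
        phosphate_pKa2=row["phosphate_pKa2"],
        initial_pH=initial_pH if initial_pH is not None else row["initial_pH"],
        glucose_0=row["glucose_0"],
        acid_0=row["acid_0"],
    )
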