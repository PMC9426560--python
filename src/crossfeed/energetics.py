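"""Stoichiometric ATP-yield, opportunity-cost and proteome-investment accounting.

Each of the five metabolic guilds (generalist WT, acetate producer ProdA,
lactate producer ProdL, acetate consumer ConsA, lactate consumer ConsL) is
represented by a named flux mode: a lumped route through central metabolism
with per-mole-substrate coefficients for substrate-level ATP, NADH, FADH2,
CO2 and the secreted product.  Oxidative phosphorylation is applied as simple
P/O ratios (NADH -> 2 ATP, FADH2 -> 1 ATP by default); producers that cannot
couple electron transport to ATP synthesis (ATP synthase or terminal oxidases
deleted) carry ``respiring=False`` and earn no oxidative ATP.

The default ratios are the unique simple integer assignment consistent with
all five bundled yields simultaneously; they are a deliberate lumping of the
branched E. coli electron transport chain, not measured stoichiometry.

Opportunity cost is ATP not generated because the guild secretes a reduced
product instead of fully oxidizing its substrate: yield(reference) minus
yield(producer) on the shared substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "FluxMode",
    "PathwayLedger",
    "EnzymeCostTable",
    "degree_of_reduction",
    "default_ledger",
    "default_cost_table",
    "GLUCOSE",
    "CO2",
]

GLUCOSE = {"C": 6, "H": 12, "O": 6}
ACETATE = {"C": 2, "H": 4, "O": 2}
LACTATE = {"C": 3, "H": 6, "O": 3}
CO2 = {"C": 1, "O": 2}

_VALENCE = {"C": 4, "H": 1, "O": -2, "N": -3}


def degree_of_reduction(formula: Mapping[str, int]) -> float:
    """Available electrons per carbon mole: (4C + H - 2O - 3N) / C."""
    c = formula.get("C", 0)
    if c <= 0:
        raise ValueError("formula must contain carbon")
    electrons = sum(_VALENCE[el] * n for el, n in formula.items() if n)
    return electrons / c


@dataclass(frozen=True)
class FluxMode:
    """A lumped route through central metabolism, per mole of substrate.

    ``atp_slp`` is net substrate-level phosphorylation (activation costs such
    as acetate -> acetyl-CoA enter as negative contributions already folded
    in).  ``products`` maps product names to (moles, elemental formula).
    ``reactions`` lists the enzyme-catalyzed steps the mode requires, for
    proteome-investment accounting.
    """

    name: str
    substrate: str
    substrate_formula: Mapping[str, int]
    atp_slp: float
    nadh: float
    fadh2: float
    co2: float
    products: Mapping[str, tuple[float, Mapping[str, int]]] = field(default_factory=dict)
    respiring: bool = True
    reactions: tuple[str, ...] = ()


class UnknownModeError(KeyError):
    pass


@dataclass
class PathwayLedger:
    """Bookkeeping over named flux modes with shared P/O ratios."""

    modes: dict[str, FluxMode]
    po_nadh: float = 2.0
    po_fadh2: float = 1.0

    def _mode(self, name: str) -> FluxMode:
        try:
            return self.modes[name]
        except KeyError:
            raise UnknownModeError(
                f"unknown mode {name!r}; available: {sorted(self.modes)}"
            ) from None

    def atp_yield(self, name: str) -> float:
        """mol ATP per mol substrate for a named mode."""
        m = self._mode(name)
        atp = m.atp_slp
        if m.respiring:
            atp += m.nadh * self.po_nadh + m.fadh2 * self.po_fadh2
        return atp

    def opportunity_cost(self, producer: str, reference: str) -> float:
        """ATP per mol substrate foregone by running ``producer`` instead of
        ``reference``; both modes must share the substrate."""
        p, r = self._mode(producer), self._mode(reference)
        if p.substrate != r.substrate:
            raise ValueError(
                f"modes consume different substrates: {p.substrate} vs {r.substrate}"
            )
        return self.atp_yield(reference) - self.atp_yield(producer)

    def electron_balance(self, name: str) -> tuple[float, float]:
        """(electrons in substrate, electrons in products + 2*(NADH+FADH2)).

        NADH/FADH2 carry two electrons each to O2 regardless of whether the
        transfer is ATP-coupled.  Both sides are per mole substrate.
        """
        m = self._mode(name)
        e_in = degree_of_reduction(m.substrate_formula) * m.substrate_formula["C"]
        e_out = 2.0 * (m.nadh + m.fadh2)
        for moles, formula in m.products.values():
            e_out += moles * degree_of_reduction(formula) * formula["C"]
        return e_in, e_out


@dataclass
class EnzymeCostTable:
    """Amino acids per functional enzyme complex, keyed by reaction name."""

    costs: dict[str, float]

    def __post_init__(self) -> None:
        bad = [k for k, v in self.costs.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive enzyme costs for {bad}")

    def proteome_investment(
        self,
        reactions: Sequence[str],
        atp_per_mode: float,
        atp_equivalent_factor: float | None = None,
    ) -> dict[str, float | None]:
        """Sum amino-acid costs over a mode's reaction set (each enzyme once).

        Returns total amino acids, amino acids per ATP produced, and -- when
        ``atp_equivalent_factor`` (ATP equivalents per amino acid, the product
        of the guild's substrate-Cmol-per-amino-acid and ATP-per-Cmol chain)
        is given -- the investment expressed in ATP equivalents.
        """
        missing = [r for r in dict.fromkeys(reactions) if r not in self.costs]
        if missing:
            raise KeyError(f"no enzyme cost entry for reaction(s) {missing}")
        total = float(sum(self.costs[r] for r in dict.fromkeys(reactions)))
        per_atp = total / atp_per_mode if atp_per_mode > 0 else None
        atp_equiv = total * atp_equivalent_factor if atp_equivalent_factor else None
        return {
            "total_amino_acids": total,
            "amino_acids_per_atp": per_atp,
            "atp_equivalent_investment": atp_equiv,
        }


def default_ledger() -> PathwayLedger:
    """The five bundled guild flux modes.

    Glucose modes are per mol glucose; acid modes per mol organic acid.

    * ``wt``: glycolysis + pyruvate dehydrogenase + full TCA + respiration;
      complete oxidation (2+2 slp ATP, 10 NADH, 2 FADH2).
    * ``prodA``: homoacetate overflow (glycolysis + Pta/AckA); electron
      transport uncoupled from ATP synthesis, so only the 4 slp ATP count.
    * ``prodL``: homolactate fermentation; glycolytic NADH is reoxidized by
      lactate dehydrogenase, net 2 slp ATP.
    * ``consA``: acetate activation (-1 ATP) then acetyl-CoA oxidation via TCA.
    * ``consL``: lactate -> pyruvate -> acetyl-CoA -> TCA.
    """
    modes = {
        "wt": FluxMode(
            name="wt",
            substrate="glucose",
            substrate_formula=GLUCOSE,
            atp_slp=4.0,  # 2 glycolysis + 2 succinyl-CoA synthetase
            nadh=10.0,
            fadh2=2.0,
            co2=6.0,
            products={},
            respiring=True,
            reactions=(
                "glycolysis", "pyruvate_dehydrogenase", "tca_cycle",
                "electron_transport", "atp_synthase",
            ),
        ),
        "prodA": FluxMode(
            name="prodA",
            substrate="glucose",
            substrate_formula=GLUCOSE,
            atp_slp=4.0,  # 2 glycolysis + 2 acetate kinase
            nadh=4.0,  # 2 glycolysis + 2 PDH, reoxidized without ATP coupling
            fadh2=0.0,
            co2=2.0,
            products={"acetate": (2.0, ACETATE)},
            respiring=False,
            reactions=("glycolysis", "pyruvate_dehydrogenase", "pta_ackA"),
        ),
        "prodL": FluxMode(
            name="prodL",
            substrate="glucose",
            substrate_formula=GLUCOSE,
            atp_slp=2.0,
            nadh=0.0,  # glycolytic NADH consumed by lactate dehydrogenase
            fadh2=0.0,
            co2=0.0,
            products={"lactate": (2.0, LACTATE)},
            respiring=False,
            reactions=("glycolysis", "lactate_dehydrogenase"),
        ),
        "consA": FluxMode(
            name="consA",
            substrate="acetate",
            substrate_formula=ACETATE,
            atp_slp=0.0,  # -1 activation + 1 succinyl-CoA synthetase
            nadh=3.0,
            fadh2=1.0,
            co2=2.0,
            products={},
            respiring=True,
            reactions=(
                "ackA_pta_reverse", "tca_cycle",
                "electron_transport", "atp_synthase",
            ),
        ),
        "consL": FluxMode(
            name="consL",
            substrate="lactate",
            substrate_formula=LACTATE,
            atp_slp=1.0,
            nadh=5.0,  # 1 lactate->pyruvate + 1 PDH + 3 TCA
            fadh2=1.0,
            co2=3.0,
            products={},
            respiring=True,
            reactions=(
                "lactate_dehydrogenase_ox", "pyruvate_dehydrogenase",
                "tca_cycle", "electron_transport", "atp_synthase",
            ),
        ),
    }
    return PathwayLedger(modes=modes)


def default_cost_table() -> EnzymeCostTable:
    """Bundled enzyme amino-acid costs.

    Only the pyruvate dehydrogenase complex cost ships by default; the full
    per-reaction table is user-loadable (CSV with columns reaction,amino_acids).
    """
    return EnzymeCostTable(costs={"pyruvate_dehydrogenase": 42096.0})


def load_cost_table_csv(path) -> EnzymeCostTable:
    import pandas as pd

    df = pd.read_csv(path)
    return EnzymeCostTable(costs=dict(zip(df["reaction"], df["amino_acids"].astype(float))))
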