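"""Named guild parameter sets and batch scenario builders.

Two families of presets ship:

* ``ode`` (default): the parameter sets used for the dynamic simulations --
  producer/generalist mu_max 0.6 1/h, producer biomass yields 0.43 (WT) or
  0.25 (AAE producer) g/g, consumer mu_max 0.3 (acetate) with biomass yield
  0.24 g/g, proton yield 0.009 mol H+/g for every guild, and Ghose-Tyagi
  critical protonated-acid concentrations 1.44 mM (acetic) / 0.45 mM (lactic).

Every guild carries the linear pH-arrest factor (growth impossible above
[H+] = 10^-4.4 M) by default.  Whether acid consumers are really arrested at
that threshold is uncertain -- batch cultures show late, stationary-phase
acid consumption and pH recovery -- so the factor is a switch: pass
``h_star=None`` as an override to disable it for a guild.  The choice is
consequential near the arrest boundary; see the methods note for the
sensitivity analysis.
* ``measured``: monoculture physiology (mu_max 0.65/0.54/0.24/0.14/0.41 1/h
  and the matching yields) for users who prefer strain-derived numbers.  The
  two families genuinely disagree on the producer mu_max (0.6 vs 0.54/0.24);
  both are retained rather than reconciled.

Half-saturation constants come from the wild-type dose-response fits (glucose
kg 0.005 mM; acetate ks 0.0723 / ki 0.760 mM; lactate ks 0.0038 / ki 0.317 mM
on the protonated-acid basis).

Cultures are inoculated at OD600 0.020 per guild; OD is converted to cell dry
weight with 0.4 g cdw/L per OD600 unit, a conventional E. coli factor.
"""

from __future__ import annotations

from .acidbase import ACETIC, LACTIC, AcidSpec, MediumSpec, medium_preset
from .constants import load_constants
from .simulation import GuildSpec, Scenario

__all__ = [
    "OD_TO_CDW",
    "INOCULUM_OD",
    "guild",
    "scenario",
    "list_presets",
]

OD_TO_CDW = 0.4  # g cdw/L per OD600 (conventional E. coli value)
INOCULUM_OD = 0.020
INOCULUM_CDW = INOCULUM_OD * OD_TO_CDW  # 0.008 g/L

_AC = load_constants()
_GT = _AC["ghose_tyagi_pstar"]

# acetate consumer Haldane parameters (wild-type-derived; the engineered
# consumer is somewhat more acid-sensitive, so these are overridable defaults)
_ACETATE_KS, _ACETATE_KI = 0.0723, 0.760
_LACTATE_KS, _LACTATE_KI = 0.0038, 0.317
_GLUCOSE_KG = 0.005

_GUILDS: dict[tuple[str, str], dict] = {
    ("wt", "ode"): dict(
        role="producer", mu_max=0.6, ks=_GLUCOSE_KG, biomass_yield=0.43,
        product_yield=0.26, p_star=_GT["acetic"],
    ),
    ("prodA", "ode"): dict(
        role="producer", mu_max=0.6, ks=_GLUCOSE_KG, biomass_yield=0.25,
        product_yield=0.38, p_star=_GT["acetic"],
    ),
    ("consA", "ode"): dict(
        role="consumer", mu_max=0.3, ks=_ACETATE_KS, ki=_ACETATE_KI,
        biomass_yield=0.24,
    ),
    ("prodL", "ode"): dict(
        role="producer", mu_max=0.3, ks=_GLUCOSE_KG, biomass_yield=0.05,
        product_yield=15.0, p_star=_GT["lactic"],
    ),
    ("consL", "ode"): dict(
        role="consumer", mu_max=0.5, ks=_LACTATE_KS, ki=_LACTATE_KI,
        biomass_yield=0.5,
    ),
    ("wt", "measured"): dict(
        role="producer", mu_max=0.65, ks=_GLUCOSE_KG, biomass_yield=0.43,
        product_yield=0.11, p_star=_GT["acetic"],
    ),
    ("prodA", "measured"): dict(
        role="producer", mu_max=0.54, ks=_GLUCOSE_KG, biomass_yield=0.20,
        product_yield=0.34, p_star=_GT["acetic"],
    ),
    ("consA", "measured"): dict(
        role="consumer", mu_max=0.14, ks=_ACETATE_KS, ki=_ACETATE_KI,
        biomass_yield=0.24,
    ),
    ("prodL", "measured"): dict(
        role="producer", mu_max=0.24, ks=_GLUCOSE_KG, biomass_yield=0.05,
        product_yield=0.86 / 0.05, p_star=_GT["lactic"],
    ),
    ("consL", "measured"): dict(
        role="consumer", mu_max=0.41, ks=_LACTATE_KS, ki=_LACTATE_KI,
        biomass_yield=0.48,
    ),
}


def guild(name: str, family: str = "ode", **overrides) -> GuildSpec:
    """Build a named guild (``wt``, ``prodA``, ``consA``, ``prodL``,
    ``consL``) from the ``ode`` or ``measured`` parameter family."""
    key = (name, family)
    if key not in _GUILDS:
        raise KeyError(
            f"unknown guild preset {name!r}/{family!r}; "
            f"available: {sorted(set(k for k, _ in _GUILDS))} x ('ode', 'measured')"
        )
    kw = dict(_GUILDS[key])
    kw.update(overrides)
    return GuildSpec(name=name, **kw)


_SCENARIOS = ("wt", "aae", "lae", "prodA", "prodL")


def scenario(
    name: str,
    buffer: str | float = "low_phosphate",
    initial_pH: float = 7.0,
    family: str = "ode",
    t_end: float = 80.0,
    producer_ratio: float = 1.0,
    **scenario_kw,
) -> Scenario:
    """Assemble a preset batch scenario.

    ``name``: ``wt`` (generalist monoculture), ``prodA``/``prodL`` (producer
    monocultures), ``aae``/``lae`` (producer+consumer consortia).  ``buffer``
    is a medium preset name or a phosphate total in mM.  ``producer_ratio``
    scales the producer inoculum relative to the consumer's (guild-ratio
    experiments); consumer inoculum stays at the standard density.
    """
    if name not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {_SCENARIOS}")
    if isinstance(buffer, str):
        medium = medium_preset(buffer, initial_pH=initial_pH)
    else:
        medium = medium_preset("low_phosphate", initial_pH=initial_pH)
        from dataclasses import replace

        medium = replace(medium, phosphate_total=float(buffer))

    if name == "wt":
        guilds = (guild("wt", family),)
        inocula = (INOCULUM_CDW,)
        acid = ACETIC
    elif name == "prodA":
        guilds = (guild("prodA", family),)
        inocula = (INOCULUM_CDW,)
        acid = ACETIC
    elif name == "prodL":
        guilds = (guild("prodL", family),)
        inocula = (INOCULUM_CDW,)
        acid = LACTIC
    elif name == "aae":
        guilds = (guild("prodA", family), guild("consA", family))
        inocula = (INOCULUM_CDW * producer_ratio, INOCULUM_CDW)
        acid = ACETIC
    else:  # lae
        guilds = (guild("prodL", family), guild("consL", family))
        inocula = (INOCULUM_CDW * producer_ratio, INOCULUM_CDW)
        acid = LACTIC
    return Scenario(
        guilds=guilds, inocula=inocula, medium=medium, acid=acid,
        t_end=t_end, **scenario_kw,
    )


def list_presets() -> dict[str, tuple[str, ...]]:
    return {
        "guilds": tuple(sorted(set(k for k, _ in _GUILDS))),
        "families": ("ode", "measured"),
        "scenarios": _SCENARIOS,
        "media": tuple(sorted(load_constants()["media"])),
    }
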