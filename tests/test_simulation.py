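import numpy as np
import pytest
from dataclasses import replace

from crossfeed.acidbase import protonated_fraction
from crossfeed.presets import INOCULUM_CDW, guild, list_presets, scenario
from crossfeed.simulation import (
    GLUCOSE_MOLAR_MASS,
    GuildSpec,
    Scenario,
    compare_contexts,
    simulate_batch,
    sweep_secretion,
)

PRESET_NAMES = ["wt", "aae", "lae"]


def traj_for(name, **kw):
    return simulate_batch(scenario(name, **kw))


class TestInvariants:
    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_nonnegative_states(self, name):
        traj = traj_for(name, t_end=40.0)
        for x in traj.biomass.values():
            assert np.all(x >= 0)
        assert np.all(traj.glucose >= 0)
        assert np.all(traj.acid_total >= 0)
        assert np.all(traj.proton_load >= 0)

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_biomass_nondecreasing_glucose_nonincreasing(self, name):
        traj = traj_for(name, t_end=40.0)
        for x in traj.biomass.values():
            assert np.all(np.diff(x) >= -1e-9)
        assert np.all(np.diff(traj.glucose) <= 1e-9)

    def test_zero_inocula_constant(self):
        base = scenario("wt", t_end=10.0)
        traj = simulate_batch(replace(base, inocula=(0.0,)))
        assert np.allclose(traj.total_biomass, 0.0)
        assert np.allclose(traj.glucose, traj.glucose[0])
        assert np.allclose(traj.acid_total, 0.0)
        assert np.allclose(traj.pH, traj.pH[0])

    def test_carbon_sanity_bound(self, wt_low_trajectory):
        # biomass C + acid C accumulated <= glucose C consumed; slack is CO2
        traj = wt_low_trajectory
        cmol_biomass = (traj.total_biomass[-1] - traj.total_biomass[0]) / 24.6
        cmol_acid = (traj.acid_total[-1] - traj.acid_total[0]) * 1e-3 * 2  # acetate C2
        cmol_glc = (traj.glucose[0] - traj.glucose[-1]) * 1e-3 * 6
        assert cmol_biomass + cmol_acid <= cmol_glc

    def test_ph_recovery_only_during_net_consumption(self, aae_low_trajectory):
        traj = aae_low_trajectory
        dph = np.diff(traj.pH)
        da = np.diff(traj.acid_total)
        rising = dph > 1e-9
        # wherever pH rises, the acid pool must be shrinking
        assert np.all(da[rising] < 1e-9)

    def test_wt_low_buffer_arrests_with_glucose_left(self, wt_low_trajectory):
        traj = wt_low_trajectory
        assert any(label == "growth_arrest" for label, _ in traj.events)
        assert traj.glucose[-1] > 1.0  # mM unconsumed
        assert traj.pH[-1] == pytest.approx(4.4, abs=0.02)

    def test_high_buffer_consortium_exhausts_glucose(self):
        traj = traj_for("aae", buffer="conventional")
        assert any(label == "glucose_exhausted" for label, _ in traj.events)
        assert traj.glucose[-1] < 1e-3


class TestMassBalanceOracle:
    def test_acid_balance_trapezoid(self, aae_low_trajectory):
        traj = aae_low_trajectory
        scen = traj.scenario
        acid = scen.acid
        rate = np.zeros_like(traj.time)
        for k, (t, g_mM, a_mM, ph) in enumerate(
            zip(traj.time, traj.glucose, traj.acid_total, traj.pH)
        ):
            h = 10.0 ** (-ph)
            ha = a_mM * protonated_fraction(ph, acid)
            for gld, name in zip(scen.guilds, traj.biomass):
                mu = gld.growth_rate(g_mM, ha, h)
                x = traj.biomass[name][k]
                if gld.role == "producer":
                    rate[k] += gld.product_yield * mu * x / acid.molar_mass * 1000.0
                else:
                    rate[k] -= mu * x / gld.biomass_yield / acid.molar_mass * 1000.0
        integrated = np.trapezoid(rate, traj.time)
        actual = traj.acid_total[-1] - traj.acid_total[0]
        scale = max(abs(actual), traj.acid_total.max())
        assert abs(integrated - actual) / scale < 0.005

    def test_glucose_to_biomass_stoichiometry(self, wt_low_trajectory):
        traj = wt_low_trajectory
        gld = traj.scenario.guilds[0]
        dx = traj.total_biomass[-1] - traj.total_biomass[0]
        dglc_g = (traj.glucose[0] - traj.glucose[-1]) * GLUCOSE_MOLAR_MASS / 1000.0
        assert dx / dglc_g == pytest.approx(gld.biomass_yield, rel=1e-6)


class TestNumericalRobustness:
    def test_tolerance_tightening_invariance(self):
        base = scenario("wt", t_end=40.0)
        loose = simulate_batch(replace(base, rel_tol=1e-6, abs_tol=1e-9))
        tight = simulate_batch(replace(base, rel_tol=1e-9, abs_tol=1e-12))
        for attr in ("total_biomass", "glucose", "acid_total", "pH"):
            a = getattr(loose, attr) if attr != "total_biomass" else loose.total_biomass
            b = getattr(tight, attr) if attr != "total_biomass" else tight.total_biomass
            assert abs(a[-1] - b[-1]) / max(abs(b[-1]), 1e-12) < 1e-3

    def test_max_step_halving_invariance(self):
        base = scenario("aae", t_end=30.0)
        coarse = simulate_batch(replace(base, max_step=1.0))
        fine = simulate_batch(replace(base, max_step=0.5))
        for a, b in (
            (coarse.total_biomass[-1], fine.total_biomass[-1]),
            (coarse.glucose[-1], fine.glucose[-1]),
            (coarse.pH[-1], fine.pH[-1]),
        ):
            assert abs(a - b) / max(abs(b), 1e-12) < 1e-3

    def test_determinism(self):
        a = traj_for("wt", t_end=20.0)
        b = traj_for("wt", t_end=20.0)
        assert np.array_equal(a.total_biomass, b.total_biomass)
        assert np.array_equal(a.pH, b.pH)


class TestValidation:
    def test_guild_validation(self):
        with pytest.raises(ValueError):
            GuildSpec(name="p", role="producer", mu_max=0.5, ks=0.01,
                      biomass_yield=0.4)  # missing p_star
        with pytest.raises(ValueError):
            GuildSpec(name="c", role="consumer", mu_max=0.5, ks=0.01,
                      biomass_yield=0.4)  # missing ki
        with pytest.raises(ValueError):
            GuildSpec(name="p", role="producer", mu_max=-1.0, ks=0.01,
                      biomass_yield=0.4, p_star=1.0)

    def test_scenario_validation(self):
        base = scenario("wt")
        with pytest.raises(ValueError):
            replace(base, inocula=(0.008, 0.008))
        with pytest.raises(ValueError):
            replace(base, inocula=(-1.0,))
        with pytest.raises(ValueError):
            replace(base, t_end=0.0)

    def test_unknown_presets(self):
        with pytest.raises(KeyError):
            scenario("nope")
        with pytest.raises(KeyError):
            guild("wt", family="nope")

    def test_list_presets(self):
        info = list_presets()
        assert "aae" in info["scenarios"]
        assert set(info["families"]) == {"ode", "measured"}


class TestSweepAndCompare:
    def test_zero_secretion_starves_consumer(self):
        base = scenario("aae", t_end=30.0)
        table = sweep_secretion(replace(base), [1e-9])
        traj = simulate_batch(
            replace(
                base,
                guilds=tuple(
                    replace(g, product_yield=1e-9) if g.role == "producer" else g
                    for g in base.guilds
                ),
            )
        )
        consumer = [n for n, g in zip(traj.biomass, base.guilds) if g.role == "consumer"][0]
        assert traj.biomass[consumer][-1] <= INOCULUM_CDW * 1.01
        assert len(table) == 1

    def test_sweep_row_order_follows_input(self):
        table = sweep_secretion(scenario("aae", t_end=20.0), [0.5, 0.26])
        assert list(table["product_yield_g_g"]) == [0.5, 0.26]

    def test_sweep_requires_producer(self):
        cons = guild("consA")
        scen = Scenario(
            guilds=(cons,), inocula=(0.008,),
            medium=scenario("aae").medium, acid=scenario("aae").acid,
        )
        with pytest.raises(ValueError):
            sweep_secretion(scen, [0.3])

    def test_compare_identical_scenarios_zero_difference(self):
        scen = scenario("aae", t_end=15.0)
        out = compare_contexts(scen, scen, [6.3])
        a = out[6.3]["consortium"]["report"]
        b = out[6.3]["generalist"]["report"]
        assert a.final_biomass == b.final_biomass
        assert a.glucose_consumed == b.glucose_consumed

    def test_compare_validates_shared_conditions(self):
        with pytest.raises(ValueError):
            compare_contexts(scenario("aae"), scenario("wt", t_end=10.0), [6.3])
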