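import math

import numpy as np
import pytest

from crossfeed.kinetics import evaluate, wildtype_model
from crossfeed.metrics import performance_report
from crossfeed.presets import scenario
from crossfeed.synthdata import (
    ObservationSpec,
    _plate_counts,
    gen_batch_observations,
    gen_dose_response,
    observations_to_trajectory,
)

LOG_GRID = np.concatenate([[0.0], np.geomspace(0.01, 2.5, 24)])


class TestDoseResponseGenerator:
    def test_noise_free_is_exact(self):
        model = wildtype_model("acetic_sole")
        ds = gen_dose_response(model, LOG_GRID, noise_sd=0.0, replicates=1, seed=0)
        for _, row in ds.data.iterrows():
            assert row["mu"] == pytest.approx(
                evaluate(model, {"S": row["conc_mM"]}), abs=1e-15
            )

    def test_same_seed_identical(self):
        model = wildtype_model("acetic_sole")
        a = gen_dose_response(model, LOG_GRID, noise_sd=0.02, seed=11)
        b = gen_dose_response(model, LOG_GRID, noise_sd=0.02, seed=11)
        assert a.data.equals(b.data)
        assert a.data.to_csv() == b.data.to_csv()

    def test_different_seeds_differ(self):
        model = wildtype_model("acetic_sole")
        a = gen_dose_response(model, LOG_GRID, noise_sd=0.02, seed=1)
        b = gen_dose_response(model, LOG_GRID, noise_sd=0.02, seed=2)
        assert not a.data.equals(b.data)

    def test_residual_sd_matches_noise_model(self):
        # 200 independent datasets at sd=0.02; empirical residual sd within
        # 10% of the generating value (evaluated away from the mu=0 clamp)
        model = wildtype_model("acetic_sole")
        true = {c: evaluate(model, {"S": c}) for c in LOG_GRID}
        residuals = []
        for seed in range(200):
            ds = gen_dose_response(model, LOG_GRID, 0.02, replicates=1, seed=seed)
            for _, r in ds.data.iterrows():
                if true[r["conc_mM"]] >= 0.1:
                    residuals.append(r["mu"] - true[r["conc_mM"]])
        sd = float(np.std(residuals, ddof=1))
        assert abs(sd - 0.02) / 0.02 < 0.10

    def test_rates_never_negative(self):
        model = wildtype_model("acetic_sole")
        ds = gen_dose_response(model, LOG_GRID, noise_sd=0.5, seed=0)
        assert (ds.data["mu"] >= 0).all()

    def test_replicate_stats_recorded(self):
        ds = gen_dose_response(
            wildtype_model("acetic_sole"), LOG_GRID, 0.02, replicates=5, seed=0
        )
        assert (ds.data["n"] == 5).all()
        assert (ds.data["sd"] >= 0).all()

    def test_validation(self):
        model = wildtype_model("acetic_sole")
        with pytest.raises(ValueError):
            gen_dose_response(model, [-1.0], 0.0)
        with pytest.raises(ValueError):
            gen_dose_response(model, [1.0], 0.0, replicates=0)
        with pytest.raises(ValueError):
            gen_dose_response(wildtype_model("acetic_glucose"), [1.0], 0.0)


class TestBatchObservations:
    def test_same_seed_identical(self, aae_low_trajectory):
        spec = ObservationSpec(seed=5)
        a = gen_batch_observations(aae_low_trajectory, spec)
        b = gen_batch_observations(aae_low_trajectory, spec)
        assert a.equals(b)

    def test_doubling_cadence(self, wt_low_trajectory):
        obs = gen_batch_observations(wt_low_trajectory, ObservationSpec(seed=0))
        t = wt_low_trajectory.time
        assert obs["time_h"].iloc[0] == t[0]
        assert obs["time_h"].iloc[-1] == t[-1]
        growth = (
            wt_low_trajectory.total_biomass[-1] / wt_low_trajectory.total_biomass[0]
        )
        assert len(obs) <= math.ceil(math.log2(growth)) + 2

    def test_censoring_below_detection_limit(self, wt_low_trajectory):
        spec = ObservationSpec(od_noise_cv=0.0, seed=0)
        obs = gen_batch_observations(wt_low_trajectory, spec)
        # acid starts at 0 -> censored NaN, never a negative value
        assert bool(obs["acid_censored"].iloc[0])
        assert np.isnan(obs["acid_mM"].iloc[0])
        assert (obs["acid_mM"].dropna() >= spec.hplc_lod).all()
        # glucose stays far above LOD -> uncensored everywhere
        assert not obs["glucose_censored"].any()

    def test_explicit_grid_and_span_check(self, wt_low_trajectory):
        obs = gen_batch_observations(
            wt_low_trajectory, ObservationSpec(sampling=(0.0, 5.0, 10.0), seed=0)
        )
        assert list(obs["time_h"]) == [0.0, 5.0, 10.0]
        with pytest.raises(ValueError):
            gen_batch_observations(
                wt_low_trajectory, ObservationSpec(sampling=(0.0, 1e6), seed=0)
            )

    def test_guild_counts_only_for_consortia(self, wt_low_trajectory, aae_low_trajectory):
        mono = gen_batch_observations(wt_low_trajectory, ObservationSpec(seed=0))
        duo = gen_batch_observations(aae_low_trajectory, ObservationSpec(seed=0))
        assert "total_cfu_ml" not in mono
        assert {"total_cfu_ml", "consumer_cfu_ml", "producer_cfu_ml"} <= set(duo)
        assert (duo["producer_cfu_ml"] >= 0).all()

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ObservationSpec(od_noise_cv=-0.1)


class TestPlateCountOracle:
    def test_mean_absolute_error_matches_poisson_theory(self):
        spec = ObservationSpec()
        xp = xc = 0.05  # g cdw/L
        dens_tot = (xp + xc) * spec.cfu_per_g / 1000.0
        dens_cons = xc * spec.cfu_per_g / 1000.0
        true_frac = xp / (xp + xc)
        errs = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            _, _, tot = _plate_counts(dens_tot, rng, spec)
            _, _, con = _plate_counts(dens_cons, rng, spec)
            errs.append(abs(max(tot - con, 0.0) / tot - true_frac))

        def expected_counts(d_cfu):
            e0 = d_cfu * spec.drop_volume_ml
            d = max(0, math.ceil(math.log10(e0 / spec.countable_range[1])))
            return 10.0 ** (-d) * e0 * spec.count_drops

        nt, nc = expected_counts(dens_tot), expected_counts(dens_cons)
        sd_frac = (dens_cons / dens_tot) * math.sqrt(1.0 / nt + 1.0 / nc)
        mae_pred = math.sqrt(2.0 / math.pi) * sd_frac
        assert 0.6 < np.mean(errs) / mae_pred < 1.5

    def test_dilution_targets_countable_range(self):
        spec = ObservationSpec()
        rng = np.random.default_rng(0)
        counts, d, back = _plate_counts(1e6, rng, spec)
        assert 1e6 * spec.drop_volume_ml * 10.0 ** (-d) <= spec.countable_range[1]
        assert back >= 0

    def test_zero_density(self):
        spec = ObservationSpec()
        assert _plate_counts(0.0, np.random.default_rng(0), spec) == (0, 0, 0.0)


class TestRoundTrip:
    def test_noise_free_roundtrip_preserves_metrics(self, wt_low_trajectory):
        spec = ObservationSpec(od_noise_cv=0.0, seed=0)
        obs = gen_batch_observations(wt_low_trajectory, spec)
        scen = wt_low_trajectory.scenario
        back = observations_to_trajectory(obs, scen)
        a = performance_report(wt_low_trajectory)
        b = performance_report(back)
        assert b.final_biomass == pytest.approx(a.final_biomass, rel=1e-9)
        assert b.glucose_consumed == pytest.approx(a.glucose_consumed, rel=1e-9)
        assert b.byproduct_final == pytest.approx(a.byproduct_final, rel=1e-9)
        assert b.biomass_per_glucose == pytest.approx(a.biomass_per_glucose, rel=1e-9)
        assert b.biomass_per_proton == pytest.approx(a.biomass_per_proton, rel=1e-3)
        assert b.specific_growth_rate == pytest.approx(
            a.specific_growth_rate, rel=1e-6
        )

    def test_synthetic_wt_batches_recover_generating_growth_rate(
        self, wt_measured_trajectory
    ):
        from crossfeed.metrics import estimate_growth_rate

        mus = []
        for seed in range(100):
            obs = gen_batch_observations(
                wt_measured_trajectory, ObservationSpec(seed=seed)
            )
            est = estimate_growth_rate(
                obs["time_h"].to_numpy(), obs["od600"].to_numpy()
            )
            mus.append(est.mu)
        assert abs(np.mean(mus) - 0.65) / 0.65 < 0.05
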