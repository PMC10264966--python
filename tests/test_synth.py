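"""Synthetic-assay generators: round trips, determinism, expectations."""

import numpy as np
import pytest
from dataclasses import replace

from thermomatch.errors import ConfigurationError, DomainError
from thermomatch.rates import (ingestion_rates, ingestion_replicates_from_frame,
                               oxygen_rates, oxygen_series_from_frame)
from thermomatch.synth import (LinearSummary, derive_linear_intercept,
                               generate_ingestion_experiment,
                               generate_is_experiment,
                               generate_oxygen_experiment,
                               generate_rate_samples, list_presets,
                               load_preset, noise_free,
                               reconstruct_tpc_from_summary,
                               resolve_linear_line)
from thermomatch.interaction import is_records_from_replicates


class TestPresets:
    def test_all_shipped_presets_load_with_valid_invariants(self):
        names = list_presets()
        assert set(names) >= {"chlamydomonas", "desmodesmus",
                              "daphnia_on_chlamydomonas",
                              "daphnia_on_desmodesmus"}
        for n in names:
            p = load_preset(n)
            assert len(set(p.assay_temperatures_c)) == 8
            if p.kind == "pair":
                assert 0 < p.assimilation_efficiency <= 1

    def test_published_assay_densities(self, pair_chlamy, pair_desmo):
        assert pair_chlamy.initial_density == pytest.approx(4.5e5)
        assert pair_desmo.initial_density == pytest.approx(1.3e6)

    def test_unknown_preset_raises(self):
        with pytest.raises(ConfigurationError):
            load_preset("no_such_species")


class TestLinearAnchoring:
    def test_zero_slope_anchored_at_crossover(self, pair_desmo):
        loss = reconstruct_tpc_from_summary(
            pair_desmo.rate_presets["respiration"])
        lin = LinearSummary(slope=0.0, tc_anchor_c=22.5, zero_slope=True,
                            units="u")
        assert derive_linear_intercept(lin, loss) == pytest.approx(
            float(loss(22.5)), rel=1e-12)

    def test_zero_slope_constant_loss_recovers_level(self):
        lin = LinearSummary(slope=0.0, tc_anchor_c=30.0, zero_slope=True,
                            units="u")
        assert derive_linear_intercept(lin, lambda t: 3.7) == pytest.approx(3.7)

    def test_sloped_line_crosses_unity_at_anchor(self, pair_chlamy):
        loss = reconstruct_tpc_from_summary(
            pair_chlamy.rate_presets["respiration"])
        line = resolve_linear_line(
            LinearSummary(slope=-0.075, tc_anchor_c=20.7, units="u"), loss)
        assert line(20.7) / float(loss(20.7)) == pytest.approx(1.0, rel=1e-12)

    def test_exactly_one_anchor_enforced(self):
        with pytest.raises(ConfigurationError):
            LinearSummary(slope=0.0, units="u")
        with pytest.raises(ConfigurationError):
            LinearSummary(slope=0.0, intercept=1.0, tc_anchor_c=20.0, units="u")


class TestOxygenGeneration:
    def test_noise_free_round_trip_recovers_rates_exactly(self, chlamy):
        p = noise_free(chlamy)
        true = reconstruct_tpc_from_summary(p.rate_presets["respiration"])
        df = generate_oxygen_experiment(p, "respiration", seed=0)
        rates = oxygen_rates(oxygen_series_from_frame(df), "respiration",
                             units="mg_O2_per_L_per_min_per_cell")
        assert len(rates) == 8 * 3 * 2
        for r in rates:
            assert r.value == pytest.approx(float(true(r.temperature_c)),
                                            rel=1e-9)

    def test_same_seed_byte_identical_csv(self, chlamy):
        a = generate_oxygen_experiment(chlamy, "net_photosynthesis", seed=11)
        b = generate_oxygen_experiment(chlamy, "net_photosynthesis", seed=11)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = generate_oxygen_experiment(chlamy, "net_photosynthesis", seed=12)
        assert not a.equals(c)

    def test_design_structure(self, chlamy):
        df = generate_oxygen_experiment(chlamy, "respiration", seed=0)
        per = df.groupby(["temperature_C", "block", "role"])["replicate_id"].nunique()
        assert (per == 3).all()
        assert df["block"].nunique() == 2
        n_read = df.groupby("replicate_id")["time_min"].count()
        assert (n_read == 31).all()

    def test_unknown_rate_kind_raises(self, chlamy):
        with pytest.raises(ConfigurationError):
            generate_oxygen_experiment(chlamy, "ingestion", seed=0)

    def test_expectation_matches_curve_across_seeds(self, chlamy):
        # different seeds: different realisations, identical expectations
        p = replace(chlamy, replicates_per_block=50)
        true = reconstruct_tpc_from_summary(p.rate_presets["net_photosynthesis"])
        vals = []
        for s in range(2):  # 2 x 50 x 2 blocks = 200 organism vials at 26 degC
            df = generate_oxygen_experiment(p, "net_photosynthesis", seed=s)
            rates = oxygen_rates(oxygen_series_from_frame(df),
                                 "net_photosynthesis")
            vals.extend(r.value for r in rates if r.temperature_c == 26.0)
        vals = np.asarray(vals)
        assert vals.size >= 200
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - float(true(26.0))) < 3 * se


class TestIngestionGeneration:
    def test_noise_free_round_trip(self, pair_chlamy_clean):
        from thermomatch.synth import consumer_gain_loss
        from thermomatch.rates import ingestion_to_energy
        gain, _ = consumer_gain_loss(pair_chlamy_clean)
        df = generate_ingestion_experiment(pair_chlamy_clean, seed=0)
        p = pair_chlamy_clean
        ing = [ingestion_to_energy(r, p.per_cell_energy_j,
                                   p.assimilation_efficiency)
               for r in ingestion_rates(ingestion_replicates_from_frame(df))]
        for r in ing:
            assert r.value == pytest.approx(float(gain(r.temperature_c)),
                                            abs=1e-9)

    def test_flat_ingestion_rarely_shows_spurious_slope(self, pair_desmo):
        # zero-slope preset: the unconstrained OLS slope should be judged
        # non-significant in >= 90% of seeds at alpha = .05
        from thermomatch.models import fit_linear_rate
        from thermomatch.rates import ingestion_to_energy
        n_nonsig = 0
        n_seeds = 30
        for s in range(n_seeds):
            df = generate_ingestion_experiment(pair_desmo, seed=s)
            ing = [ingestion_to_energy(r, pair_desmo.per_cell_energy_j,
                                       pair_desmo.assimilation_efficiency)
                   for r in ingestion_rates(ingestion_replicates_from_frame(df))]
            m = fit_linear_rate(ing)
            n_nonsig += m.constrained_zero_
        assert n_nonsig >= 0.9 * n_seeds

    def test_dead_consumers_enter_denominator(self, pair_chlamy):
        p = replace(noise_free(pair_chlamy), dead_consumer_rate=0.4)
        df = generate_ingestion_experiment(p, seed=3)
        treat = df[df["role"] == "organism"]
        assert treat["n_consumers"].min() < 5
        assert treat["n_consumers"].min() >= 1
        # recovery still exact because the recorded live count is used
        from thermomatch.synth import consumer_gain_loss
        from thermomatch.rates import ingestion_to_energy
        gain, _ = consumer_gain_loss(p)
        ing = [ingestion_to_energy(r, p.per_cell_energy_j,
                                   p.assimilation_efficiency)
               for r in ingestion_rates(ingestion_replicates_from_frame(df))]
        for r in ing:
            assert r.value == pytest.approx(float(gain(r.temperature_c)),
                                            abs=1e-9)


class TestISGeneration:
    def test_noise_free_records_sit_on_the_line(self, pair_chlamy_clean):
        df = generate_is_experiment(pair_chlamy_clean, seed=0)
        recs = is_records_from_replicates(
            ingestion_replicates_from_frame(df), "pair")
        line = pair_chlamy_clean.is_line
        for r in recs:
            assert r.value == pytest.approx(float(line(r.temperature_c)),
                                            abs=1e-12)

    def test_determinism(self, pair_desmo):
        a = generate_is_experiment(pair_desmo, seed=4)
        b = generate_is_experiment(pair_desmo, seed=4)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_resource_preset_cannot_generate_is(self, chlamy):
        with pytest.raises(ConfigurationError):
            generate_is_experiment(chlamy, seed=0)


class TestDirectRateSampler:
    def test_unit_mean_multiplicative_noise(self, chlamy):
        true = reconstruct_tpc_from_summary(
            chlamy.rate_presets["net_photosynthesis"])
        rates = generate_rate_samples(chlamy, "net_photosynthesis",
                                      n_per_temp=250, cv=0.1, seed=1)
        vals = np.array([r.value for r in rates if r.temperature_c == 30.0])
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - float(true(30.0))) < 3 * se
        cvs = vals.std(ddof=1) / vals.mean()
        assert cvs == pytest.approx(0.1, rel=0.25)

    def test_linear_rate_kind_rejected(self, pair_chlamy):
        with pytest.raises(ConfigurationError):
            generate_rate_samples(pair_chlamy, "ingestion", seed=0)
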