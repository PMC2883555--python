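import math

import numpy as np
import pytest

from poreflux.analytic import exact_steady_state, one_site_steady_state
from poreflux.channel import ChannelSpec, make_square_well_species, make_uniform_species
from poreflux.kmc import KmcSettings, SimulationTally, mean_density, simulate, standard_errors
from poreflux.observables import metrics


def within_3se(observed, expected, se, floor=5e-3):
    return abs(observed - expected) <= 3 * se + floor


class TestSettings:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            KmcSettings(sample_time=0.0)
        with pytest.raises(ValueError):
            KmcSettings(sample_time=1.0, n_batches=1)


class TestConservation:
    def test_integer_identities_hold_exactly(self, two_site):
        tally = simulate(two_site, KmcSettings(sample_time=2e5, seed=3))
        assert np.array_equal(tally.attempts, tally.blocked + tally.entries)
        assert np.array_equal(
            tally.entries,
            tally.exits_left + tally.exits_right + tally.in_channel_final,
        )
        assert tally.attempts.sum() > 0

    def test_batch_counts_sum_to_totals(self, two_site):
        tally = simulate(two_site, KmcSettings(sample_time=1e5, n_batches=8, seed=5))
        assert np.array_equal(tally.batch_entries.sum(axis=0), tally.entries)
        assert np.array_equal(tally.batch_exits_right.sum(axis=0), tally.exits_right)

    def test_capacity_never_exceeded_in_time_average(self, two_site):
        tally = simulate(two_site, KmcSettings(sample_time=1e5, seed=7))
        dens = mean_density(tally)
        assert (dens.sum(axis=1) <= two_site.capacity + 1e-12).all()


class TestDeterminismAndEdgeCases:
    def test_identical_seed_reproduces_bitwise(self, two_site):
        settings = KmcSettings(sample_time=5e4, seed=42)
        a, b = simulate(two_site, settings), simulate(two_site, settings)
        assert np.array_equal(a.batch_exits_right, b.batch_exits_right)
        assert np.array_equal(a.batch_occupancy, b.batch_occupancy)
        assert np.array_equal(a.in_channel_final, b.in_channel_final)

    def test_different_seeds_differ(self, two_site):
        a = simulate(two_site, KmcSettings(sample_time=5e4, seed=1))
        b = simulate(two_site, KmcSettings(sample_time=5e4, seed=2))
        assert not np.array_equal(a.batch_exits_right, b.batch_exits_right)

    def test_zero_flux_terminates_cleanly(self):
        sp = make_uniform_species("u", 0.0, 1.0, 3)
        spec = ChannelSpec(3, 1, 1, (sp,))
        tally = simulate(spec, KmcSettings(sample_time=100.0, seed=0))
        assert tally.zero_rate_termination
        assert tally.elapsed_sample_time == 100.0
        assert tally.attempts.sum() == 0
        assert (mean_density(tally) == 0).all()

    def test_invalid_spec_rejected(self):
        sp = make_uniform_species("u", 0.01, 1.0, 2)
        with pytest.raises(ValueError, match="entrance_site"):
            simulate(ChannelSpec(2, 1, 0, (sp,)), KmcSettings(sample_time=10.0))


class TestAgainstClosedForm:
    def test_one_site_efficiency_and_probability(self, one_site_n_only):
        ref = one_site_steady_state(0.01, 0.0, 0.5, 0.5)
        tally = simulate(one_site_n_only, KmcSettings(sample_time=2e6, seed=11))
        m = metrics(tally)["n"]
        assert within_3se(m.efficiency.value, ref.efficiency_n, m.efficiency.se)
        assert within_3se(
            m.translocation_probability.value, ref.prob_n, m.translocation_probability.se
        )

    def test_one_site_density_matches_occupancy_probability(self, one_site_n_only):
        ref = one_site_steady_state(0.01, 0.0, 0.5, 0.5)
        tally = simulate(one_site_n_only, KmcSettings(sample_time=2e6, n_batches=20, seed=13))
        dens = mean_density(tally)[0, 0]
        batch = tally.batch_occupancy[:, 0, 0] / (tally.elapsed_sample_time / tally.n_batches)
        se = batch.std(ddof=1) / math.sqrt(tally.n_batches)
        assert within_3se(dens, ref.P_n, se, floor=1e-3)

    def test_dilute_uniform_splitting_probability(self, dilute_uniform):
        """4-site uniform channel entered at site 1: transport odds are 1/(N+1)."""
        tally = simulate(dilute_uniform, KmcSettings(sample_time=4e6, seed=17))
        m = metrics(tally)["u"]
        assert within_3se(m.translocation_probability.value, 0.2, m.translocation_probability.se)

    def test_saturated_entrance_density_approaches_capacity(self):
        # J far above the exit rates: the entrance site is essentially always full
        sp = make_square_well_species("n", 10.0, 100.0, 2)
        spec = ChannelSpec(2, 1, 1, (sp,))
        tally = simulate(spec, KmcSettings(sample_time=2e4, seed=19))
        assert mean_density(tally)[0, 0] > 0.95


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_random_small_channels_match_exact_solver(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(2, 5))
        capacity = int(rng.integers(1, 3))
        entrance = int(rng.integers(1, n_sites + 1))
        species = []
        for label in ("a", "b"):
            from poreflux.channel import SpeciesSpec, internal_edges

            hops = {
                e: float(10 ** rng.uniform(-2, 0)) for e in internal_edges(n_sites)
            }
            species.append(
                SpeciesSpec(
                    label,
                    float(10 ** rng.uniform(-2, math.log10(0.05))),
                    hops,
                    float(10 ** rng.uniform(-2, 0)),
                    float(10 ** rng.uniform(-2, 0)),
                )
            )
        spec = ChannelSpec(n_sites, capacity, entrance, tuple(species))
        exact = metrics(exact_steady_state(spec))
        tally = simulate(spec, KmcSettings(sample_time=3e5, n_batches=20, seed=seed))
        sim = metrics(tally)
        for label in spec.labels:
            for name in ("efficiency", "entry_probability", "translocation_probability"):
                mv = getattr(sim[label], name)
                ref = getattr(exact[label], name)
                if mv.se is None or not ref.defined:
                    continue
                assert within_3se(mv.value, ref.value, mv.se), (label, name)


class TestDensityAndErrors:
    def test_zero_sample_time_density_error(self, two_site):
        tally = simulate(two_site, KmcSettings(sample_time=1e4, seed=1))
        tally.elapsed_sample_time = 0.0
        with pytest.raises(ValueError, match="sample time"):
            mean_density(tally)

    def test_batch_means_reference_value(self, two_site):
        """Two batches with efficiencies 0.4 and 0.6 give mean 0.5, SE 0.1."""
        tally = simulate(two_site, KmcSettings(sample_time=1e4, seed=1))
        B, S = 2, len(tally.labels)
        tally.batch_attempts = np.tile([[10], [10]], (1, S))
        tally.batch_exits_right = np.tile([[4], [6]], (1, S))
        tally.batch_entries = np.tile([[10], [10]], (1, S))
        tally.attempts = tally.batch_attempts.sum(axis=0)
        ses = standard_errors(tally)
        mean, se = ses[tally.labels[0]]["efficiency"]
        assert mean == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_identical_batches_zero_se(self, two_site):
        tally = simulate(two_site, KmcSettings(sample_time=1e4, seed=1))
        S = len(tally.labels)
        tally.batch_attempts = np.full((4, S), 10)
        tally.batch_exits_right = np.full((4, S), 5)
        tally.batch_entries = np.full((4, S), 10)
        tally.attempts = tally.batch_attempts.sum(axis=0)
        ses = standard_errors(tally)
        assert ses[tally.labels[0]]["efficiency"][1] == 0.0

    def test_insufficient_batches_error(self, two_site):
        tally = simulate(two_site, KmcSettings(sample_time=1e4, seed=1))
        S = len(tally.labels)
        tally.batch_attempts = np.zeros((4, S), dtype=np.int64)
        tally.batch_attempts[0] = 10
        tally.attempts = tally.batch_attempts.sum(axis=0)
        with pytest.raises(ValueError, match="batches"):
            standard_errors(tally)

    def test_dilute_limit_halving_flux_keeps_probability(self, dilute_uniform):
        """In the dilute limit the translocation probability is flux-independent."""
        from dataclasses import replace as dc_replace
        from poreflux.channel import SpeciesSpec

        half = dc_replace(
            dilute_uniform,
            species=(
                SpeciesSpec(
                    "u",
                    dilute_uniform.species[0].flux_J / 2,
                    dict(dilute_uniform.species[0].hop_rate),
                    1.0,
                    1.0,
                ),
            ),
        )
        a = metrics(simulate(dilute_uniform, KmcSettings(sample_time=3e6, seed=23)))["u"]
        b = metrics(simulate(half, KmcSettings(sample_time=6e6, seed=29)))["u"]
        se = math.hypot(a.translocation_probability.se, b.translocation_probability.se)
        assert abs(a.translocation_probability.value - b.translocation_probability.value) <= (
            3 * se + 5e-3
        )
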