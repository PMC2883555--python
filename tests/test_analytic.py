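import math

import numpy as np
import pytest

from poreflux.analytic import (
    enumerate_states,
    exact_steady_state,
    one_site_efficiency_ratio,
    one_site_steady_state,
)
from poreflux.channel import ChannelSpec, SpeciesSpec, make_uniform_species


class TestOneSiteClosedForm:
    def test_reference_values(self):
        """J=0.01, symmetric exits 0.5/0.5: P_empty=100/101, eff=50/101, p=1/2."""
        sol = one_site_steady_state(0.01, 0.0, 0.5, 0.5)
        assert sol.P_empty == pytest.approx(100 / 101, rel=1e-14)
        assert sol.efficiency_n == pytest.approx(50 / 101, rel=1e-14)
        assert sol.prob_n == pytest.approx(0.5, rel=1e-14)

    def test_normalization_and_bounds(self):
        sol = one_site_steady_state(0.3, 0.7, 0.5, 1.5, 2.0, 0.5)
        assert sol.P_empty + sol.P_n + sol.P_m == pytest.approx(1.0, abs=1e-15)
        for p in (sol.P_empty, sol.P_n, sol.P_m, sol.efficiency_n, sol.efficiency_m):
            assert 0.0 <= p <= 1.0

    def test_identical_species_have_equal_efficiencies(self):
        sol = one_site_steady_state(0.02, 0.02, 0.4, 0.6, 0.4, 0.6)
        assert sol.efficiency_n == sol.efficiency_m

    def test_small_current_limit_efficiency_equals_probability(self):
        # J → 0 with symmetric exits: efficiency → probability → 1/2
        sol = one_site_steady_state(1e-12, 0.0, 1.0, 1.0)
        assert sol.efficiency_n == pytest.approx(0.5, rel=1e-9)
        assert sol.prob_n == 0.5

    def test_absorbing_channel_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            one_site_steady_state(0.01, 0.0, 0.0, 0.0)

    def test_efficiency_monotone_in_forward_rate(self):
        probs = [
            one_site_steady_state(1e-9, 0.0, f, 1.0).prob_n for f in (0.1, 0.5, 1.0, 5.0)
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))


class TestEfficiencyRatio:
    def test_reference_ratio(self):
        # (1/4) / (1/2) = 0.5 independent of the fluxes
        assert one_site_efficiency_ratio(0.01, 0.02, 0.5, 0.5, 1.0, 3.0) == pytest.approx(0.5)

    def test_identical_species_ratio_one(self):
        assert one_site_efficiency_ratio(0.01, 0.01, 0.5, 0.5, 0.5, 0.5) == 1.0

    def test_mixture_composition_invariance(self):
        """Competition cannot change the one-site efficiency ratio."""
        ratios = {
            one_site_efficiency_ratio(J_n, J_m, 0.5, 0.5, 1.0, 3.0)
            for (J_n, J_m) in [(0.005, 0.005), (0.009, 0.001), (0.001, 0.009)]
        }
        assert len(ratios) == 1

    def test_zero_numerator_species_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            one_site_efficiency_ratio(0.01, 0.01, 0.0, 0.5, 1.0, 1.0)


class TestEnumerateStates:
    @pytest.mark.parametrize(
        "n_sites,n_species,capacity,expected",
        [(1, 2, 1, 3), (2, 2, 1, 9), (3, 1, 2, 27)],
    )
    def test_state_counts(self, n_sites, n_species, capacity, expected):
        species = tuple(
            make_uniform_species(f"s{i}", 0.01, 1.0, n_sites) for i in range(n_species)
        )
        spec = ChannelSpec(n_sites, capacity, 1, species)
        states = enumerate_states(spec)
        assert states.shape == (expected, n_sites, n_species)
        # duplicate-free
        assert len({s.tobytes() for s in states}) == expected

    def test_capacity_respected_in_every_state(self):
        species = tuple(make_uniform_species(f"s{i}", 0.01, 1.0, 3) for i in range(2))
        states = enumerate_states(ChannelSpec(3, 2, 1, species))
        assert states.sum(axis=2).max() == 2

    def test_deterministic_lexicographic_order(self):
        species = tuple(make_uniform_species(f"s{i}", 0.01, 1.0, 2) for i in range(2))
        spec = ChannelSpec(2, 1, 1, species)
        a, b = enumerate_states(spec), enumerate_states(spec)
        assert np.array_equal(a, b)
        flat = [tuple(s.ravel()) for s in a]
        assert flat == sorted(flat)

    def test_cap_exceeded_points_to_kmc(self):
        species = (make_uniform_species("u", 0.01, 1.0, 20),)
        with pytest.raises(ValueError, match="Monte Carlo"):
            enumerate_states(ChannelSpec(20, 3, 1, species), max_states=100)


class TestExactSteadyState:
    def test_one_site_matches_closed_form(self, one_site_n_only):
        sol = exact_steady_state(one_site_n_only)
        ref = one_site_steady_state(0.01, 0.0, 0.5, 0.5)
        s = sol.per_species["n"]
        assert s.efficiency == pytest.approx(ref.efficiency_n, rel=1e-12)
        assert s.translocation_probability == pytest.approx(ref.prob_n, rel=1e-12)
        assert s.entry_probability == pytest.approx(ref.P_empty, rel=1e-12)
        assert s.mean_density[0] == pytest.approx(ref.P_n, rel=1e-12)

    def test_one_site_mixture_matches_closed_form(self, one_site_mixture):
        sol = exact_steady_state(one_site_mixture)
        ref = one_site_steady_state(0.01, 0.01, 0.5, 0.5, 1.0, 3.0)
        assert sol.per_species["n"].efficiency == pytest.approx(ref.efficiency_n, rel=1e-12)
        assert sol.per_species["m"].efficiency == pytest.approx(ref.efficiency_m, rel=1e-12)

    @pytest.mark.parametrize("n_sites", [2, 4])
    def test_dilute_splitting_probability(self, n_sites):
        """Entered at site 1, J → 0: gambler's-ruin splitting 1/(N+1)."""
        sp = make_uniform_species("u", 1e-8, 1.0, n_sites)
        sol = exact_steady_state(ChannelSpec(n_sites, 1, 1, (sp,)))
        assert sol.per_species["u"].translocation_probability == pytest.approx(
            1.0 / (n_sites + 1), rel=1e-5
        )

    def test_translocation_increases_with_forward_exit(self):
        def transloc(exit_right):
            sp = make_uniform_species("u", 1e-8, 1.0, 2)
            sp = SpeciesSpec("u", 1e-8, dict(sp.hop_rate), sp.exit_left, exit_right)
            return exact_steady_state(
                ChannelSpec(2, 1, 1, (sp,))
            ).per_species["u"].translocation_probability

        vals = [transloc(x) for x in (0.5, 1.0, 2.0, 4.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("fixture", ["one_site_mixture", "two_site"])
    def test_flux_balance_per_species(self, fixture, request):
        """Stationarity: entry flux = left exit + right exit for each species."""
        sol = exact_steady_state(request.getfixturevalue(fixture))
        assert sol.pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert (sol.pi >= 0).all()
        for s in sol.per_species.values():
            assert s.entry_flux - s.exit_flux_left - s.exit_flux_right == pytest.approx(
                0.0, abs=1e-10 * max(s.entry_flux, 1e-30)
            )

    def test_two_site_competition_inhibits_weak_species(self, two_site):
        """A strongly trapped competitor lowers the weak species' translocation."""
        mix = exact_steady_state(two_site)
        weak_alone = ChannelSpec(
            2, 1, 1, (two_site.species_by_label("m"),)
        )
        alone = exact_steady_state(weak_alone)
        assert (
            mix.per_species["m"].translocation_probability
            < alone.per_species["m"].translocation_probability
        )

    def test_invalid_spec_rejected(self):
        sp = make_uniform_species("u", 0.01, 1.0, 2)
        with pytest.raises(ValueError, match="entrance_site"):
            exact_steady_state(ChannelSpec(2, 1, 5, (sp,)))

    def test_state_table_encodes_all_states(self, two_site):
        table = exact_steady_state(two_site).state_table()
        assert len(table) == 9
        assert table["probability"].sum() == pytest.approx(1.0, abs=1e-12)
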