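"""Monte Carlo randomization tests against exhaustive enumeration."""

import itertools

import numpy as np
import pytest

import loonlakes as ll

from conftest import make_lake


def enumerate_null(visits, lakes, trait, pool_radius_km=None):
    """Independent oracle: all destination assignments, one per pool lake
    per visit, returning the array of null mean-|difference| statistics."""
    by_id = {l.lake_id: l for l in lakes}
    pools = []
    for v in visits:
        natal = by_id[v.natal_lake_id]
        pool = [l for l in lakes if l.loon_suitable and l.lake_id != natal.lake_id]
        if pool_radius_km is not None:
            pool = [l for l in pool
                    if ll.haversine_km(natal.lat, natal.lon, l.lat, l.lon)
                    <= pool_radius_km]
        pools.append([abs(l.get_trait(trait) - natal.get_trait(trait))
                      for l in pool])
    stats = []
    for combo in itertools.product(*pools):
        stats.append(sum(combo) / len(combo))
    return np.array(stats)


class TestObservedMeanDifference:
    def test_single_visit(self):
        lakes = [make_lake("N", ph=7.0), make_lake("D", lat=45.8, ph=8.0)]
        visits = [ll.VisitRecord("J1", "N", "D")]
        assert ll.observed_mean_difference(visits, lakes, "ph") == 1.0

    def test_mean_of_two_differences(self):
        lakes = [make_lake("N", ph=7.0), make_lake("D1", lat=45.8, ph=8.0),
                 make_lake("D2", lat=45.9, ph=4.0)]
        visits = [ll.VisitRecord("J1", "N", "D1"), ll.VisitRecord("J2", "N", "D2")]
        assert ll.observed_mean_difference(visits, lakes, "ph") == 2.0

    def test_repeat_visit_records_count_once_per_record(self):
        lakes = [make_lake("N", ph=7.0), make_lake("D", lat=45.8, ph=8.0),
                 make_lake("E", lat=45.9, ph=4.0)]
        base = [ll.VisitRecord("J1", "N", "D"), ll.VisitRecord("J1", "N", "E")]
        doubled = base + [base[0]]
        m_base = ll.observed_mean_difference(base, lakes, "ph")
        m_doubled = ll.observed_mean_difference(doubled, lakes, "ph")
        assert m_base == 2.0
        assert m_doubled == pytest.approx((1.0 + 3.0 + 1.0) / 3.0)

    def test_empty_visits_rejected(self):
        with pytest.raises(ValueError):
            ll.observed_mean_difference([], [make_lake("N")], "ph")


class TestResamplingPool:
    def test_unrestricted_pool_is_all_suitable_except_natal(self, grid_lakes):
        natal = grid_lakes[0]
        pool = ll.build_resampling_pool(natal, grid_lakes)
        assert natal not in pool
        assert len(pool) == len(grid_lakes) - 1

    def test_radius_restriction(self, grid_lakes):
        natal = grid_lakes[0]
        pool = ll.build_resampling_pool(natal, grid_lakes, radius_km=20.0)
        for lake in pool:
            assert ll.haversine_km(natal.lat, natal.lon, lake.lat, lake.lon) <= 20.0
        outside = [l for l in grid_lakes[1:] if l not in pool]
        for lake in outside:
            assert ll.haversine_km(natal.lat, natal.lon, lake.lat, lake.lon) > 20.0

    def test_unsuitable_lakes_excluded(self, grid_lakes):
        grid_lakes[1].loon_suitable = False
        pool = ll.build_resampling_pool(grid_lakes[0], grid_lakes)
        assert grid_lakes[1] not in pool

    def test_empty_pool_names_the_natal_lake(self):
        natal = make_lake("N")
        with pytest.raises(ValueError, match="N"):
            ll.build_resampling_pool(natal, [natal])


class TestRandomizationTest:
    def test_worked_three_lake_example(self, three_lake_instance):
        lakes, visits = three_lake_instance
        # exhaustive null: destinations {A, B, C} give statistics {1, 0, 1}
        null = enumerate_null(visits, lakes, "ph")
        assert sorted(null) == [0.0, 1.0, 1.0]
        observed = ll.observed_mean_difference(visits, lakes, "ph")
        exact_add_one = (np.count_nonzero(null <= observed) + 1) / (len(null) + 1)
        assert exact_add_one == 0.5

    def test_monte_carlo_matches_enumeration_on_the_worked_example(
            self, three_lake_instance):
        lakes, visits = three_lake_instance
        res = ll.randomization_test(visits, lakes, "ph", n_iterations=50_000,
                                    seed=1)
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=0.02)

    def test_observed_above_all_null_gives_p_one(self):
        lakes = [make_lake("N", ph=4.0), make_lake("D", lat=45.8, ph=9.0),
                 make_lake("E", lat=45.9, ph=4.5)]
        visits = [ll.VisitRecord("J1", "N", "D")]  # diff 5, null diffs {5, .5}
        res = ll.randomization_test(visits, lakes, "ph", n_iterations=999, seed=0)
        assert res.p_value == 1.0

    def test_identical_seed_identical_result(self, grid_lakes):
        visits = [ll.VisitRecord("J1", "G00", "G11"),
                  ll.VisitRecord("J2", "G22", "G01")]
        a = ll.randomization_test(visits, grid_lakes, "ph", 2000, seed=42)
        b = ll.randomization_test(visits, grid_lakes, "ph", 2000, seed=42)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_means, b.null_means)

    def test_default_iteration_count_is_ten_thousand(self, three_lake_instance):
        lakes, visits = three_lake_instance
        res = ll.randomization_test(visits, lakes, "ph", seed=0)
        assert res.n_iterations == 10_000

    def test_null_quantiles_bracket_the_null_mean(self, grid_lakes):
        visits = [ll.VisitRecord("J1", "G00", "G11"),
                  ll.VisitRecord("J2", "G22", "G01")]
        res = ll.randomization_test(visits, grid_lakes, "ph", 2000, seed=1)
        assert res.null_q025 <= res.null_mean <= res.null_q975

    def test_subset_radius_drops_long_visits(self, grid_lakes):
        near = ll.VisitRecord("J1", "G00", "G01")   # one grid step
        far = ll.VisitRecord("J2", "G00", "G44")    # opposite corner
        res = ll.randomization_test([near, far], grid_lakes, "ph", 500,
                                    subset_radius_km=12.0, seed=0)
        assert res.n_obs == 1

    def test_monte_carlo_agrees_with_enumeration_on_random_small_instances(self):
        rng = np.random.default_rng(123)
        for trial in range(8):
            n_lakes = int(rng.integers(4, 7))
            lakes = [make_lake(f"L{k}", lat=45.5 + 0.05 * k,
                               ph=float(rng.uniform(5, 9)))
                     for k in range(n_lakes)]
            n_visits = int(rng.integers(1, 4))
            visits = []
            for j in range(n_visits):
                natal, dest = rng.choice(n_lakes, size=2, replace=False)
                visits.append(ll.VisitRecord(f"J{j}", f"L{natal}", f"L{dest}"))
            null = enumerate_null(visits, lakes, "ph")
            observed = ll.observed_mean_difference(visits, lakes, "ph")
            exact = np.count_nonzero(null <= observed + 1e-12) / len(null)
            res = ll.randomization_test(visits, lakes, "ph",
                                        n_iterations=50_000, seed=trial)
            assert res.p_value == pytest.approx(exact, abs=0.02)


class TestRunAllTraits:
    @pytest.fixture()
    def dataset(self):
        lakes = ll.generate_landscape(ll.LandscapeConfig(n_lakes=50, seed=3))
        visits = ll.simulate_visits(
            lakes, ll.PreferenceModel(seed=4, n_juveniles=20))
        return lakes, visits

    def test_family_alpha_split_over_five_traits(self, dataset):
        lakes, visits = dataset
        results = ll.run_all_traits(visits, lakes, n_iterations=200, seed=0)
        assert len(results) == 5
        for r in results:
            assert r.alpha == pytest.approx(0.01)

    def test_single_trait_keeps_family_alpha(self, dataset):
        lakes, visits = dataset
        results = ll.run_all_traits(visits, lakes, traits=["ph"],
                                    n_iterations=200, seed=0)
        assert results[0].alpha == pytest.approx(0.05)

    def test_reproducible_per_seed(self, dataset):
        lakes, visits = dataset
        a = ll.run_all_traits(visits, lakes, n_iterations=300, seed=9)
        b = ll.run_all_traits(visits, lakes, n_iterations=300, seed=9)
        assert [r.p_value for r in a] == [r.p_value for r in b]
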