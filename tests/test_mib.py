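"""MIB computation, series building and the Spearman age trend."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from mibmodel import build_series, compute_mib, spearman_mib_age
from mibmodel.mib import MibPoint, MibSeries
from conftest import catch_frame

MASSES = {"A": 50.0, "B": 300.0, "C": 100.0}


def one_site_year(species_counts, site="s1", age=10.0, year=2004,
                  area="post_agri_planted"):
    return catch_frame(
        [(site, area, age, year, sp, n) for sp, n in species_counts]
    )


def brute_force_spearman_p(x, y):
    """Two-sided permutation p for Spearman rho, enumerated from scratch."""
    rho_obs = stats.spearmanr(x, y).statistic
    hits = total = 0
    for perm in permutations(y):
        rho = stats.spearmanr(x, perm).statistic
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


class TestComputeMib:
    @pytest.mark.parametrize("counts,expected_mib,expected_n,reliable", [
        ([("C", 30)], 100.0, 30, True),          # single species, >= 25
        ([("A", 10)], 50.0, 10, False),          # below the 25-catch threshold
        ([("A", 20), ("B", 30)], 200.0, 50, True),  # weighted mean 10000/50
    ])
    def test_weighted_mean_and_reliability(self, counts, expected_mib,
                                           expected_n, reliable):
        point = compute_mib(one_site_year(counts), MASSES)
        assert point.mib == pytest.approx(expected_mib)
        assert point.n_individuals == expected_n
        assert point.reliable is reliable

    def test_empty_sample_has_no_mib(self):
        point = compute_mib(one_site_year([("A", 0)]), MASSES)
        assert point.mib is None
        assert point.n_individuals == 0
        assert point.reliable is False

    def test_unknown_species_named_in_error(self):
        with pytest.raises(KeyError, match="Zabrus"):
            compute_mib(one_site_year([("Zabrus", 5)]), MASSES)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_mib(one_site_year([("A", -1)]), MASSES)

    def test_mixed_site_years_rejected(self):
        frame = catch_frame([
            ("s1", "x", 5.0, 2004, "A", 5),
            ("s2", "x", 5.0, 2004, "A", 5),
        ])
        with pytest.raises(ValueError, match="single site-year"):
            compute_mib(frame, MASSES)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.tuples(st.sampled_from("ABC"), st.integers(1, 50)),
                        min_size=1, max_size=6),
        split_idx=st.integers(0, 5),
        data=st.data(),
    )
    def test_aggregation_invariance(self, counts, split_idx, data):
        """Splitting one record into two with the same total leaves MIB unchanged."""
        before = compute_mib(one_site_year(counts), MASSES)
        i = split_idx % len(counts)
        sp, n = counts[i]
        if n < 2:
            return
        part = data.draw(st.integers(1, n - 1))
        split = counts[:i] + [(sp, part), (sp, n - part)] + counts[i + 1:]
        after = compute_mib(one_site_year(split), MASSES)
        assert after.mib == pytest.approx(before.mib, rel=1e-12)
        assert after.n_individuals == before.n_individuals

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(counts=st.lists(
        st.tuples(st.sampled_from("ABC"), st.integers(1, 50)),
        min_size=1, max_size=6))
    def test_mib_bounded_by_species_masses(self, counts):
        point = compute_mib(one_site_year(counts), MASSES)
        present = [MASSES[sp] for sp, _ in counts]
        assert min(present) <= point.mib <= max(present)


class TestBuildSeries:
    def test_three_sampling_years_give_consecutive_ages(self):
        rows = [("s1", "ash_heap", 8.0, y, "A", 30) for y in (2004, 2005, 2006)]
        series = build_series(catch_frame(rows), MASSES, "ash_heap")
        assert [p.stand_age for p in series.points] == [8.0, 9.0, 10.0]

    def test_single_site_year(self):
        series = build_series(one_site_year([("A", 30)]), MASSES,
                              "post_agri_planted")
        assert len(series) == 1

    def test_two_sites_three_years_sorted(self):
        rows = []
        for site, base in (("s1", 8.0), ("s2", 3.0)):
            for y in (2004, 2005, 2006):
                rows.append((site, "mining_heap", base, y, "A", 30))
        series = build_series(catch_frame(rows), MASSES, "mining_heap")
        ages = [p.stand_age for p in series.points]
        assert ages == [3.0, 4.0, 5.0, 8.0, 9.0, 10.0]

    def test_missing_area_type_errors(self):
        with pytest.raises(ValueError, match="area_type"):
            build_series(one_site_year([("A", 5)]), MASSES, "forest_soil_planted")

    def test_inconsistent_base_age_errors(self):
        frame = catch_frame([
            ("s1", "x", 5.0, 2004, "A", 5),
            ("s1", "x", 6.0, 2005, "A", 5),
        ])
        with pytest.raises(ValueError, match="base stand ages"):
            build_series(frame, MASSES, "x")


def series_of(ages, mibs):
    points = tuple(
        MibPoint(f"s{i}", float(a), float(m), 30, True)
        for i, (a, m) in enumerate(zip(ages, mibs))
    )
    return MibSeries("test", points)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p, n = spearman_mib_age(series_of([1, 2, 3, 4], [10, 20, 30, 40]))
        assert rho == pytest.approx(1.0)
        assert n == 4

    def test_perfect_antimonotone(self):
        rho, _, _ = spearman_mib_age(series_of([1, 2, 3, 4], [40, 30, 20, 10]))
        assert rho == pytest.approx(-1.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_mib_age(series_of([1, 2], [10, 20]))

    def test_zero_variance(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_mib_age(series_of([1, 2, 3], [10.0, 10.0, 10.0]))

    def test_unreliable_points_can_be_excluded(self):
        pts = tuple(
            MibPoint(f"s{i}", float(i), m, n_ind, n_ind >= 25)
            for i, (m, n_ind) in enumerate(
                [(10.0, 30), (20.0, 30), (30.0, 30), (40.0, 30), (5.0, 4)])
        )
        series = MibSeries("t", pts)
        rho_all, _, n_all = spearman_mib_age(series, include_unreliable=True)
        rho_rel, _, n_rel = spearman_mib_age(series, include_unreliable=False)
        assert n_all == 5 and n_rel == 4
        assert rho_rel == pytest.approx(1.0)
        assert rho_all < 1.0

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            ages = rng.permutation(n).astype(float)
            mibs = rng.uniform(10, 500, size=n)
            _, p, _ = spearman_mib_age(series_of(ages, mibs))
            assert p == pytest.approx(brute_force_spearman_p(ages, mibs))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_invariance_under_monotone_transforms(self, data):
        n = data.draw(st.integers(5, 9))
        ages = data.draw(st.lists(st.floats(0.1, 100), min_size=n, max_size=n,
                                  unique=True))
        mibs = data.draw(st.lists(st.floats(1.0, 500), min_size=n, max_size=n,
                                  unique=True))
        t_ages = [math.exp(a / 25) for a in ages]
        t_mibs = [m ** 2 for m in mibs]
        # the invariance premise is untied data: the transform must not
        # collapse adjacent floats into ties
        assume(len(set(t_ages)) == n and len(set(t_mibs)) == n)
        rho1, p1, _ = spearman_mib_age(series_of(ages, mibs))
        rho2, p2, _ = spearman_mib_age(series_of(t_ages, t_mibs))
        assert rho2 == pytest.approx(rho1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)
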