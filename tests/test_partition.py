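"""Tests for the immigrant split and the five-term partition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divpart import (
    COMPONENTS,
    TERMS,
    DatasetMismatchError,
    EmptyMetacommunityError,
    ImmigrantSplit,
    classify_immigrants,
    decompose_resident_change,
    partition_all,
    partition_change,
    partition_series,
    shannon,
    split_change,
)
from helpers import make_table, random_pair
from oracles import brute_partition

ADD_TOL = 1e-10


def _term_sum(res):
    return sum(res.terms.values())


# ---------------------------------------------------------------------------
# hypothesis strategy: random census pairs over one universe
# ---------------------------------------------------------------------------

@st.composite
def census_pairs(draw, max_species=4, max_habitats=2, max_comms=2, max_count=20):
    S = draw(st.integers(1, max_species))
    J = draw(st.integers(1, max_habitats))
    K = draw(st.integers(1, max_comms))
    C = J * K
    cells = st.lists(
        st.integers(0, max_count), min_size=S * C, max_size=S * C
    ).filter(lambda xs: sum(xs) > 0)
    habs = [j for j in range(J) for _ in range(K)]
    prev = make_table(np.array(draw(cells)).reshape(S, C), habs=habs, census=0)
    fut = prev.with_counts(np.array(draw(cells)).reshape(S, C), census=1)
    return prev, fut, habs


# ---------------------------------------------------------------------------
# classify_immigrants
# ---------------------------------------------------------------------------

class TestClassifier:
    def test_persisting_species_are_residents(self):
        prev = make_table([[5], [5]])
        fut = prev.with_counts([[8], [2]])
        split = classify_immigrants(prev, fut)
        assert split.immigrants.total == 0
        assert split.phi == 0.0
        np.testing.assert_array_equal(split.residents.counts, fut.counts)

    def test_new_species_cell_is_all_immigrant(self):
        prev = make_table([[5], [0]])
        fut = prev.with_counts([[5], [20]])
        split = classify_immigrants(prev, fut)
        assert split.immigrants.counts[1, 0] == 20
        assert split.residents.counts[1, 0] == 0

    def test_phi_ratio(self):
        prev = make_table([[5], [0]])
        fut = prev.with_counts([[20], [20]])
        assert classify_immigrants(prev, fut).phi == pytest.approx(0.5)

    def test_split_reassembles_future(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            prev, fut, _ = random_pair(rng)
            split = classify_immigrants(prev, fut)
            np.testing.assert_array_equal(
                split.immigrants.counts + split.residents.counts, fut.counts
            )
            assert split.phi == split.immigrants.total / fut.total

    def test_mismatched_universe_rejected(self):
        prev = make_table([[5], [5]])
        fut = make_table([[5], [5]], habs=[1])
        with pytest.raises(DatasetMismatchError):
            classify_immigrants(prev, fut)

    def test_empty_future_rejected(self):
        prev = make_table([[5]])
        with pytest.raises(EmptyMetacommunityError):
            classify_immigrants(prev, prev.with_counts([[0]]))


# ---------------------------------------------------------------------------
# split_change
# ---------------------------------------------------------------------------

class TestSplitChange:
    def test_no_immigrants_all_resident(self):
        prev = make_table([[10], [10]])
        fut = prev.with_counts([[30], [10]])
        imm, res = split_change(prev, fut, component="gamma")
        assert imm == 0.0
        d_h = shannon(fut, "gamma").entropy - shannon(prev, "gamma").entropy
        assert res == pytest.approx(d_h, abs=ADD_TOL)

    def test_arrival_at_baseline_rarity(self):
        # residents steady at (10, 10); immigrant species arrives with 20.
        # Pooled z': immigrants at relative abundance 0.5 are exactly as
        # rare as the baseline entropy, so the immigration term is zero
        # and residents carry the whole +0.3466 change.
        prev = make_table([[10], [10], [0]])
        fut = prev.with_counts([[10], [10], [20]])
        imm, res = split_change(prev, fut, component="gamma")
        assert imm == pytest.approx(0.0, abs=1e-12)
        assert res == pytest.approx(0.3465735903, abs=1e-9)

    def test_stationary(self):
        prev = make_table([[4, 6], [1, 3]], habs=[0, 1])
        imm, res = split_change(prev, prev.with_counts(prev.counts), component="gamma")
        assert imm == 0.0
        assert res == pytest.approx(0.0, abs=ADD_TOL)

    @given(census_pairs())
    @settings(max_examples=80, deadline=None)
    def test_two_parts_sum_to_delta(self, pair):
        prev, fut, _ = pair
        d_h = shannon(fut, "gamma").entropy - shannon(prev, "gamma").entropy
        imm, res = split_change(prev, fut, component="gamma")
        assert imm + res == pytest.approx(d_h, abs=ADD_TOL)


# ---------------------------------------------------------------------------
# decompose_resident_change
# ---------------------------------------------------------------------------

class TestDecompose:
    def test_growth_is_pure_transmission(self):
        # (10, 10) -> (30, 10): both species start equally rare, so the
        # species term cancels and transmission carries dH = -0.1308.
        prev = make_table([[10], [10]])
        fut = prev.with_counts([[30], [10]])
        split = classify_immigrants(prev, fut)
        sp, hab, comm, trans = decompose_resident_change(prev, split, "gamma")
        assert sp == pytest.approx(0.0, abs=1e-12)
        assert hab == pytest.approx(0.0, abs=1e-12)
        assert comm == pytest.approx(0.0, abs=1e-12)
        assert trans == pytest.approx(-0.1308120359, abs=1e-9)

    def test_identity_change_is_zero(self):
        prev = make_table([[3, 4], [5, 0]], habs=[0, 1])
        split = classify_immigrants(prev, prev.with_counts(prev.counts))
        for comp in COMPONENTS:
            for term in decompose_resident_change(prev, split, comp):
                assert term == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_split_rejected(self):
        prev = make_table([[5], [5]])
        fut = prev.with_counts([[2], [8]])
        # residents claimed in a cell that was empty before
        bogus = ImmigrantSplit(
            immigrants=prev.with_counts([[0], [0]]),
            residents=prev.with_counts([[2], [8]]),
            phi=0.0,
        )
        prev0 = make_table([[0], [10]])
        with pytest.raises(ValueError, match="previous occupancy"):
            decompose_resident_change(prev0, bogus, "gamma")

    @given(census_pairs())
    @settings(max_examples=80, deadline=None)
    def test_gamma_insensitive_to_lower_scales(self, pair):
        prev, fut, _ = pair
        res = partition_change(prev, fut, "gamma")
        assert res.habitat_selection == pytest.approx(0.0, abs=1e-12)
        assert res.community_selection == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# partition_change / partition_all
# ---------------------------------------------------------------------------

class TestPartitionChange:
    def test_stationary_all_zero(self):
        prev = make_table([[4, 6], [1, 3]], habs=[0, 1])
        for comp, res in partition_all(prev, prev.with_counts(prev.counts)).items():
            for v in res.terms.values():
                assert v == pytest.approx(0.0, abs=1e-12)
            assert res.total == pytest.approx(0.0, abs=1e-12)
            for f in res.hill_factors.values():
                assert f == pytest.approx(1.0, abs=1e-10)

    def test_growth_example_total(self):
        prev = make_table([[10], [10]])
        res = partition_change(prev, prev.with_counts([[30], [10]]), "gamma")
        assert res.total == pytest.approx(-0.1308120359, abs=1e-9)
        assert res.transmission == pytest.approx(res.total, abs=1e-12)

    def test_immigrant_example_terms(self):
        prev = make_table([[10], [10], [0]])
        res = partition_change(prev, prev.with_counts([[10], [10], [20]]), "gamma")
        assert res.immigration == pytest.approx(0.0, abs=1e-12)
        assert res.species_selection == pytest.approx(0.0, abs=1e-12)
        assert res.transmission == pytest.approx(0.3465735903, abs=1e-9)
        assert res.phi == pytest.approx(0.5)

    def test_all_new_species_phi_one(self):
        prev = make_table([[10], [0]])
        fut = prev.with_counts([[0], [10]])
        res = partition_change(prev, fut, "gamma")
        assert res.phi == 1.0
        assert not res.resident_defined
        assert res.species_selection == 0.0
        assert res.transmission == 0.0
        assert res.immigration == pytest.approx(res.total, abs=ADD_TOL)

    def test_extinction_stays_finite(self):
        # a resident species vanishing entirely needs no special term
        prev = make_table([[10, 10], [5, 5]], habs=[0, 1])
        fut = prev.with_counts([[12, 9], [0, 0]])
        for comp, res in partition_all(prev, fut).items():
            assert all(math.isfinite(v) for v in res.terms.values())
            assert _term_sum(res) == pytest.approx(res.total, abs=ADD_TOL)

    def test_hill_factors_multiply(self):
        rng = np.random.default_rng(3)
        prev, fut, _ = random_pair(rng)
        res = partition_change(prev, fut, "alpha")
        prod = np.prod([res.hill_factors[t] for t in TERMS])
        assert prod == pytest.approx(math.exp(res.total), rel=1e-9)

    @given(census_pairs())
    @settings(max_examples=100, deadline=None)
    def test_exact_additivity_and_beta_linearity(self, pair):
        prev, fut, _ = pair
        results = partition_all(prev, fut)
        for comp in COMPONENTS:
            res = results[comp]
            assert _term_sum(res) == pytest.approx(res.total, abs=ADD_TOL)
        for term in TERMS + ("total",):
            g = getattr(results["gamma"], term)
            a = getattr(results["alpha"], term)
            b = getattr(results["beta"], term)
            assert b == pytest.approx(g - a, abs=ADD_TOL)

    @given(census_pairs())
    @settings(max_examples=60, deadline=None)
    def test_resident_z_source_additivity(self, pair):
        prev, fut, _ = pair
        for comp, res in partition_all(prev, fut, z_source="resident").items():
            assert _term_sum(res) == pytest.approx(res.total, abs=ADD_TOL)

    def test_z_source_validated(self):
        prev = make_table([[1], [1]])
        with pytest.raises(ValueError, match="z_source"):
            partition_change(prev, prev.with_counts([[1], [2]]), "gamma", z_source="x")


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

class TestOracle:
    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(300):
            prev, fut, habs = random_pair(
                rng, max_species=3, max_habitats=2, max_comms=2, max_count=12
            )
            results = partition_all(prev, fut)
            for comp in COMPONENTS:
                expected = brute_partition(
                    prev.counts.tolist(), fut.counts.tolist(), habs, comp
                )
                res = results[comp]
                for term in TERMS + ("total",):
                    dev = abs(getattr(res, term) - expected[term])
                    worst = max(worst, dev)
        assert worst < 1e-10


# ---------------------------------------------------------------------------
# partition_series
# ---------------------------------------------------------------------------

class TestSeries:
    def _series(self, rng, n_census=8):
        prev, _, habs = random_pair(rng, max_species=4)
        tables = [prev]
        for t in range(1, n_census):
            counts = np.where(
                rng.random(prev.counts.shape) < 0.2,
                0,
                rng.integers(1, 25, prev.counts.shape),
            )
            if counts.sum() == 0:
                counts[0, 0] = 3
            tables.append(prev.with_counts(counts, census=t))
        return tables

    def test_eight_censuses_give_seven_results(self):
        tables = self._series(np.random.default_rng(0))
        out = partition_series(tables)
        assert set(out) == set(COMPONENTS)
        assert all(len(v) == 7 for v in out.values())

    def test_constant_series_all_zero(self):
        base = make_table([[4, 1], [2, 2]], habs=[0, 1])
        tables = [base.with_counts(base.counts, census=t) for t in range(4)]
        for results in partition_series(tables).values():
            for res in results:
                assert all(v == pytest.approx(0.0, abs=1e-12) for v in res.terms.values())

    def test_totals_telescope(self):
        tables = self._series(np.random.default_rng(11))
        out = partition_series(tables)
        for comp in COMPONENTS:
            direct = (
                shannon(tables[-1], comp).entropy - shannon(tables[0], comp).entropy
            )
            assert sum(r.total for r in out[comp]) == pytest.approx(direct, abs=ADD_TOL)

    def test_requires_two_censuses(self):
        with pytest.raises(ValueError, match="2 censuses"):
            partition_series([make_table([[1]])])
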