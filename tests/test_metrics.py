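import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rivertrends import metrics as M
from ._oracles import (
    jaccard_by_enumeration,
    richness_at_coverage_mc,
    simpson_by_loops,
)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (["a", "b", "c"], ["b", "c", "d"], 0.5),
            (["a", "b"], ["a", "b"], 0.0),
            (["a", "b"], ["c", "d"], 1.0),
        ],
    )
    def test_examples(self, a, b, expected):
        j, *_ = M.jaccard_dissimilarity(a, b)
        assert j == pytest.approx(expected)

    def test_two_empty_communities_error(self):
        with pytest.raises(ValueError):
            M.jaccard_dissimilarity([], [])

    @pytest.mark.parametrize(
        "gain, loss, common, jt",
        [(1, 1, 2, 0.5), (3, 0, 5, 0.0), (4, 4, 0, 1.0)],
    )
    def test_partition_examples(self, gain, loss, common, jt):
        got_jt, got_jn = M.jaccard_partition(gain, loss, common)
        assert got_jt == pytest.approx(jt)
        assert got_jn == pytest.approx(1 - jt)

    def test_partition_all_zero_errors(self):
        with pytest.raises(ValueError):
            M.jaccard_partition(0, 0, 0)


class TestSimpson:
    def test_identical_is_zero(self):
        assert M.simpson_dissimilarity({"a": 2, "b": 1}, {"a": 2, "b": 1}) == 0.0

    def test_disjoint_is_one(self):
        assert M.simpson_dissimilarity({"a": 3}, {"b": 5}) == 1.0

    def test_hand_computed_value(self):
        # p=(1,0), p'=(0.5,0.5): 0.5/(1 + 0.5 - 0.5) = 0.5
        assert M.simpson_dissimilarity({"a": 1.0}, {"a": 0.5, "b": 0.5}) == pytest.approx(0.5)

    def test_all_zero_vector_errors(self):
        with pytest.raises(ValueError):
            M.simpson_dissimilarity({"a": 0.0}, {"a": 1.0})


def _random_community(rng, pool="abcdefghijkl"):
    k = rng.integers(1, len(pool) + 1)
    species = rng.choice(list(pool), size=k, replace=False)
    return {s: float(rng.uniform(0.1, 20)) for s in species}


def test_dissimilarities_match_enumeration_oracles_on_random_pairs():
    """Jaccard/turnover/nestedness and Simpson against brute-force oracles
    on 150 random community pairs, plus symmetry and the J_t + J_n = 1
    identity."""
    rng = np.random.default_rng(11)
    for _ in range(150):
        ca, cb = _random_community(rng), _random_community(rng)
        j, gain, loss, tot, common = M.jaccard_dissimilarity(ca, cb)
        jt, jn = M.jaccard_partition(gain, loss, common)
        oj, ojt, ojn = jaccard_by_enumeration(set(ca), set(cb))
        assert j == pytest.approx(oj)
        assert jt == pytest.approx(ojt)
        assert jn == pytest.approx(ojn)
        assert jt + jn == pytest.approx(1.0)
        h = M.simpson_dissimilarity(ca, cb)
        assert h == pytest.approx(simpson_by_loops(ca, cb), abs=1e-12)
        # symmetry
        assert h == pytest.approx(M.simpson_dissimilarity(cb, ca))
        j2, *_ = M.jaccard_dissimilarity(cb, ca)
        assert j == pytest.approx(j2)


class TestPseudocounts:
    @pytest.mark.parametrize(
        "densities, expected",
        [
            ([0.5, 1.2, 0.5], [1, 2, 1]),
            ([3.0, 3.0, 3.0], [1, 1, 1]),
            ([3.0], [1]),
        ],
    )
    def test_examples(self, densities, expected):
        assert list(M.densities_to_pseudocounts(densities)) == expected

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            M.densities_to_pseudocounts([0.5, 0.0])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e4), min_size=1, max_size=30)
    )
    def test_always_yields_a_singleton(self, densities):
        """Pseudo-counts keep every species and guarantee a singleton, so
        the coverage estimator is always defined."""
        counts = M.densities_to_pseudocounts(densities)
        assert counts.min() >= 1
        assert 1 in counts
        assert 0 <= M.sample_coverage(counts) <= 1


class TestSampleCoverage:
    def test_hand_computed(self):
        # n=100, f1=10, f2=5 -> 1 - 0.1 * (990/1000) = 0.901
        counts = [1] * 10 + [2] * 5 + [80]
        assert M.sample_coverage(counts) == pytest.approx(0.901)

    def test_no_singletons_is_one(self):
        assert M.sample_coverage([2, 3, 4]) == 1.0

    def test_all_singletons_is_zero(self):
        assert M.sample_coverage([1, 1, 1, 1]) == 0.0


class TestCoverageRichness:
    def test_even_community_matches_oracle(self):
        got, capped = M.coverage_richness([10, 10, 10], 0.985)
        assert not capped
        assert 2.9 < got <= 3.0
        mc = richness_at_coverage_mc([10, 10, 10], 0.985, n_rep=30000, seed=3)
        assert got == pytest.approx(mc, abs=0.02)

    def test_target_at_observed_coverage_returns_raw_richness(self):
        counts = [1, 2, 5, 9]
        got, capped = M.coverage_richness(counts, M.sample_coverage(counts))
        assert got == pytest.approx(4.0)
        assert not capped

    def test_low_coverage_sample_is_capped_extrapolation(self):
        got, capped = M.coverage_richness([5, 3, 1, 1], 0.985)
        assert capped
        assert 4.0 < got < 4.0 + 2.0  # within S_obs + f0 under the 2n cap

    def test_matches_mc_oracle_on_random_communities(self):
        rng = np.random.default_rng(42)
        errs, tried = [], 0
        while len(errs) < 20 and tried < 300:
            tried += 1
            k = rng.integers(8, 30)
            x = rng.poisson(rng.uniform(2, 30), k) + 1
            if M.sample_coverage(x) <= 0.985 or x.sum() > 400:
                continue
            ours, _ = M.coverage_richness(x, 0.985)
            mc = richness_at_coverage_mc(x, 0.985, n_rep=1200, seed=len(errs))
            errs.append(abs(ours - mc))
        assert len(errs) == 20
        assert max(errs) < 0.05

    def test_monotone_families_preserve_rank(self):
        """Raw and coverage richness agree in rank over nested communities."""
        base = np.array([30, 20, 12, 8, 5, 3, 2, 2])
        raw, cov = [], []
        for k in range(3, len(base) + 1):
            raw.append(k)
            cov.append(M.coverage_richness(base[:k], 0.985)[0])
        assert np.all(np.diff(cov) > 0)


class TestNonnativeProportions:
    def test_example(self):
        got = M.nonnative_proportions(
            {"a": 8.0, "b": 2.0}, {"a": "native", "b": "nonnative"}
        )
        assert got == (pytest.approx(0.2), pytest.approx(0.5))

    @pytest.mark.parametrize(
        "origins, expected",
        [({"a": "native", "b": "native"}, (0.0, 0.0)),
         ({"a": "nonnative", "b": "nonnative"}, (1.0, 1.0))],
    )
    def test_boundaries(self, origins, expected):
        assert M.nonnative_proportions({"a": 1.0, "b": 1.0}, origins) == expected

    def test_unknown_counts_as_native(self):
        got = M.nonnative_proportions({"a": 1.0, "b": 1.0}, {"a": "unknown"})
        assert got == (0.0, 0.0)


def _series_frame(communities, site="s1", unit="count"):
    """communities: {year: {species: abundance}}"""
    rows = []
    for year, comm in communities.items():
        for sp, ab in comm.items():
            rows.append(
                {"site_id": site, "basin_id": "b1",
                 "date": pd.Timestamp(year, 6, 15), "protocol": "ef",
                 "species_id": sp, "abundance": ab, "unit": unit,
                 "origin": "native"}
            )
    return pd.DataFrame(rows)


class TestMetricsSeries:
    def test_constant_community_flat(self):
        comm = {y: {"a": 5.0, "b": 3.0} for y in range(2000, 2005)}
        out = M.metrics_series(_series_frame(comm))
        assert (out["jaccard"] == 0).all()
        assert (out["simpson_dissim"] == 0).all()
        assert out["total_abundance"].nunique() == 1

    def test_baseline_row_is_zero(self):
        comm = {2000: {"a": 5.0}, 2001: {"b": 4.0}}
        out = M.metrics_series(_series_frame(comm))
        first = out.iloc[0]
        assert first["t"] == 0
        assert first[["jaccard", "turnover", "simpson_dissim"]].eq(0).all()

    def test_one_replacement_per_year_increases_jaccard(self):
        pool = list("abcdefgh")
        comm = {
            2000 + i: {s: 2.0 for s in pool[i: i + 4]} for i in range(5)
        }
        out = M.metrics_series(_series_frame(comm))
        j = out["jaccard"].to_numpy()
        assert np.all(np.diff(j) > 0)

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            M.metrics_series(_series_frame({2000: {"a": 1.0}}))

    def test_density_series_uses_pseudocounts(self):
        comm = {y: {"a": 0.5, "b": 1.2} for y in (2000, 2001)}
        out = M.metrics_series(_series_frame(comm, unit="density_100m2"))
        assert (out["richness_cov"] > 0).all()
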