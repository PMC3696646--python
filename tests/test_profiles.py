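"""Uncentered-Pearson clustering and hypergeometric enrichment."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecmprofiler.matrix import AbundanceMatrix
from ecmprofiler.profiles import (
    cluster_proteins,
    enrich_cluster,
    hypergeom_upper_tail,
    uncentered_pearson,
)


def make_matrix(profiles: dict[str, list[float]]) -> AbundanceMatrix:
    vals = pd.DataFrame.from_dict(profiles, orient="index").astype(float)
    vals.columns = [f"s{i}" for i in range(vals.shape[1])]
    return AbundanceMatrix(vals, vals > 0)


class TestUncenteredPearson:
    def test_identity(self):
        assert uncentered_pearson([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert uncentered_pearson([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_direct_formula(self):
        # (1*2 + 2*1) / sqrt(5 * 5) = 4/5
        assert uncentered_pearson([1.0, 2.0], [2.0, 1.0]) == pytest.approx(0.8)

    def test_zero_norm_is_error(self):
        with pytest.raises(ValueError, match="zero-norm"):
            uncentered_pearson([0.0, 0.0], [1.0, 2.0])

    @given(
        x=st.lists(st.floats(0.01, 1e3), min_size=2, max_size=8),
        c=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_scale_invariance(self, x, c):
        y = [v + 1.0 for v in x][::-1]
        r1 = uncentered_pearson(x, y)
        r2 = uncentered_pearson(x, [c * v for v in y])
        assert r1 == pytest.approx(r2, rel=1e-9)
        assert -1.0 - 1e-12 <= r1 <= 1.0 + 1e-12


class TestClusterProteins:
    def test_identical_profiles_form_one_cluster(self):
        # A and B identical up to scale (r_u = 1); C nearly orthogonal
        # (r_u(A, C) = 5 / (sqrt(14) * 5) ~ 0.27 < 0.5)
        m = make_matrix({"A": [1, 2, 3], "B": [2, 4, 6], "C": [5, 0, 0]})
        cs = cluster_proteins(m, threshold=0.5)
        assert ["A", "B"] in cs.clusters
        assert "C" in cs.singletons

    def test_orthogonal_profiles_stay_singletons(self):
        m = make_matrix({"A": [1, 0, 0], "B": [0, 1, 0], "C": [0, 0, 1]})
        cs = cluster_proteins(m, threshold=0.5)
        assert cs.clusters == [] and set(cs.singletons) == {"A", "B", "C"}

    def test_zero_profile_dropped_with_warning(self, caplog):
        m = make_matrix({"A": [1, 2], "B": [2, 4], "Z": [0, 0]})
        with caplog.at_level("WARNING"):
            cs = cluster_proteins(m)
        assert cs.dropped == ["Z"] and "Z" not in cs.proteins

    def test_too_few_valid_proteins(self):
        m = make_matrix({"A": [1, 2], "Z": [0, 0]})
        with pytest.raises(ValueError, match="at least two"):
            cluster_proteins(m)

    def test_planted_two_group_partition_recovered(self, rng):
        # two planted profile shapes across 6 samples; within-group r_u > 0.9,
        # between-group r_u < 0.1 by construction
        shape1 = np.array([10.0, 9.0, 8.0, 0.0, 0.0, 0.0])
        shape2 = np.array([0.0, 0.0, 0.0, 7.0, 9.0, 11.0])
        profiles = {}
        for i in range(8):
            base = shape1 if i < 4 else shape2
            profiles[f"G{i}"] = base * rng.uniform(0.5, 2.0) + rng.uniform(0, 0.3, 6)
        m = make_matrix(profiles)
        cs = cluster_proteins(m, threshold=0.5)
        got = {frozenset(c) for c in cs.clusters}
        expected = {
            frozenset(f"G{i}" for i in range(4)),
            frozenset(f"G{i}" for i in range(4, 8)),
        }
        assert got == expected and not cs.singletons

    def test_cluster_roots_meet_similarity_threshold(self, rng):
        profiles = {f"G{i}": rng.uniform(0, 10, 5) for i in range(12)}
        m = make_matrix(profiles)
        cs = cluster_proteins(m, threshold=0.5)
        # within every extracted cluster, all pairwise cophenetic similarities
        # (>= root merge similarity) respect the threshold
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import pdist, squareform

        coph = squareform(cophenet(cs.linkage_matrix, pdist(m.values.to_numpy(), "cosine"))[1])
        idx = {p: i for i, p in enumerate(cs.proteins)}
        for cluster in cs.clusters:
            for a, b in combinations(cluster, 2):
                assert 1.0 - coph[idx[a], idx[b]] >= 0.5 - 1e-12

    def test_deterministic_given_input_order(self, rng):
        profiles = {f"G{i}": rng.uniform(0, 10, 5) for i in range(15)}
        m = make_matrix(profiles)
        a, b = cluster_proteins(m), cluster_proteins(m)
        assert a.clusters == b.clusters and a.leaf_order == b.leaf_order


def enumeration_oracle(k, K, n, N):
    """P(overlap >= k) by exhaustive enumeration of n-subsets of N."""
    hits = total = 0
    universe = range(N)
    annotated = set(range(K))
    for subset in combinations(universe, n):
        total += 1
        if len(annotated & set(subset)) >= k:
            hits += 1
    return hits / total


class TestEnrichment:
    def test_term_covering_background_has_p_one(self):
        ann = {f"g{i}": {"GO:X"} for i in range(10)}
        results = enrich_cluster([f"g{i}" for i in range(4)], ann, list(ann))
        assert results[0].p_value == pytest.approx(1.0)

    def test_exact_overlap_probability(self):
        # all 5 cluster members annotated, 5 of 10 in background: 1/C(10,5)
        assert hypergeom_upper_tail(5, 5, 5, 10) == pytest.approx(1 / comb(10, 5))

    @pytest.mark.parametrize(
        "k,K,n,N",
        [(2, 4, 3, 8), (1, 5, 5, 10), (3, 6, 4, 12), (4, 4, 4, 9), (0, 3, 2, 7)],
    )
    def test_matches_enumeration_oracle(self, k, K, n, N):
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
            enumeration_oracle(k, K, n, N), rel=1e-9
        )

    def test_matches_monte_carlo_within_3_se(self, rng):
        k, K, n, N = 4, 10, 8, 30
        p = hypergeom_upper_tail(k, K, n, N)
        draws = rng.hypergeometric(K, N - K, n, size=100_000)
        p_hat = float(np.mean(draws >= k))
        se = np.sqrt(p_hat * (1 - p_hat) / draws.size)
        assert abs(p - p_hat) <= 3 * se

    def test_benjamini_hochberg_step_up(self):
        # p = (0.01, 0.02, 0.03, 0.04), m = 4: q_i = min_{j>=i} p_j * m / j = 0.04
        ann = {"a": {"T1"}, "b": {"T2"}, "c": {"T3"}, "d": {"T4"}}
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_ease_variant_is_conservative(self):
        ann = {f"g{i}": ({"GO:X"} if i < 6 else set()) for i in range(20)}
        cluster = [f"g{i}" for i in range(3, 8)]
        bg = list(ann)
        plain = enrich_cluster(cluster, ann, bg)[0]
        ease = enrich_cluster(cluster, ann, bg, ease=True)[0]
        assert ease.p_value >= plain.p_value

    def test_background_must_contain_cluster(self):
        with pytest.raises(ValueError, match="background"):
            enrich_cluster(["a"], {}, ["b"])

    def test_null_false_positive_rate_controlled(self, rng):
        # shuffled labels: fraction of clusters with any q <= 0.05 term should
        # not exceed alpha by more than sampling error
        n_runs, hits = 150, 0
        symbols = [f"g{i}" for i in range(40)]
        for _ in range(n_runs):
            terms = [f"T{j}" for j in range(8)]
            ann = {s: set(rng.choice(terms, size=2, replace=False)) for s in symbols}
            cluster = list(rng.choice(symbols, size=8, replace=False))
            results = enrich_cluster(cluster, ann, symbols)
            hits += any(r.significant for r in results)
        rate = hits / n_runs
        se = np.sqrt(0.05 * 0.95 / n_runs)
        assert rate <= 0.05 + 2 * se
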