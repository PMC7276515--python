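"""Preranked enrichment: running-sum oracle, exhaustive permutation
oracle, determinism and null calibration."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdbexpr.enrichment import (GeneSetCollection, build_ranked_list,
                                enrichment_score, overlap_edges,
                                permute_and_score)


def brute_force_es(scores, hit_mask, weight):
    """Independent oracle: walk the list position by position and track
    the weighted running sum; ES is the signed maximal deviation."""
    scores = np.asarray(scores, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    N, K = len(scores), hit_mask.sum()
    if K == N:
        return 0.0
    total = np.sum(np.abs(scores[hit_mask]) ** weight)
    running, es = 0.0, 0.0
    for i in range(N):
        if hit_mask[i]:
            running += np.abs(scores[i]) ** weight / total
        else:
            running -= 1.0 / (N - K)
        if abs(running) > abs(es):
            es = running
    return es


def _ranked(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    return pd.DataFrame({"gene": genes, "score": scores})


class TestBuildRankedList:
    def test_single_transcript_genes_identity(self):
        t = pd.DataFrame({"transcript": ["t1", "t2"], "gene": ["A", "B"],
                          "beta": [1.0, -1.0], "se": [0.5, 0.5]})
        for seed in (0, 1, 99):
            out = build_ranked_list(t, seed=seed)
            assert list(out["gene"]) == ["A", "B"]
            np.testing.assert_allclose(out["score"], [2.0, -2.0])

    def test_random_transcript_choice_is_seeded(self):
        t = pd.DataFrame({"transcript": [f"t{i}" for i in range(3)],
                          "gene": "A", "beta": [1.0, 2.0, 3.0],
                          "se": [1.0, 1.0, 1.0]})
        picks = {build_ranked_list(t, seed=s)["score"].iloc[0]
                 for s in range(12)}
        assert len(picks) > 1          # different seeds can differ
        a = build_ranked_list(t, seed=4)
        b = build_ranked_list(t, seed=4)
        pd.testing.assert_frame_equal(a, b)   # same seed identical

    def test_output_length_is_distinct_gene_count(self, rng):
        genes = rng.choice([f"G{i}" for i in range(80)], size=200)
        t = pd.DataFrame({"transcript": [f"t{i}" for i in range(200)],
                          "gene": genes,
                          "beta": rng.normal(size=200), "se": 1.0})
        out = build_ranked_list(t, seed=0)
        assert len(out) == len(set(genes))
        assert (out["score"].to_numpy()[:-1]
                >= out["score"].to_numpy()[1:] - 1e-12).all()


class TestEnrichmentScore:
    def test_matches_brute_force_on_random_small_cases(self, rng):
        for _ in range(50):
            N = int(rng.integers(4, 11))
            scores = np.sort(rng.normal(size=N))[::-1]
            K = int(rng.integers(1, N))
            members = rng.choice(N, size=K, replace=False)
            mask = np.zeros(N, bool)
            mask[members] = True
            ranked = _ranked(scores)
            for weight in (0.0, 1.0):
                es, _, _ = enrichment_score(
                    ranked, ranked["gene"].to_numpy()[mask], weight=weight)
                assert es == pytest.approx(
                    brute_force_es(scores, mask, weight), abs=1e-12)

    def test_top_k_set_scores_positive_and_peaks_at_k(self):
        N, k = 10, 3
        ranked = _ranked(np.linspace(2, -2, N))
        members = ranked["gene"].iloc[:k].tolist()
        es, running, leading = enrichment_score(ranked, members, weight=0.0)
        assert es > 0
        assert np.argmax(running) == k - 1
        assert leading == members
        # with weight 0 the peak value is k/k - 0 misses = 1 - 0, reached
        # after the k-th hit having passed no misses: ES = 1 - 0/(N-k)
        assert es == pytest.approx(1.0)
        assert es == pytest.approx(brute_force_es(
            ranked["score"], np.arange(N) < k, 0.0))

    def test_whole_universe_set_scores_zero(self):
        ranked = _ranked(np.linspace(1, -1, 5))
        es, running, leading = enrichment_score(ranked, ranked["gene"],
                                                weight=0.0)
        assert es == 0.0

    def test_reversal_negates_es_at_weight_zero(self, rng):
        scores = np.sort(rng.normal(size=9))[::-1]
        ranked = _ranked(scores)
        members = ranked["gene"].iloc[[0, 3]].tolist()
        es_f, _, _ = enrichment_score(ranked, members, weight=0.0)
        rev = _ranked(scores[::-1], genes=list(ranked["gene"][::-1]))
        es_r, _, _ = enrichment_score(rev, members, weight=0.0)
        assert es_r == pytest.approx(-es_f, abs=1e-12)

    def test_es_bounded(self, rng):
        for _ in range(30):
            N = int(rng.integers(5, 40))
            ranked = _ranked(np.sort(rng.normal(size=N))[::-1])
            K = int(rng.integers(1, N))
            members = ranked["gene"].sample(K, random_state=1).tolist()
            es, _, _ = enrichment_score(ranked, members)
            assert -1.0 <= es <= 1.0

    def test_no_overlap_raises(self):
        ranked = _ranked([1.0, 0.5])
        with pytest.raises(ValueError, match="no members"):
            enrichment_score(ranked, ["absent"])


class TestPermuteAndScore:
    def test_permutation_p_matches_exhaustive_enumeration(self):
        """N=8, |set|=2, equal |scores|, weight 0: the permutation p
        must agree with exhaustive enumeration over all C(8,2)=28
        placements within Monte Carlo error."""
        scores = np.array([1.0] * 4 + [-1.0] * 4)
        ranked = _ranked(scores)
        members = ranked["gene"].iloc[[0, 1]].tolist()
        es_obs = enrichment_score(ranked, members, weight=0.0)[0]
        null = [brute_force_es(scores, np.isin(np.arange(8), c), 0.0)
                for c in map(list, combinations(range(8), 2))]
        null = np.array(null)
        same_sign = null[null >= 0] if es_obs >= 0 else null[null < 0]
        p_exact = (np.sum(same_sign >= es_obs) / len(same_sign)
                   if es_obs >= 0 else
                   np.sum(same_sign <= es_obs) / len(same_sign))
        coll = GeneSetCollection(sets={"S": set(members)})
        n_perm = 4000
        out = permute_and_score(ranked, coll, n_perm=n_perm, seed=7,
                                weight=0.0, min_size=1, max_size=10)
        p_mc = out.iloc[0]["perm_p"]
        mc_err = np.sqrt(p_exact * (1 - p_exact) / (n_perm / 2))
        assert p_mc == pytest.approx(p_exact, abs=3 * mc_err + 2 / n_perm)

    def test_bit_identical_under_same_seed(self, rng):
        ranked = _ranked(np.sort(rng.normal(size=60))[::-1])
        sets = {f"S{i}": set(ranked["gene"].sample(12, random_state=i))
                for i in range(5)}
        coll = GeneSetCollection(sets=sets)
        a = permute_and_score(ranked, coll, n_perm=150, seed=3)
        b = permute_and_score(ranked, coll, n_perm=150, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_null_p_uniform_over_random_sets(self, rng):
        """Random sets on random scores: permutation p approximately
        uniform (KS at alpha=0.01 over 200 sets)."""
        ranked = _ranked(np.sort(rng.normal(size=300))[::-1])
        sets = {f"S{i}": set(rng.choice(ranked["gene"], 15, replace=False))
                for i in range(200)}
        out = permute_and_score(ranked, GeneSetCollection(sets=sets),
                                n_perm=500, seed=1)
        ks = stats.kstest(out["perm_p"], "uniform")
        assert ks.pvalue > 0.01

    def test_size_filter_and_untestable_flag(self, rng):
        ranked = _ranked(np.sort(rng.normal(size=50))[::-1])
        sets = {"tiny": {ranked["gene"].iloc[0]},
                "foreign": {"absent1", "absent2", "absent3"},
                "ok": set(ranked["gene"].iloc[:15])}
        out = permute_and_score(ranked, GeneSetCollection(sets=sets),
                                n_perm=120, seed=0, min_size=10)
        assert set(out["set"]) == {"foreign", "ok"}
        assert not out.set_index("set").loc["foreign", "testable"]

    def test_oversized_set_raises(self):
        ranked = _ranked([1.0, -1.0])
        coll = GeneSetCollection(sets={"big": {"a", "b", "c"}})
        with pytest.raises(ValueError, match="larger than"):
            permute_and_score(ranked, coll, n_perm=100, seed=0)


class TestOverlapEdges:
    def test_identical_sets_full_weight(self):
        out = overlap_edges({"A": {"x", "y"}, "B": {"x", "y"}})
        assert len(out) == 1 and out.iloc[0]["weight"] == 1.0

    def test_disjoint_sets_no_edge(self):
        assert overlap_edges({"A": {"x"}, "B": {"y"}}).empty

    def test_threshold_arithmetic(self):
        a = set(range(10))
        b = set(range(7, 27))            # |A∩B| = 3, min size 10 -> 0.3
        out = overlap_edges({"A": a, "B": b})
        assert len(out) == 1
        assert out.iloc[0]["weight"] == pytest.approx(0.3)
        out2 = overlap_edges({"A": a, "B": b}, threshold=0.35)
        assert out2.empty
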