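"""Consensus-clustering core: PAM, ensemble dissimilarity, agglomeration."""

import numpy as np
import pytest

import eaccd
from eaccd.core import (
    DissimilarityMatrix,
    EnsembleConfig,
    MergeTree,
    agglomerate,
    cophenetic_matrix,
    cut_tree,
    ensemble_dissimilarity,
    initial_dissimilarity,
    pam_partition,
)

from _oracles import exhaustive_pam_optimum, naive_cophenetic, scipy_merge_tree


def random_dissimilarity(rng, n, labels=None):
    m = rng.uniform(0.1, 2.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DissimilarityMatrix(labels or tuple(f"x{i}" for i in range(n)), m)


class TestDissimilarityMatrix:
    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DissimilarityMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            DissimilarityMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_standardized_max_is_one_and_zero_matrix_rejected(self, rng):
        d = random_dissimilarity(rng, 5)
        assert d.standardized().values.max() == pytest.approx(1.0)
        zero = DissimilarityMatrix(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="no separation"):
            zero.standardized()


class TestPam:
    def test_k_equals_n_gives_singletons_with_zero_objective(self, rng):
        d = random_dissimilarity(rng, 6)
        p = pam_partition(d, 6, init="build")
        assert p.objective == 0.0
        assert sorted(p.medoids) == list(range(6))
        assert sorted(set(p.assignment)) == list(range(1, 7))

    def test_k_one_medoid_is_row_sum_argmin(self, rng):
        d = random_dissimilarity(rng, 7)
        p = pam_partition(d, 1, init="build")
        assert p.medoids[0] == int(d.values.sum(axis=1).argmin())
        assert p.objective == pytest.approx(d.values[p.medoids[0]].sum())

    def test_k_out_of_range_rejected(self, rng):
        d = random_dissimilarity(rng, 4)
        with pytest.raises(ValueError):
            pam_partition(d, 5, init="build")

    def test_objective_consistent_with_assignment(self, rng):
        d = random_dissimilarity(rng, 8)
        p = pam_partition(d, 3, init="random", rng=rng)
        med = sorted(p.medoids)
        recomputed = sum(
            d.values[i, med[c - 1]] for i, c in enumerate(p.assignment)
        )
        assert p.objective == pytest.approx(recomputed)
        # each medoid belongs to its own cluster
        for pos, m in enumerate(med, start=1):
            assert p.assignment[m] == pos

    @pytest.mark.parametrize("k", [2, 3])
    def test_never_beats_exhaustive_optimum_and_restarts_find_it(self, k):
        """On 7-point instances the swap phase's local optimum is bounded
        below by the exhaustive optimum, and best-of-20 random restarts
        attains it on nearly every instance."""
        master = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            d = random_dissimilarity(master, 7)
            opt = exhaustive_pam_optimum(d.values, k)
            best = np.inf
            for _ in range(20):
                p = pam_partition(d, k, init="random", rng=master)
                assert p.objective >= opt - 1e-9
                best = min(best, p.objective)
            if best <= opt + 1e-9:
                hits += 1
        assert hits >= 95

    def test_build_init_is_deterministic(self, rng):
        d = random_dissimilarity(rng, 9)
        p1 = pam_partition(d, 3, init="build")
        p2 = pam_partition(d, 3, init="build")
        assert p1 == p2


class TestEnsemble:
    def test_single_run_entries_are_binary(self, rng):
        d = random_dissimilarity(rng, 6)
        cfg = EnsembleConfig(m=1, k_min=2, k_max=4, seed=5)
        out = ensemble_dissimilarity(d, cfg)
        assert set(np.unique(out.values)) <= {0.0, 1.0}

    def test_consensus_bounds_diagonal_and_symmetry(self, rng):
        d = random_dissimilarity(rng, 8)
        for m, seed in [(1, 0), (7, 1), (100, 2)]:
            cfg = EnsembleConfig(m=m, k_min=2, k_max=7, seed=seed)
            out = ensemble_dissimilarity(d, cfg)
            assert np.all(out.values >= 0) and np.all(out.values <= 1)
            assert np.all(np.diag(out.values) == 0)
            np.testing.assert_array_equal(out.values, out.values.T)

    def test_reproducible_from_seed(self, rng):
        d = random_dissimilarity(rng, 6)
        cfg = EnsembleConfig(m=200, k_min=2, k_max=5, seed=77)
        a = ensemble_dissimilarity(d, cfg)
        b = ensemble_dissimilarity(d, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_planted_separation_dominates_consensus(self):
        """Two blocks with large between-block dissimilarity: between-block
        consensus approaches 1 and strictly exceeds every within-block
        entry (the separation property; individual within-block values
        depend on how splits rotate across K draws)."""
        n = 8
        m = np.full((n, n), 10.0)
        block = [0, 1, 2, 3]
        for i in range(n):
            for j in range(n):
                if (i in block) == (j in block):
                    m[i, j] = np.random.default_rng(i * n + j).uniform(0.1, 0.4)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        d = DissimilarityMatrix(tuple(f"x{i}" for i in range(n)), m)
        cfg = EnsembleConfig(m=10000, k_min=2, k_max=7, seed=0)
        out = ensemble_dissimilarity(d, cfg)
        within = [out.values[i, j] for i in range(n) for j in range(n)
                  if i < j and (i in block) == (j in block)]
        between = [out.values[i, j] for i in range(n) for j in range(n)
                   if i < j and (i in block) != (j in block)]
        assert max(within) < min(between)
        assert min(between) > 0.95

    def test_invalid_config_rejected(self, rng):
        d = random_dissimilarity(rng, 5)
        with pytest.raises(ValueError):
            ensemble_dissimilarity(d, EnsembleConfig(m=0, k_min=2, k_max=4))
        with pytest.raises(ValueError):
            ensemble_dissimilarity(d, EnsembleConfig(m=5, k_min=2, k_max=5))
        with pytest.raises(ValueError):
            ensemble_dissimilarity(d, EnsembleConfig(m=5, k_min=3, k_max=2))


class TestAgglomerate:
    def test_two_points_single_merge_at_their_dissimilarity(self):
        d = DissimilarityMatrix(("a", "b"), np.array([[0.0, 0.7], [0.7, 0.0]]))
        tree = agglomerate(d, "average")
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(0.7)

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    def test_matches_scipy_on_random_matrices(self, method):
        """Merge topology and heights agree with scipy's independent
        (nearest-neighbour-chain) agglomeration on 100 random 5-7 point
        matrices."""
        master = np.random.default_rng(31337)
        for _ in range(100):
            n = int(master.integers(5, 8))
            d = random_dissimilarity(master, n)
            ours = agglomerate(d, method)
            ref = scipy_merge_tree(d.values, method)
            ours_sets = {frozenset(a) | frozenset(b) for a, b, _ in ours.merges}
            ref_sets = {a | b for a, b, _ in ref}
            assert ours_sets == ref_sets
            np.testing.assert_allclose(
                sorted(h for _, _, h in ours.merges),
                sorted(h for _, _, h in ref),
                rtol=1e-10,
            )

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    def test_heights_non_decreasing(self, method, rng):
        d = random_dissimilarity(rng, 9)
        tree = agglomerate(d, method)
        assert np.all(np.diff(tree.heights()) >= -1e-12)

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    def test_ultrametric_input_is_a_fixed_point(self, method):
        """Agglomerating an ultrametric returns cophenetic distances equal
        to the input for every linkage."""
        base = DissimilarityMatrix(
            tuple("abcde"), np.array([
                [0, 1, 4, 4, 4],
                [1, 0, 4, 4, 4],
                [4, 4, 0, 2, 3],
                [4, 4, 2, 0, 3],
                [4, 4, 3, 3, 0],
            ], dtype=float),
        )
        tree = agglomerate(base, method)
        np.testing.assert_allclose(cophenetic_matrix(tree).values, base.values)

    def test_single_leaf_rejected(self):
        d = DissimilarityMatrix(("a",), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            agglomerate(d)

    def test_deterministic_tie_break_on_exact_ties(self):
        values = np.array([
            [0.0, 1.0, 1.0, 5.0],
            [1.0, 0.0, 1.0, 5.0],
            [1.0, 1.0, 0.0, 5.0],
            [5.0, 5.0, 5.0, 0.0],
        ])
        tree = agglomerate(DissimilarityMatrix(tuple("abcd"), values), "average")
        assert tree.merges[0][:2] == ((0,), (1,))  # lowest index pair first


class TestCutAndCophenetic:
    def test_cut_extremes(self, rng):
        d = random_dissimilarity(rng, 6)
        tree = agglomerate(d)
        assert set(cut_tree(tree, 1).values()) == {1}
        assert sorted(cut_tree(tree, 6).values()) == [1, 2, 3, 4, 5, 6]
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 7)

    def test_cut_respects_merge_order(self):
        d = DissimilarityMatrix(
            tuple("abcd"), np.array([
                [0, 1, 8, 9],
                [1, 0, 8, 9],
                [8, 8, 0, 2],
                [9, 9, 2, 0],
            ], dtype=float),
        )
        tree = agglomerate(d, "average")
        assert cut_tree(tree, 2) == {"a": 1, "b": 1, "c": 2, "d": 2}

    def test_cophenetic_matches_naive_and_is_ultrametric(self, rng):
        d = random_dissimilarity(rng, 6)
        tree = agglomerate(d, "average")
        coph = cophenetic_matrix(tree)
        np.testing.assert_allclose(
            coph.values,
            naive_cophenetic(
                [(frozenset(a), frozenset(b), h) for a, b, h in tree.merges], 6
            ),
        )
        # three-point condition: d(i,j) <= max(d(i,k), d(j,k)) for all triples
        v = coph.values
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert v[i, j] <= max(v[i, k], v[j, k]) + 1e-12


class TestMergeTreeSerialization:
    def test_newick_round_trips_through_dendropy(self, rng):
        import dendropy

        d = random_dissimilarity(rng, 5)
        tree = agglomerate(d, "average")
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == set(d.labels)
        # root height recoverable as distance from any leaf to root
        root_h = tree.heights()[-1]
        leaf = next(t.leaf_node_iter())
        depth = leaf.edge.length + sum(
            nd.edge.length for nd in leaf.ancestor_iter() if nd.edge.length
        )
        assert depth == pytest.approx(root_h)

    def test_json_lists_all_merges(self, rng):
        import json

        d = random_dissimilarity(rng, 6)
        tree = agglomerate(d)
        payload = json.loads(tree.to_json())
        assert len(payload["merges"]) == 5
        assert payload["labels"] == list(d.labels)


class TestInitialDissimilarity:
    def test_identical_cohorts_give_zero_entry(self):
        recs = tuple(
            eaccd.PatientRecord(float(t), 1, ("g",)) for t in (1, 3, 5, 9)
        )
        a = eaccd.CombinationCohort("A", ("g",), recs)
        b = eaccd.CombinationCohort("B", ("g",), recs)
        d = initial_dissimilarity([a, b])
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hazard_ordering_reflected(self):
        gen = np.random.default_rng(11)
        def cohort(label, h):
            return eaccd.CombinationCohort(
                label, (label,),
                tuple(eaccd.PatientRecord(float(t), 1, (label,))
                      for t in gen.exponential(1 / h, 200)),
            )
        cohorts = [cohort("a", 0.1), cohort("b", 0.1), cohort("c", 1.0)]
        d = initial_dissimilarity(cohorts)
        assert d.values[0, 1] < d.values[0, 2]
        assert d.values[0, 1] < d.values[1, 2]

    def test_twelve_cohorts_shape_and_symmetry(self, dis0):
        d = dis0("logrank")
        assert d.values.shape == (12, 12)
        np.testing.assert_array_equal(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        assert np.all(d.values >= 0)


class TestRunEaccd:
    def test_full_pipeline_contracts(self, standard_cohorts):
        cfg = EnsembleConfig(m=50, k_min=2, k_max=11, seed=3)
        res = eaccd.run_eaccd(standard_cohorts, "logrank", cfg, "average")
        assert res.dis0.labels == res.dis.labels == res.tree.labels
        assert np.all(res.dis.values >= 0) and np.all(res.dis.values <= 1)
        assert len(res.tree.merges) == 11

    def test_seeded_runs_are_bit_identical(self, standard_cohorts):
        cfg = EnsembleConfig(m=30, k_min=2, k_max=11, seed=9)
        r1 = eaccd.run_eaccd(standard_cohorts, "logrank", cfg)
        r2 = eaccd.run_eaccd(standard_cohorts, "logrank", cfg)
        np.testing.assert_array_equal(r1.dis.values, r2.dis.values)
        assert r1.tree == r2.tree
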