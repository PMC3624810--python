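"""Binary gap recoding and maximum-parsimony search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapguide import gapparsimony
from gapguide.alignment import Alignment

from conftest import tree


def matrix(taxa, rows):
    data = np.array(rows, dtype=np.uint8)
    return gapparsimony.BinaryGapMatrix(
        taxa=list(taxa),
        data=data,
        provenance=[(0, j) for j in range(data.shape[1])],
    )


# the 4-taxon example: characters split AB|CD and AC|BD respectively
M4 = matrix("ABCD", [[1, 1], [1, 0], [0, 1], [0, 0]])


class TestRecode:
    def test_hand_recoding(self):
        aln = Alignment({"s1": "A-CG", "s2": "AACG", "s3": "A--G"})
        m = gapparsimony.recode_gap_patterns(aln)
        assert m.taxa == ["s1", "s2", "s3"]
        assert m.n_characters == 2
        np.testing.assert_array_equal(m.data, [[1, 0], [0, 0], [1, 1]])
        assert m.provenance == [(0, 1), (0, 2)]

    def test_gap_free_alignment_gives_empty_matrix(self):
        m = gapparsimony.recode_gap_patterns(Alignment({"a": "MK", "b": "MV"}))
        assert m.n_characters == 0
        assert m.n_variable == 0

    def test_shared_gap_column_recoded_with_remaining_residue(self):
        aln = Alignment({"a": "M-K", "b": "M-K", "c": "MWK"})
        m = gapparsimony.recode_gap_patterns(aln)
        np.testing.assert_array_equal(m.data, [[1], [1], [0]])


class TestScore:
    # verified independently with R/phangorn: character 1 (AB|CD) costs one
    # change on the matching tree, character 2 (AC|BD) costs two there
    def test_score_on_matching_quartet(self):
        assert gapparsimony.parsimony_score(M4, tree("((A,B),(C,D));")) == 3

    def test_score_on_alternative_quartet(self):
        assert gapparsimony.parsimony_score(M4, tree("((A,C),(B,D));")) == 3

    def test_score_on_worst_quartet(self):
        assert gapparsimony.parsimony_score(M4, tree("((A,D),(B,C));")) == 4

    def test_constant_character_costs_nothing(self):
        m = matrix("ABCD", [[1], [1], [1], [0]])
        for nwk in ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]:
            assert gapparsimony.parsimony_score(m, tree(nwk)) == 1
        m0 = matrix("ABCD", [[0, 1], [0, 1], [0, 1], [0, 1]])
        # both characters all-identical: zero changes anywhere
        assert gapparsimony.parsimony_score(m0, tree("((A,B),(C,D));")) == 0

    def test_missing_leaf_row_rejected(self):
        with pytest.raises(gapparsimony.GapParsimonyError, match="without"):
            gapparsimony.parsimony_score(M4, tree("((A,B),(C,E));"))

    def test_lower_bound_is_variable_character_count(self):
        rng = np.random.default_rng(4)
        m = matrix("ABCDEF", rng.integers(0, 2, size=(6, 15)))
        score = gapparsimony.parsimony_score(
            m, tree("((A,B),(C,D),(E,F));")
        )
        assert score >= m.n_variable

    @given(seed=st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_score_invariant_under_taxon_and_character_permutation(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 2, size=(5, 8))
        taxa = ["A", "B", "C", "D", "E"]
        t = tree("((A,B),(C,(D,E)));")
        m1 = matrix(taxa, data)
        perm_t = rng.permutation(5)
        perm_c = rng.permutation(8)
        m2 = gapparsimony.BinaryGapMatrix(
            taxa=[taxa[i] for i in perm_t],
            data=data[np.ix_(perm_t, perm_c)],
            provenance=[(0, int(j)) for j in perm_c],
        )
        assert gapparsimony.parsimony_score(
            m1, t
        ) == gapparsimony.parsimony_score(m2, t)


class TestSearch:
    def test_exhaustive_finds_the_tied_quartet_optima(self):
        res = gapparsimony.search_mp_tree(M4, mode="exhaustive")
        assert res.best_score == 3
        assert len(res.topologies) == 2
        assert res.metadata["examined"] == 3

    def test_uninformative_matrix_flagged(self):
        m = matrix("ABCD", [[1], [1], [1], [1]])
        res = gapparsimony.search_mp_tree(m, mode="heuristic", seed=0)
        assert res.uninformative
        assert res.best_score == 0

    def test_exhaustive_cap_enforced(self):
        data = np.zeros((10, 1), dtype=np.uint8)
        data[:5, 0] = 1
        m = matrix("ABCDEFGHIJ", data)
        with pytest.raises(gapparsimony.GapParsimonyError, match="capped at 9"):
            gapparsimony.search_mp_tree(m, mode="exhaustive")

    def test_heuristic_matches_exhaustive_on_six_taxa(self):
        rng = np.random.default_rng(12)
        for rep in range(5):
            m = matrix("ABCDEF", rng.integers(0, 2, size=(6, 12)))
            ex = gapparsimony.search_mp_tree(m, mode="exhaustive")
            he = gapparsimony.search_mp_tree(
                m, mode="heuristic", seed=rep, restarts=5
            )
            assert he.best_score >= ex.best_score  # never better than optimum
            assert he.best_score == ex.best_score

    def test_heuristic_seed_determinism(self):
        rng = np.random.default_rng(3)
        m = matrix("ABCDEFG", rng.integers(0, 2, size=(7, 10)))
        r1 = gapparsimony.search_mp_tree(m, seed=42, restarts=3)
        r2 = gapparsimony.search_mp_tree(m, seed=42, restarts=3)
        assert r1.best_score == r2.best_score
        n1 = [t.as_string(schema="newick") for t in r1.topologies]
        n2 = [t.as_string(schema="newick") for t in r2.topologies]
        assert n1 == n2


class TestConcatenate:
    def test_character_counts_add(self):
        m1 = matrix("ABCD", [[1, 0], [0, 0], [0, 1], [1, 1]])
        m2 = matrix("ABCD", [[1], [0], [1], [0]])
        cat = gapparsimony.concatenate([m1, m2])
        assert cat.n_characters == 3
        assert [g for g, _ in cat.provenance] == [0, 0, 1]

    def test_single_matrix_identity(self):
        cat = gapparsimony.concatenate([M4])
        np.testing.assert_array_equal(cat.data, M4.data)
        assert cat.taxa == M4.taxa

    def test_taxon_order_harmonised(self):
        m1 = matrix("ABCD", [[1], [0], [0], [1]])
        m2 = gapparsimony.BinaryGapMatrix(
            taxa=["D", "C", "B", "A"],
            data=np.array([[1], [0], [0], [1]], dtype=np.uint8),
            provenance=[(0, 0)],
        )
        cat = gapparsimony.concatenate([m1, m2])
        # m2 row for A is 1, for D is 1; after reordering to ABCD the second
        # character reads (1, 0, 0, 1)
        np.testing.assert_array_equal(cat.data[:, 1], [1, 0, 0, 1])

    def test_taxon_set_mismatch_rejected(self):
        m1 = matrix("ABCD", [[1], [0], [0], [1]])
        m2 = matrix("ABCE", [[1], [0], [0], [1]])
        with pytest.raises(gapparsimony.GapParsimonyError, match="taxon set"):
            gapparsimony.concatenate([m1, m2])

    def test_concatenation_recovers_generating_tree_better_than_single_gene(self):
        # characters drawn from the splits of a generating tree plus noise:
        # concatenating genes accumulates signal
        from gapguide import treemetrics

        gen = tree("((A,B),(C,D),(E,F));")
        rng = np.random.default_rng(8)
        taxa = list("ABCDEF")
        split_patterns = [
            [1, 1, 0, 0, 0, 0],
            [0, 0, 1, 1, 0, 0],
            [0, 0, 0, 0, 1, 1],
        ]
        def gene():
            cols = []
            for _ in range(4):
                if rng.random() < 0.6:
                    cols.append(list(split_patterns[rng.integers(3)]))
                else:
                    cols.append(list(rng.integers(0, 2, size=6)))
            return matrix(taxa, np.array(cols).T)

        genes = [gene() for _ in range(30)]
        cat = gapparsimony.concatenate(genes)
        cat_tree = gapparsimony.search_mp_tree(
            cat, mode="exhaustive"
        ).topologies
        d_cat = np.mean(
            [treemetrics.split_distance(t, gen) for t in cat_tree]
        )
        single = [
            np.mean(
                [
                    treemetrics.split_distance(t, gen)
                    for t in gapparsimony.search_mp_tree(
                        g, mode="exhaustive"
                    ).topologies
                ]
            )
            for g in genes[:10]
        ]
        assert d_cat <= np.median(single)
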