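"""Progressive aligner: pairwise oracle, guide-tree fidelity, NJ estimation."""

import itertools

import numpy as np
import pytest

from gapguide import aligner, seqsim
from gapguide._topo import from_dendropy, splits

from conftest import tree


# ---------------------------------------------------------------------------
# independent oracle: plain-Python affine-gap global alignment score


def gotoh_score(a: str, b: str, scheme: aligner.ScoringScheme) -> float:
    """Textbook O(n*m) affine-gap DP, scalar recurrences only."""
    idx = {c: i for i, c in enumerate(aligner.AMINO_ACIDS)}
    go, ge = scheme.gap_open, scheme.gap_extend
    neg = float("-inf")
    la, lb = len(a), len(b)
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = go + ge * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = go + ge * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = scheme.matrix[idx[a[i - 1]], idx[b[j - 1]]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge)
            Y[i][j] = max(M[i][j - 1] + go, Y[i][j - 1] + ge)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def alignment_score(row_a: str, row_b: str, scheme: aligner.ScoringScheme) -> float:
    """Score of a concrete pairwise alignment under the affine scheme."""
    idx = {c: i for i, c in enumerate(aligner.AMINO_ACIDS)}
    score = 0.0
    state = None
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            score += scheme.matrix[idx[x], idx[y]]
            state = None
        else:
            gap_state = "x" if y == "-" else "y"
            score += scheme.gap_extend if state == gap_state else scheme.gap_open
            state = gap_state
    return score


@pytest.fixture(scope="module")
def scheme():
    return aligner.default_scheme()


class TestPairwise:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("MKVLITAGPTRE", "MKVLITAGPTRE"),
            ("MKVLITAGPTRE", "MKVLITRE"),
            ("ACDEFGHIKLMNP", "ACDEFGIKLMNP"),
            ("WWWWAAAA", "AAAA"),
            ("MKTAYIAKQR", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIE"[:14]),
        ],
    )
    def test_optimal_score_matches_gotoh_oracle(self, a, b, scheme):
        row_a, row_b, score = aligner.pairwise_align(a, b, scheme)
        assert score == pytest.approx(gotoh_score(a, b, scheme))
        # the emitted alignment realises the optimal score
        assert alignment_score(row_a, row_b, scheme) == pytest.approx(score)
        assert row_a.replace("-", "") == a
        assert row_b.replace("-", "") == b

    def test_internal_deletion_gives_single_gap_block(self, scheme):
        import re

        a = "MKVLITAGPTREWQ"
        b = a[:5] + a[8:]  # 3-residue internal deletion
        row_a, row_b, _ = aligner.pairwise_align(a, b, scheme)
        assert row_a == a
        assert re.findall(r"-+", row_b) == ["---"]


class TestEstimateGuideTree:
    def test_two_identical_pairs_form_cherries(self):
        s1 = "MKVLITAGPTREWQNDAAKL"
        s3 = "WWCCHHPPGGYYFFDDEEKK"
        seqs = {"a": s1, "b": s1, "c": s3, "d": s3}
        t = aligner.estimate_guide_tree(seqs)
        assert splits(from_dendropy(t)) == splits(
            from_dendropy(tree("((a,b),(c,d));"))
        )

    def test_three_sequences_single_topology(self):
        t = aligner.estimate_guide_tree(
            {"a": "MKVLITAGPT", "b": "MKVLITAGPA", "c": "MKVLITAGWW"}
        )
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["a", "b", "c"]

    def test_too_few_sequences_rejected(self):
        with pytest.raises(aligner.AlignerError, match=">= 3"):
            aligner.estimate_guide_tree({"a": "MKVL", "b": "MKVL"})

    def test_nj_recovers_additive_six_leaf_tree(self):
        # distances generated from a known tree are perfectly additive,
        # so neighbour joining must recover its topology
        ref = tree("((a:1,b:2):1,(c:3,(d:1,e:2):2):1,f:4);")
        pdm = ref.phylogenetic_distance_matrix()
        taxa = sorted(ref.taxon_namespace, key=lambda t: t.label)
        ids = [t.label for t in taxa]
        n = len(ids)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        out = aligner.nj_tree(dm, ids)
        assert splits(from_dendropy(out)) == splits(from_dendropy(ref))


class TestProgressive:
    def test_identical_sequences_align_gap_free(self):
        s = "MKVLITAGPTREWQ"
        aln, _ = aligner.progressive_align({"a": s, "b": s, "c": s, "d": s})
        assert aln.n_columns == len(s)
        assert all(row == s for _, row in aln)

    def test_strip_gaps_round_trip(self):
        rec = seqsim.simulate_set(
            seqsim.SimulationConfig(n_taxa=8, root_length=120), 0, 42
        )
        aln, _ = aligner.progressive_align(rec.leaf_sequences)
        assert aln.strip_gaps() == rec.leaf_sequences
        assert aln.n_columns >= max(len(s) for s in rec.leaf_sequences.values())

    def test_merge_log_follows_guide_tree_postorder(self):
        seqs = {
            "a": "MKVLITAGPTRE",
            "b": "MKVLITAGPTRE",
            "c": "MKVLWWAGPTRE",
            "d": "MKVLWWAGPTRE",
        }
        t1 = tree("((a,b),(c,d));")
        t2 = tree("((a,c),(b,d));")
        _, log1 = aligner.progressive_align(seqs, t1)
        _, log2 = aligner.progressive_align(seqs, t2)
        pairs1 = [(set(s.left), set(s.right)) for s in log1]
        pairs2 = [(set(s.left), set(s.right)) for s in log2]
        assert pairs1 == [
            ({"a"}, {"b"}),
            ({"c"}, {"d"}),
            ({"a", "b"}, {"c", "d"}),
        ]
        assert pairs2 == [
            ({"a"}, {"c"}),
            ({"b"}, {"d"}),
            ({"a", "c"}, {"b", "d"}),
        ]

    def test_leaf_identifier_mismatch_rejected(self):
        seqs = {"a": "MKVL", "b": "MKVL", "x": "MKVL"}
        with pytest.raises(aligner.AlignerError, match="sequence-only.*'x'"):
            aligner.progressive_align(seqs, tree("((a,b),c);"))

    def test_unrooted_guide_tree_accepted(self):
        seqs = {
            "a": "MKVLITAGPTRE",
            "b": "MKVLITAGPTRE",
            "c": "MKVLWWAGPTRE",
            "d": "MKVLWWAGPTRE",
        }
        unrooted = tree("(a,b,(c,d));")
        aln, log = aligner.progressive_align(seqs, unrooted)
        assert len(aln) == 4
        assert len(log) == 3


class TestScoringScheme:
    def test_rejects_positive_gap_penalties(self):
        with pytest.raises(aligner.AlignerError):
            aligner.ScoringScheme(gap_open=1.0)

    def test_rejects_open_weaker_than_extend(self):
        with pytest.raises(aligner.AlignerError):
            aligner.ScoringScheme(gap_open=-1.0, gap_extend=-5.0)
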