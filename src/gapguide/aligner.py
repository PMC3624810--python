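"""Minimal guide-tree-driven progressive multiple aligner.

A deliberately simple progressive aligner whose one load-bearing property
is *guide-tree fidelity*: when a guide-tree is supplied it is used verbatim,
and the merge log proves that profiles were merged exactly in the tree's
post-order.  That makes it possible to align the same sequences under a
correct, a self-estimated, or a deliberately wrong guide-tree and attribute
any difference in the resulting gap patterns to the tree alone.

Profiles are aligned with affine-gap (Gotoh) dynamic programming; the
substitution term between two profile columns is the mean sum-of-pairs
score over residue pairs.  Tie-breaking in the traceback is fixed as
diagonal > up > left, so results are deterministic.  When no guide-tree is
given, one is estimated by neighbour joining on pairwise distances
(1 - fractional identity from pairwise global alignments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alignment import Alignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NEG = -1e30
_TIE_TOL = 1e-9


class AlignerError(ValueError):
    pass


def _blosum62() -> np.ndarray:
    raw = substitution_matrices.load("BLOSUM62")
    m = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = raw[a][b]
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix over the 20 amino acids plus affine gap costs."""

    matrix: np.ndarray = field(default_factory=_blosum62)
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (20, 20):
            raise AlignerError("substitution matrix must be 20x20")
        if not np.allclose(m, m.T):
            raise AlignerError("substitution matrix must be symmetric")
        if not self.gap_open <= self.gap_extend <= 0:
            raise AlignerError("need gap_open <= gap_extend <= 0")
        object.__setattr__(self, "matrix", m)


def default_scheme() -> ScoringScheme:
    return ScoringScheme()


@dataclass
class MergeStep:
    step: int
    left: List[str]
    right: List[str]


# ---------------------------------------------------------------------------
# profile machinery


def _profile_counts(rows: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    ncol = len(rows[0])
    counts = np.zeros((ncol, 20))
    for row in rows:
        for j, c in enumerate(row):
            if c == "-":
                continue
            k = _AA_INDEX.get(c)
            if k is None:
                raise AlignerError(f"unknown residue {c!r} (alphabet {AMINO_ACIDS})")
            counts[j, k] += 1
    nongap = counts.sum(axis=1)
    return counts, nongap


def _align_counts(
    counts_a: np.ndarray,
    nongap_a: np.ndarray,
    counts_b: np.ndarray,
    nongap_b: np.ndarray,
    scheme: ScoringScheme,
) -> Tuple[List[Tuple[Optional[int], Optional[int]]], float]:
    """Affine-gap global alignment of two column-profiles.

    Returns the column path (index into A or None, index into B or None)
    and the alignment score.  States: M (match), X (gap in B, consume A,
    "up"), Y (gap in A, consume B, "left")."""
    la, lb = counts_a.shape[0], counts_b.shape[0]
    go, ge = scheme.gap_open, scheme.gap_extend
    sub = (counts_a @ scheme.matrix) @ counts_b.T
    sub /= np.outer(nongap_a, nongap_b)

    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)
    Y = np.full((la + 1, lb + 1), _NEG)
    M[0, 0] = 0.0
    if lb:
        Y[0, 1:] = go + ge * np.arange(lb)
    jj = np.arange(lb)
    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1, :lb], X[i - 1, :lb]), Y[i - 1, :lb])
        M[i, 1:] = sub[i - 1] + prev_best
        X[i] = np.maximum(M[i - 1] + go, X[i - 1] + ge)
        if lb:
            t = np.maximum.accumulate(M[i, :lb] - ge * jj)
            Y[i, 1:] = go + ge * jj + t

    i, j = la, lb
    end = (M[i, j], X[i, j], Y[i, j])
    best = max(end)
    state = "M" if end[0] >= best - _TIE_TOL else ("X" if end[1] >= best - _TIE_TOL else "Y")
    path: List[Tuple[Optional[int], Optional[int]]] = []
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            here = (M[i, j], X[i, j], Y[i, j])
            b = max(here)
            state = "M" if here[0] >= b - _TIE_TOL else ("X" if here[1] >= b - _TIE_TOL else "Y")
        elif state == "X":
            path.append((i - 1, None))
            state = "M" if M[i - 1, j] + go >= X[i, j] - _TIE_TOL else "X"
            i -= 1
        else:
            path.append((None, j - 1))
            state = "M" if M[i, j - 1] + go >= Y[i, j] - _TIE_TOL else "Y"
            j -= 1
    path.reverse()
    return path, float(best)


def _merge_rows(
    rows_a: List[str],
    rows_b: List[str],
    path: Sequence[Tuple[Optional[int], Optional[int]]],
) -> Tuple[List[str], List[str]]:
    out_a = ["".join(r[ai] if ai is not None else "-" for ai, _ in path) for r in rows_a]
    out_b = ["".join(r[bj] if bj is not None else "-" for _, bj in path) for r in rows_b]
    return out_a, out_b


# ---------------------------------------------------------------------------
# pairwise layer


def pairwise_align(
    seq_a: str, seq_b: str, scheme: Optional[ScoringScheme] = None
) -> Tuple[str, str, float]:
    """Global affine-gap alignment of two ungapped sequences."""
    scheme = scheme or default_scheme()
    ca, na = _profile_counts([seq_a])
    cb, nb = _profile_counts([seq_b])
    path, score = _align_counts(ca, na, cb, nb, scheme)
    (row_a,), (row_b,) = _merge_rows([seq_a], [seq_b], path)
    return row_a, row_b, score


def pairwise_distance(
    seq_a: str, seq_b: str, scheme: Optional[ScoringScheme] = None
) -> float:
    """1 - fractional identity over aligned residue pairs."""
    row_a, row_b, _ = pairwise_align(seq_a, seq_b, scheme)
    pairs = matches = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            pairs += 1
            if x == y:
                matches += 1
    if pairs == 0:
        return 1.0
    return 1.0 - matches / pairs


def nj_tree(distances: np.ndarray, ids: Sequence[str]) -> dendropy.Tree:
    """Neighbour-joining tree from a symmetric distance matrix; negative
    estimated branch lengths are clamped to zero."""
    tree = _skbio_nj(DistanceMatrix(np.asarray(distances, dtype=float), list(ids)))
    out = dendropy.Tree.get(
        data=str(tree), schema="newick", preserve_underscores=True
    )
    for edge in out.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return out


def estimate_guide_tree(
    sequences: Dict[str, str], scheme: Optional[ScoringScheme] = None
) -> dendropy.Tree:
    """Neighbour-joining guide-tree on pairwise alignment distances."""
    ids = list(sequences)
    if len(ids) < 3:
        raise AlignerError("guide-tree estimation needs >= 3 sequences")
    if len(set(ids)) != len(ids):
        raise AlignerError("duplicate identifiers")
    scheme = scheme or default_scheme()
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(sequences[ids[i]], sequences[ids[j]], scheme)
            dm[i, j] = dm[j, i] = d
    return nj_tree(dm, ids)


# ---------------------------------------------------------------------------
# progressive layer


def _rooted_copy(tree: dendropy.Tree) -> dendropy.Tree:
    """Working copy of a guide-tree, midpoint-rooted if it is unrooted.

    The midpoint edge is found by hand (longest leaf-to-leaf path, ties
    broken by sorted labels) and the tree rerooted at that edge, so no leaf
    is ever absorbed into the root and rooting stays deterministic."""
    work = tree.clone(depth=1)
    for edge in work.preorder_edge_iter():
        if edge.length is None:
            edge.length = 1.0
    if len(work.seed_node.child_nodes()) > 2:
        _midpoint_root(work)
    return work


def _midpoint_root(work: dendropy.Tree) -> None:
    leaves = sorted(
        work.leaf_node_iter(), key=lambda n: n.taxon.label
    )
    parent: Dict[int, object] = {}
    for node in work.preorder_node_iter():
        parent[id(node)] = node.parent_node

    def path_edges(na, nb):
        anc_a = []
        n = na
        while n is not None:
            anc_a.append(n)
            n = parent[id(n)]
        in_a = {id(x) for x in anc_a}
        n = nb
        while id(n) not in in_a:
            n = parent[id(n)]
        mrca = n
        up = []
        n = na
        while n is not mrca:
            up.append(n.edge)
            n = parent[id(n)]
        down = []
        n = nb
        while n is not mrca:
            down.append(n.edge)
            n = parent[id(n)]
        return up + list(reversed(down))

    best = None
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            edges_ab = path_edges(a, b)
            d = sum(e.length or 0.0 for e in edges_ab)
            if best is None or d > best[0]:
                best = (d, edges_ab)
    if best is None or best[0] <= 0:
        return  # star-like or zero-length tree: merge the polytomy as given
    dmax, edges_ab = best
    half = dmax / 2.0
    acc = 0.0
    for e in edges_ab:
        length = e.length or 0.0
        if length > 0 and acc + length >= half:
            work.reroot_at_edge(e, update_bipartitions=False)
            return
        acc += length


def progressive_align(
    sequences: Dict[str, str],
    guide_tree: Optional[dendropy.Tree] = None,
    scheme: Optional[ScoringScheme] = None,
) -> Tuple[Alignment, List[MergeStep]]:
    """Align ``sequences`` progressively, merging profiles in the post-order
    of ``guide_tree`` (estimated by neighbour joining when absent).

    Returns the alignment and the merge log; the log records, per profile
    merge, the identifiers on each side, in execution order."""
    scheme = scheme or default_scheme()
    ids = list(sequences)
    if len(ids) < 2:
        raise AlignerError("need >= 2 sequences")
    if guide_tree is None:
        if len(ids) == 2:
            a, b = ids
            ra, rb, _ = pairwise_align(sequences[a], sequences[b], scheme)
            return Alignment([(a, ra), (b, rb)]), [MergeStep(0, [a], [b])]
        guide_tree = estimate_guide_tree(sequences, scheme)
    tree_leaves = {
        lf.taxon.label for lf in guide_tree.leaf_node_iter()
    }
    if tree_leaves != set(ids):
        raise AlignerError(
            "guide-tree leaves and sequence identifiers differ: "
            f"tree-only {sorted(tree_leaves - set(ids))}, "
            f"sequence-only {sorted(set(ids) - tree_leaves)}"
        )
    work = _rooted_copy(guide_tree)
    log: List[MergeStep] = []
    profiles: Dict[int, Tuple[List[str], List[str]]] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            profiles[id(node)] = ([lbl], [sequences[lbl]])
            continue
        kids = node.child_nodes()
        acc_ids, acc_rows = profiles.pop(id(kids[0]))
        for kid in kids[1:]:
            kid_ids, kid_rows = profiles.pop(id(kid))
            ca, na = _profile_counts(acc_rows)
            cb, nb = _profile_counts(kid_rows)
            path, _ = _align_counts(ca, na, cb, nb, scheme)
            out_a, out_b = _merge_rows(acc_rows, kid_rows, path)
            log.append(MergeStep(len(log), list(acc_ids), list(kid_ids)))
            acc_ids = acc_ids + kid_ids
            acc_rows = out_a + out_b
        profiles[id(node)] = (acc_ids, acc_rows)
    final_ids, final_rows = profiles[id(work.seed_node)]
    aln = Alignment(list(zip(final_ids, final_rows)))
    return aln, log


def write_merge_log(log: Sequence[MergeStep], path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tleft\tright\n")
        for s in log:
            fh.write(f"{s.step}\t{','.join(s.left)}\t{','.join(s.right)}\n")
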