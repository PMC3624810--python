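"""Maximum-parsimony trees from binary gap presence/absence characters.

Every alignment column containing at least one gap becomes a two-state
character (1 = gap in that taxon, 0 = residue).  For binary characters
Wagner and Fitch parsimony coincide; scoring is implemented as unit-cost
small parsimony (a Sankoff down-pass, exact for polytomies too) vectorised
over all characters with numpy.

Tree search is either exhaustive enumeration of all resolved unrooted
topologies (capped at 9 taxa, 135135 trees) or a heuristic: a neighbour-
joining start tree on Hamming distances plus seeded random start trees,
each hill-climbed through its full SPR neighbourhood until no move
improves the score.  All equally best topologies encountered are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from . import _topo
from .alignment import GAP, Alignment

EXHAUSTIVE_CAP = 9
_INF = np.int32(10**6)


class GapParsimonyError(ValueError):
    pass


@dataclass
class BinaryGapMatrix:
    """taxa x characters presence/absence matrix with per-character
    provenance ``(gene index, source alignment column)``."""

    taxa: List[str]
    data: np.ndarray  # (n_taxa, n_chars) uint8
    provenance: List[Tuple[int, int]]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise GapParsimonyError("matrix shape does not match taxa")
        if self.data.shape[1] != len(self.provenance):
            raise GapParsimonyError("provenance length does not match characters")
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise GapParsimonyError("matrix entries must be 0/1")

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]

    @property
    def n_variable(self) -> int:
        """Characters with both states present."""
        if self.n_characters == 0:
            return 0
        col_sums = self.data.sum(axis=0)
        return int(((col_sums > 0) & (col_sums < len(self.taxa))).sum())

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)} {self.n_characters}\n")
            for i, t in enumerate(self.taxa):
                fh.write(f"{t}  {''.join(map(str, self.data[i]))}\n")


@dataclass
class ParsimonyResult:
    best_score: int
    topologies: List[dendropy.Tree]
    uninformative: bool = False
    metadata: dict = field(default_factory=dict)


def recode_gap_patterns(aln: Alignment, gene: int = 0) -> BinaryGapMatrix:
    """One binary character per alignment column containing >= 1 gap."""
    taxa = aln.ids
    cols = []
    prov = []
    for j in range(aln.n_columns):
        col = aln.column(j)
        if GAP in col:
            cols.append([1 if c == GAP else 0 for c in col])
            prov.append((gene, j))
    data = (
        np.array(cols, dtype=np.uint8).T
        if cols
        else np.zeros((len(taxa), 0), dtype=np.uint8)
    )
    return BinaryGapMatrix(taxa=taxa, data=data, provenance=prov)


def concatenate(matrices: Sequence[BinaryGapMatrix]) -> BinaryGapMatrix:
    """Append characters of several gene matrices over identical taxon sets;
    provenance keeps each character's source gene index."""
    if not matrices:
        raise GapParsimonyError("nothing to concatenate")
    first = matrices[0]
    prov: List[Tuple[int, int]] = []
    blocks = []
    for g, m in enumerate(matrices):
        if set(m.taxa) != set(first.taxa):
            raise GapParsimonyError(
                f"taxon set of matrix {g} differs from the first"
            )
        order = [m.taxa.index(t) for t in first.taxa]
        blocks.append(m.data[order])
        prov.extend((g, col) for _, col in m.provenance)
    return BinaryGapMatrix(
        taxa=list(first.taxa),
        data=np.hstack(blocks),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# scoring


def _score_adj(adj: _topo.Adj, states: Dict[str, np.ndarray]) -> int:
    """Unit-cost small parsimony summed over characters (Sankoff down-pass)."""
    order, children = _topo.postorder(adj)
    nchar = next(iter(states.values())).shape[0] if states else 0
    cost: Dict[object, Tuple[np.ndarray, np.ndarray]] = {}
    for node in order:
        kids = children[node]
        if not kids:
            s = states[node]
            c0 = np.where(s == 0, np.int32(0), _INF)
            c1 = np.where(s == 1, np.int32(0), _INF)
        else:
            c0 = np.zeros(nchar, dtype=np.int32)
            c1 = np.zeros(nchar, dtype=np.int32)
            for k in kids:
                k0, k1 = cost.pop(k)
                c0 += np.minimum(k0, k1 + 1)
                c1 += np.minimum(k1, k0 + 1)
        cost[node] = (c0, c1)
    root0, root1 = cost[order[-1]]
    return int(np.minimum(root0, root1).sum())


def parsimony_score(matrix: BinaryGapMatrix, topology: dendropy.Tree) -> int:
    """Minimum number of 0<->1 changes of all characters on ``topology``."""
    adj = _topo.from_dendropy(topology)
    leaves = _topo.leaves(adj)
    missing = sorted(set(leaves) - set(matrix.taxa))
    if missing:
        raise GapParsimonyError(f"leaves without character rows: {missing}")
    states = {
        t: matrix.data[matrix.taxa.index(t)].astype(np.int8) for t in leaves
    }
    return _score_adj(adj, states)


# ---------------------------------------------------------------------------
# search


def _nj_start(matrix: BinaryGapMatrix) -> _topo.Adj:
    """Neighbour-joining start topology on normalised Hamming distances."""
    n = len(matrix.taxa)
    if matrix.n_characters == 0:
        return _topo.caterpillar(sorted(matrix.taxa))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            h = np.mean(matrix.data[i] != matrix.data[j])
            d[i, j] = d[j, i] = h
    tree = _skbio_nj(DistanceMatrix(d, matrix.taxa))
    dtree = dendropy.Tree.get(
        data=str(tree), schema="newick", preserve_underscores=True
    )
    return _topo.from_dendropy(dtree)


def _hill_climb(
    adj: _topo.Adj, states: Dict[str, np.ndarray]
) -> Tuple[_topo.Adj, int, int]:
    """Steepest-descent SPR hill climbing; returns (tree, score, moves)."""
    score = _score_adj(adj, states)
    moves = 0
    improved = True
    while improved:
        improved = False
        best_adj, best_score = None, score
        for cand in _topo.spr_neighbors(adj):
            s = _score_adj(cand, states)
            moves += 1
            if s < best_score:
                best_adj, best_score = cand, s
        if best_adj is not None:
            adj, score = best_adj, best_score
            improved = True
    return adj, score, moves


def search_mp_tree(
    matrix: BinaryGapMatrix,
    mode: str = "heuristic",
    seed: int = 0,
    restarts: int = 10,
) -> ParsimonyResult:
    """Most-parsimonious unrooted topologies for a binary gap matrix.

    ``mode="exhaustive"`` enumerates every resolved topology (<= 9 taxa)
    and returns the complete optimum set; ``mode="heuristic"`` SPR-climbs
    from a neighbour-joining start plus ``restarts`` seeded random starts
    and returns all distinct best topologies encountered."""
    taxa = sorted(matrix.taxa)
    if len(taxa) < 4:
        raise GapParsimonyError("tree search needs >= 4 taxa")
    states = {
        t: matrix.data[matrix.taxa.index(t)].astype(np.int8) for t in taxa
    }
    if matrix.n_variable == 0:
        start = _topo.caterpillar(taxa)
        return ParsimonyResult(
            best_score=0,
            topologies=[_topo.to_dendropy(start)],
            uninformative=True,
            metadata={"mode": mode, "note": "no variable characters"},
        )

    if mode == "exhaustive":
        if len(taxa) > EXHAUSTIVE_CAP:
            raise GapParsimonyError(
                f"exhaustive search is capped at {EXHAUSTIVE_CAP} taxa "
                f"(got {len(taxa)})"
            )
        best_score: Optional[int] = None
        best: List[_topo.Adj] = []
        examined = 0
        for adj in _topo.enumerate_topologies(taxa):
            s = _score_adj(adj, states)
            examined += 1
            if best_score is None or s < best_score:
                best_score, best = s, [adj]
            elif s == best_score:
                best.append(adj)
        return ParsimonyResult(
            best_score=int(best_score),
            topologies=[_topo.to_dendropy(a) for a in best],
            metadata={"mode": "exhaustive", "examined": examined},
        )

    if mode != "heuristic":
        raise GapParsimonyError(f"unknown search mode: {mode!r}")
    rng = np.random.default_rng(seed)
    starts = [_nj_start(matrix)] + [
        _topo.random_topology(taxa, rng) for _ in range(restarts)
    ]
    best_score = None
    best_splits: Dict[_topo.SplitSet, _topo.Adj] = {}
    total_moves = 0
    for start in starts:
        adj, s, moves = _hill_climb(start, states)
        total_moves += moves
        if best_score is None or s < best_score:
            best_score = s
            best_splits = {_topo.splits(adj): adj}
        elif s == best_score:
            best_splits.setdefault(_topo.splits(adj), adj)
    return ParsimonyResult(
        best_score=int(best_score),
        topologies=[
            _topo.to_dendropy(best_splits[k])
            for k in sorted(best_splits, key=lambda s: sorted(map(sorted, s)))
        ],
        metadata={
            "mode": "heuristic",
            "starts": len(starts),
            "moves": total_moves,
            "seed": seed,
        },
    )
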