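"""The guidescore: a 2D measure of guide-tree dependency.

Fix a *canonical* tree (the true or accepted species tree) and a *wrong*
tree at maximal split distance to it.  Any tree on the same leaves can then
be projected to a point ``(x, y)`` where ``x`` is its normalized split
distance to the canonical tree and ``y`` its distance to the wrong tree; a
set of trees is projected to the arithmetic mean of its members' points.

The *guidescore* between two such points — typically the trees inferred
from alignments built under the canonical guide-tree versus under the
wrong guide-tree — is their Euclidean distance.  It is 0 when altering the
guide-tree changes nothing and at most sqrt(2); large values mean the
inferred trees chase whatever guide-tree the aligner was given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from . import _topo, aligner, gapparsimony, treemetrics
from .alignment import Alignment


class GuideScoreError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceFrame:
    """The (canonical, wrong) tree pair that defines the 2D space."""

    canonical: dendropy.Tree
    wrong: dendropy.Tree

    def signature(self) -> Tuple[frozenset, frozenset]:
        return (
            _topo.splits(_topo.from_dendropy(self.canonical)),
            _topo.splits(_topo.from_dendropy(self.wrong)),
        )


@dataclass
class GuidePoint:
    x: float  # mean split distance to the canonical tree
    y: float  # mean split distance to the wrong tree
    frame: ReferenceFrame
    per_tree: List[Tuple[float, float]] = field(default_factory=list)


def project(
    trees: Sequence[dendropy.Tree], frame: ReferenceFrame
) -> GuidePoint:
    """Mean (distance-to-canonical, distance-to-wrong) point of a tree set."""
    if not trees:
        raise GuideScoreError("cannot project an empty tree set")
    coords = [
        (
            treemetrics.split_distance(t, frame.canonical),
            treemetrics.split_distance(t, frame.wrong),
        )
        for t in trees
    ]
    xs, ys = zip(*coords)
    return GuidePoint(
        x=float(np.mean(xs)),
        y=float(np.mean(ys)),
        frame=frame,
        per_tree=list(coords),
    )


def guidescore(point_a: GuidePoint, point_b: GuidePoint) -> float:
    """Euclidean distance between two projected points (same frame)."""
    if point_a.frame.signature() != point_b.frame.signature():
        raise GuideScoreError(
            "points were projected against different canonical/wrong pairs"
        )
    return math.hypot(point_a.x - point_b.x, point_a.y - point_b.y)


TreeBuilder = Callable[[Alignment], List[dendropy.Tree]]


def gap_parsimony_builder(
    seed: int = 0, restarts: int = 3, mode: str = "heuristic"
) -> TreeBuilder:
    """Tree builder inferring MP trees from the alignment's gap patterns."""

    def build(aln: Alignment) -> List[dendropy.Tree]:
        matrix = gapparsimony.recode_gap_patterns(aln)
        result = gapparsimony.search_mp_tree(
            matrix, mode=mode, seed=seed, restarts=restarts
        )
        return result.topologies

    return build


def guidescore_experiment(
    gene_sets: Sequence[Dict[str, str]],
    canonical: dendropy.Tree,
    wrong: Optional[dendropy.Tree] = None,
    tree_builder: Optional[TreeBuilder] = None,
    seed: int = 0,
    scheme: Optional[aligner.ScoringScheme] = None,
) -> Tuple[pd.DataFrame, float]:
    """Full guide-tree-dependency experiment on unaligned gene sets.

    Each gene set (shared taxa) is aligned twice — once under the canonical
    guide-tree, once under the wrong one — the chosen builder infers trees
    from each alignment (gap parsimony by default; pass a callable reading
    externally produced Newick trees to compare e.g. ML reconstructions),
    both tree sets are projected, and the per-gene guidescore reported.

    Returns the per-gene table (gene, condition, x, y, score) and the
    aggregate guidescore between the mean canonical-condition and
    wrong-condition points.  Genes failing either alignment or tree step
    are reported with NaN coordinates and skipped in the aggregate."""
    if not gene_sets:
        raise GuideScoreError("no gene sets supplied")
    if wrong is None:
        wrong = treemetrics.make_wrong_tree(canonical, seed=seed)
    frame = ReferenceFrame(canonical=canonical, wrong=wrong)
    if tree_builder is None:
        tree_builder = gap_parsimony_builder(seed=seed)
    rows = []
    points: Dict[str, List[Tuple[float, float]]] = {"canonical": [], "wrong": []}
    for g, seqs in enumerate(gene_sets):
        try:
            per_condition = {}
            for condition, guide in (("canonical", canonical), ("wrong", wrong)):
                aln, _ = aligner.progressive_align(seqs, guide, scheme)
                trees = tree_builder(aln)
                per_condition[condition] = project(trees, frame)
            score = guidescore(
                per_condition["canonical"], per_condition["wrong"]
            )
            for condition, pt in per_condition.items():
                points[condition].append((pt.x, pt.y))
                rows.append(
                    {
                        "gene": g,
                        "condition": condition,
                        "x": pt.x,
                        "y": pt.y,
                        "n_trees": len(pt.per_tree),
                        "guidescore": score,
                    }
                )
        except (ValueError, RuntimeError) as exc:
            rows.append(
                {
                    "gene": g,
                    "condition": "error",
                    "x": float("nan"),
                    "y": float("nan"),
                    "n_trees": 0,
                    "guidescore": float("nan"),
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    if points["canonical"] and points["wrong"]:
        mean_c = np.mean(points["canonical"], axis=0)
        mean_w = np.mean(points["wrong"], axis=0)
        aggregate = float(math.hypot(*(mean_c - mean_w)))
    else:
        aggregate = float("nan")
    return table, aggregate
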