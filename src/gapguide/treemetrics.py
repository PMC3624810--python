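"""Topological tree comparison and deliberately wrong guide-trees.

The distance used throughout the package is the normalized split distance
(Robinson–Foulds on nontrivial bipartitions): the size of the symmetric
difference of the two trees' split sets divided by the total number of
splits, ``|S1 Δ S2| / (|S1| + |S2|)``.  It is 0 for topologically identical
trees, 1 when the trees share no nontrivial split, ignores branch lengths
and rooting, and degrades gracefully on partially resolved trees.

A *wrong tree* is a resolved topology on the same leaves at split distance
exactly 1 from a canonical tree — the maximally perturbed guide-tree used
to probe how strongly an aligner's gap placement follows its guide.
"""

from __future__ import annotations

from typing import Optional

import dendropy
import numpy as np

from . import _topo


class TreeMetricError(ValueError):
    """Raised on incompatible trees or unreachable construction targets."""


def _check_same_leaves(t1: _topo.Adj, t2: _topo.Adj) -> None:
    l1, l2 = set(_topo.leaves(t1)), set(_topo.leaves(t2))
    if l1 != l2:
        raise TreeMetricError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )


def split_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Normalized split distance between two trees on the same leaf set."""
    a1, a2 = _topo.from_dendropy(t1), _topo.from_dendropy(t2)
    _check_same_leaves(a1, a2)
    return _split_distance_adj(a1, a2)


def _split_distance_adj(a1: _topo.Adj, a2: _topo.Adj) -> float:
    s1, s2 = _topo.splits(a1), _topo.splits(a2)
    total = len(s1) + len(s2)
    if total == 0:
        return 0.0
    return len(s1 ^ s2) / total


def make_wrong_tree(
    canonical: dendropy.Tree,
    seed: int,
    max_tries: int = 5000,
) -> dendropy.Tree:
    """A resolved tree on the same leaves sharing no nontrivial split with
    ``canonical`` (split distance exactly 1).

    Seeded rejection sampling: random-permutation caterpillars first (they
    rarely share splits with any fixed tree), then uniformly grown random
    topologies.  Many maximally wrong trees exist; the seed picks one
    reproducibly.
    """
    canon = _topo.from_dendropy(canonical)
    names = _topo.leaves(canon)
    if len(names) < 4:
        raise TreeMetricError("need >= 4 leaves for a nontrivially wrong tree")
    canon_splits = _topo.splits(canon)
    rng = np.random.default_rng(seed)
    best: Optional[_topo.Adj] = None
    best_d = -1.0
    for attempt in range(max_tries):
        if attempt < max_tries // 2:
            perm = [names[i] for i in rng.permutation(len(names))]
            cand = _topo.caterpillar(perm)
        else:
            cand = _topo.random_topology(names, rng)
        shared = _topo.splits(cand) & canon_splits
        if not shared:
            return _topo.to_dendropy(cand)
        d = _split_distance_adj(cand, canon)
        if d > best_d:
            best_d, best = d, cand
    raise TreeMetricError(
        f"no 100%-distant tree found in {max_tries} tries; "
        f"best distance reached: {best_d:.3f}"
    )


def make_tree_at_distance(
    canonical: dendropy.Tree,
    target: float,
    tolerance: float,
    seed: int,
    max_steps: int = 20000,
) -> dendropy.Tree:
    """A tree at normalized split distance ``target`` (± ``tolerance``) from
    ``canonical``, found by a seeded random walk of NNI rearrangements that
    accepts moves shrinking ``|distance - target|`` (sideways moves are
    accepted stochastically to escape plateaus)."""
    if not 0.0 <= target <= 1.0:
        raise TreeMetricError(f"target distance {target} outside [0, 1]")
    if tolerance < 0:
        raise TreeMetricError("tolerance must be >= 0")
    canon = _topo.from_dendropy(canonical)
    if target == 0.0:
        return _topo.to_dendropy(canon)
    if len(_topo.leaves(canon)) < 4:
        raise TreeMetricError("need >= 4 leaves")
    rng = np.random.default_rng(seed)
    current = _topo.copy_adj(canon)
    d = 0.0
    best, best_d = current, d
    for _ in range(max_steps):
        if abs(d - target) <= tolerance:
            return _topo.to_dendropy(current)
        cand = _topo.random_nni(current, rng)
        d_new = _split_distance_adj(cand, canon)
        gap_new, gap_old = abs(d_new - target), abs(d - target)
        if gap_new < gap_old or (gap_new == gap_old and rng.random() < 0.3):
            current, d = cand, d_new
            if abs(d - target) < abs(best_d - target):
                best, best_d = current, d
    if abs(best_d - target) <= tolerance:
        return _topo.to_dendropy(best)
    raise TreeMetricError(
        f"target {target} ± {tolerance} unreachable in {max_steps} NNI steps; "
        f"closest achieved: {best_d:.3f}"
    )
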