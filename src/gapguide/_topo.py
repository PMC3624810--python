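"""Internal unrooted-topology toolkit.

Trees here are plain adjacency dicts ``{node: [neighbours]}``.  Leaves are
taxon-name strings, internal nodes are ints.  Public modules convert to and
from :mod:`dendropy` trees at their boundaries; this module keeps topology
surgery (NNI, SPR, enumeration, random sampling) simple and deterministic.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterator, List, Sequence, Tuple

import dendropy
import numpy as np

Adj = Dict[object, List[object]]
Split = FrozenSet[str]
SplitSet = FrozenSet[Split]


def _key(node: object) -> Tuple[int, str]:
    # stable ordering across mixed str/int node ids
    return (0, node) if isinstance(node, str) else (1, f"{node:012d}")


def copy_adj(adj: Adj) -> Adj:
    return {k: list(v) for k, v in adj.items()}


def leaves(adj: Adj) -> List[str]:
    return sorted(n for n in adj if isinstance(n, str))


def edges(adj: Adj) -> List[Tuple[object, object]]:
    """Undirected edges, deterministically ordered."""
    out = []
    for u in sorted(adj, key=_key):
        for v in adj[u]:
            if _key(u) < _key(v):
                out.append((u, v))
    return out


def _fresh_id(adj: Adj) -> int:
    ints = [n for n in adj if isinstance(n, int)]
    return (max(ints) + 1) if ints else 0


# ---------------------------------------------------------------------------
# construction


def caterpillar(order: Sequence[str]) -> Adj:
    """Caterpillar (ladder) topology over leaves in the given order."""
    names = list(order)
    n = len(names)
    if n < 3:
        raise ValueError("need >= 3 leaves")
    adj: Adj = {0: [names[0], names[1]], names[0]: [0], names[1]: [0]}
    prev = 0
    for k in range(2, n - 1):
        node = k - 1
        adj[node] = [prev, names[k]]
        adj[prev].append(node)
        adj[names[k]] = [node]
        prev = node
    adj[prev].append(names[n - 1])
    adj[names[n - 1]] = [prev]
    return adj


def random_topology(names: Sequence[str], rng: np.random.Generator) -> Adj:
    """Uniform-ish random resolved topology by sequential random addition."""
    names = list(names)
    if len(names) < 3:
        raise ValueError("need >= 3 leaves")
    adj: Adj = {0: names[:3]}
    for nm in names[:3]:
        adj[nm] = [0]
    for nm in names[3:]:
        es = edges(adj)
        u, v = es[rng.integers(len(es))]
        w = _fresh_id(adj)
        adj[u][adj[u].index(v)] = w
        adj[v][adj[v].index(u)] = w
        adj[w] = [u, v, nm]
        adj[nm] = [w]
    return adj


def enumerate_topologies(names: Sequence[str]) -> Iterator[Adj]:
    """All (2n-5)!! resolved unrooted topologies on the given leaves."""
    names = sorted(names)
    if len(names) < 3:
        raise ValueError("need >= 3 leaves")
    base: Adj = {0: names[:3]}
    for nm in names[:3]:
        base[nm] = [0]

    def grow(adj: Adj, rest: List[str]) -> Iterator[Adj]:
        if not rest:
            yield adj
            return
        nm, tail = rest[0], rest[1:]
        for u, v in edges(adj):
            new = copy_adj(adj)
            w = _fresh_id(new)
            new[u][new[u].index(v)] = w
            new[v][new[v].index(u)] = w
            new[w] = [u, v, nm]
            new[nm] = [w]
            yield from grow(new, tail)

    yield from grow(base, names[3:])


# ---------------------------------------------------------------------------
# splits


def splits(adj: Adj) -> SplitSet:
    """Nontrivial bipartitions, each encoded as the side not holding the
    lexicographically smallest leaf."""
    lvs = leaves(adj)
    n = len(lvs)
    ref = lvs[0]
    out = set()
    for u, v in edges(adj):
        if isinstance(u, str) or isinstance(v, str):
            continue
        side = frozenset(_component_leaves(adj, v, u))
        if ref in side:
            side = frozenset(lvs) - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return frozenset(out)


def _component_leaves(adj: Adj, start: object, blocked: object) -> List[str]:
    seen = {blocked, start}
    stack = [start]
    out = []
    while stack:
        node = stack.pop()
        if isinstance(node, str):
            out.append(node)
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return out


# ---------------------------------------------------------------------------
# rearrangements


def nni_neighbors(adj: Adj) -> Iterator[Adj]:
    """Both nearest-neighbour interchanges across every internal edge."""
    for u, v in edges(adj):
        if isinstance(u, str) or isinstance(v, str):
            continue
        a, b = [x for x in adj[u] if x != v]
        cs = [x for x in adj[v] if x != u]
        for c in cs:
            new = copy_adj(adj)
            new[u][new[u].index(b)] = c
            new[v][new[v].index(c)] = b
            new[b][new[b].index(u)] = v
            new[c][new[c].index(v)] = u
            yield new


def random_nni(adj: Adj, rng: np.random.Generator) -> Adj:
    nbrs = list(nni_neighbors(adj))
    return nbrs[rng.integers(len(nbrs))]


def spr_neighbors(adj: Adj) -> Iterator[Adj]:
    """Subtree-prune-regraft neighbourhood (excluding the identity move)."""
    for u, v in edges(adj):
        for prune_from, sub in ((u, v), (v, u)):
            # prune the subtree hanging off `sub`, away from `prune_from`
            if isinstance(prune_from, str):
                continue  # nothing left to regraft onto
            rest = [x for x in adj[prune_from] if x != sub]
            if len(rest) != 2:
                continue  # only resolved (degree-3) attachment points
            a, b = rest
            base = copy_adj(adj)
            base[a][base[a].index(prune_from)] = b
            base[b][base[b].index(prune_from)] = a
            del base[prune_from]
            base[sub].remove(prune_from)
            remaining = _component_nodes(base, a, sub)
            for x, y in edges(base):
                if x not in remaining or y not in remaining:
                    continue
                if {x, y} == {a, b}:
                    continue  # regrafting here rebuilds the original tree
                new = copy_adj(base)
                new[x][new[x].index(y)] = prune_from
                new[y][new[y].index(x)] = prune_from
                new[prune_from] = [x, y, sub]
                new[sub].append(prune_from)
                yield new


def _component_nodes(adj: Adj, start: object, avoid: object) -> set:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj.get(node, ()):
            if nb != avoid and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


# ---------------------------------------------------------------------------
# traversal / conversion


def postorder(adj: Adj) -> Tuple[List[object], Dict[object, List[object]]]:
    """Postorder node list and children map, rooted at the smallest internal
    node (or at the first leaf's neighbour for star-like trees)."""
    internals = sorted((n for n in adj if isinstance(n, int)))
    root = internals[0] if internals else next(iter(adj))
    order: List[object] = []
    children: Dict[object, List[object]] = {}
    stack: List[Tuple[object, object]] = [(root, None)]
    visit: List[Tuple[object, object]] = []
    while stack:
        node, parent = stack.pop()
        visit.append((node, parent))
        kids = sorted((nb for nb in adj[node] if nb != parent), key=_key)
        children[node] = kids
        for k in kids:
            stack.append((k, node))
    for node, _ in reversed(visit):
        order.append(node)
    return order, children


def to_newick(adj: Adj, branch_length: "float | None" = None) -> str:
    order, children = postorder(adj)
    root = order[-1]
    bl = "" if branch_length is None else f":{branch_length:g}"

    def render(node: object) -> str:
        kids = children[node]
        if not kids:
            return f"{node}{bl}"
        inner = ",".join(render(k) for k in kids)
        return f"({inner}){bl}"

    return render(root) + ";"


def to_dendropy(adj: Adj, branch_length: "float | None" = 1.0) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=to_newick(adj, branch_length),
        schema="newick",
        preserve_underscores=True,
    )


def from_dendropy(tree: dendropy.Tree) -> Adj:
    """Unrooted adjacency from a dendropy tree; degree-2 nodes suppressed."""
    adj: Adj = {}
    ids: Dict[object, object] = {}
    next_int = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("leaf without a label")
            ids[node] = node.taxon.label
        else:
            ids[node] = next_int
            next_int += 1
        adj[ids[node]] = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            adj[ids[node]].append(ids[child])
            adj[ids[child]].append(ids[node])
    # suppress degree-2 internals (e.g. the root of a rooted input)
    for node in [n for n in adj if isinstance(n, int)]:
        if len(adj[node]) == 2:
            a, b = adj[node]
            adj[a][adj[a].index(node)] = b
            adj[b][adj[b].index(node)] = a
            del adj[node]
    lvs = [n for n in adj if isinstance(n, str)]
    if len(set(lvs)) != len(lvs):
        raise ValueError("duplicate leaf labels")
    return adj
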