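"""Protein-sequence evolution with substitutions and indels along a tree.

The simulator provides known-truth benchmarks: it evolves a root sequence
down a given tree, recording every insertion and deletion, and emits the
*true alignment* — the multiple alignment implied by the actual event
history — together with the true tree and an event log.

Model: Poisson substitutions (per-site replacement probability
``1 - exp(-rate * t)`` on a branch of length ``t``, replacement drawn from
a configurable residue-frequency vector), Poisson indel events with mean
``indel_rate * length * t`` per branch, geometric indel lengths, and a
configurable insertion:deletion ratio.  Insertions create fresh alignment
columns (gaps in every lineage not descending from the event); deletions
turn residues into gaps in the affected lineage only.

The defaults — 32 taxa, root length 300, substitution rate 1.0 and indel
rate 0.02 per site per unit branch length, mean indel length 3, equal
insertion and deletion probability, branch length 0.25 — define moderately
divergent, visibly gappy protein families of the kind used to benchmark
alignment trimming.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .alignment import Alignment, write_sequences

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SYMMETRIC = "symmetric"
ASYMMETRIC = "asymmetric"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated gene set."""

    n_taxa: int = 32
    shape: str = SYMMETRIC
    root_length: int = 300
    sub_rate: float = 1.0            # substitutions / site / unit branch length
    indel_rate: float = 0.02         # indel events / site / unit branch length
    indel_length_p: float = 1.0 / 3  # geometric length parameter (mean 1/p)
    insertion_fraction: float = 0.5  # P(event is an insertion)
    branch_length: float = 0.25      # every branch, in substitutions / site
    seed: int = 0
    frequencies: Optional[Tuple[float, ...]] = None  # uniform over 20 if None

    def validate(self) -> None:
        if self.n_taxa < 3:
            raise SimulationError("n_taxa must be >= 3")
        if self.shape not in (SYMMETRIC, ASYMMETRIC):
            raise SimulationError(f"unknown topology shape: {self.shape!r}")
        if self.root_length < 1:
            raise SimulationError("root sequence length must be >= 1")
        if self.sub_rate < 0 or self.indel_rate < 0 or self.branch_length < 0:
            raise SimulationError("rates and branch lengths must be >= 0")
        if not 0.0 < self.indel_length_p < 1.0:
            raise SimulationError("indel length parameter p must be in (0, 1)")
        if not 0.0 <= self.insertion_fraction <= 1.0:
            raise SimulationError("insertion fraction must be in [0, 1]")
        if self.frequencies is not None:
            f = np.asarray(self.frequencies, dtype=float)
            if f.shape != (20,) or np.any(f < 0) or not np.isclose(f.sum(), 1.0):
                raise SimulationError(
                    "frequencies must be 20 nonnegative values summing to 1"
                )


@dataclass(frozen=True)
class IndelEvent:
    branch: str        # label of the child node of the branch
    kind: str          # "insertion" | "deletion"
    site: int          # first affected column in final alignment coords; -1 if
                       # every affected column was later lost from all leaves
    length: int        # event length in residues


@dataclass
class SimulationRecord:
    true_tree: dendropy.Tree
    alignment: Alignment
    leaf_sequences: Dict[str, str]   # evolved, ungapped
    events: List[IndelEvent] = field(default_factory=list)


def make_topology(shape: str, n_taxa: int, branch_length: float) -> dendropy.Tree:
    """Balanced ("symmetric") or caterpillar ("asymmetric") tree with equal
    branch lengths and leaves t1..tN."""
    if n_taxa < 3:
        raise SimulationError("n_taxa must be >= 3")
    if branch_length < 0:
        raise SimulationError("branch length must be >= 0")
    names = [f"t{i + 1}" for i in range(n_taxa)]
    bl = f":{branch_length:g}"
    if shape == SYMMETRIC:
        if n_taxa & (n_taxa - 1) != 0:
            raise SimulationError(
                f"symmetric topology requires a power-of-2 taxon count, got {n_taxa}"
            )

        def balance(block: Sequence[str]) -> str:
            if len(block) == 1:
                return f"{block[0]}{bl}"
            half = len(block) // 2
            return f"({balance(block[:half])},{balance(block[half:])}){bl}"

        half = n_taxa // 2
        newick = f"({balance(names[:half])},{balance(names[half:])});"
    elif shape == ASYMMETRIC:
        nwk = f"({names[0]}{bl},{names[1]}{bl})"
        for nm in names[2:]:
            nwk = f"({nwk}{bl},{nm}{bl})"
        newick = nwk + ";"
    else:
        raise SimulationError(f"unknown topology shape: {shape!r}")
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def simulate(config: SimulationConfig, tree: dendropy.Tree) -> SimulationRecord:
    """Evolve a root sequence down ``tree`` and return the true alignment,
    the evolved leaf sequences and the indel event log.  Fully determined by
    ``config.seed``."""
    config.validate()
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaf_labels) != config.n_taxa:
        raise SimulationError(
            f"tree has {len(leaf_labels)} leaves but config.n_taxa={config.n_taxa}"
        )
    rng = np.random.default_rng(config.seed)
    freqs = (
        np.full(20, 0.05)
        if config.frequencies is None
        else np.asarray(config.frequencies, dtype=float)
    )
    alphabet = np.array(list(AMINO_ACIDS))

    # master column bookkeeping: parallel lists of column ids and, per node,
    # aligned character rows over those columns
    col_ids: List[int] = list(range(config.root_length))
    next_col = config.root_length
    rows: Dict[int, List[str]] = {}

    root_seq = rng.choice(alphabet, size=config.root_length, p=freqs)
    raw_events: List[Tuple[str, str, List[int], int]] = []

    node_names: Dict[int, str] = {}
    n_internal = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node_names[id(node)] = node.taxon.label
        else:
            node_names[id(node)] = f"n{n_internal}"
            n_internal += 1

    rows[id(tree.seed_node)] = list(root_seq)

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_row = rows[id(node.parent_node)]
        t = node.edge.length if node.edge.length is not None else 0.0
        child = list(parent_row)
        name = node_names[id(node)]

        # substitutions
        res_idx = [i for i, c in enumerate(child) if c != "-"]
        if res_idx and config.sub_rate > 0 and t > 0:
            p_sub = 1.0 - np.exp(-config.sub_rate * t)
            hits = rng.random(len(res_idx)) < p_sub
            n_hit = int(hits.sum())
            if n_hit:
                repl = rng.choice(alphabet, size=n_hit, p=freqs)
                for k, i in enumerate(np.asarray(res_idx)[hits]):
                    child[i] = repl[k]

        # indels
        n_events = (
            rng.poisson(config.indel_rate * len(res_idx) * t)
            if config.indel_rate > 0 and t > 0
            else 0
        )
        for _ in range(n_events):
            res_idx = [i for i, c in enumerate(child) if c != "-"]
            n_res = len(res_idx)
            is_insertion = rng.random() < config.insertion_fraction
            length = int(rng.geometric(config.indel_length_p))
            if is_insertion:
                k = int(rng.integers(0, n_res + 1))
                m = 0 if k == 0 else res_idx[k - 1] + 1
                new_ids = list(range(next_col, next_col + length))
                next_col += length
                col_ids[m:m] = new_ids
                for row in rows.values():
                    row[m:m] = ["-"] * length
                child[m:m] = list(rng.choice(alphabet, size=length, p=freqs))
                raw_events.append((name, "insertion", new_ids, length))
            else:
                if n_res <= 1:
                    continue  # never delete a lineage down to nothing
                s = int(rng.integers(0, n_res))
                eff = min(length, n_res - s, n_res - 1)
                if eff <= 0:
                    continue
                cols = [col_ids[res_idx[s + j]] for j in range(eff)]
                for j in range(eff):
                    child[res_idx[s + j]] = "-"
                raw_events.append((name, "deletion", cols, eff))

        rows[id(node)] = child

    # assemble the leaf alignment; drop columns no leaf retains
    leaf_nodes = list(tree.leaf_node_iter())
    leaf_rows = {lf.taxon.label: rows[id(lf)] for lf in leaf_nodes}
    keep = [
        j
        for j in range(len(col_ids))
        if any(r[j] != "-" for r in leaf_rows.values())
    ]
    final_index = {col_ids[j]: k for k, j in enumerate(keep)}
    aln = Alignment(
        [(lbl, "".join(leaf_rows[lbl][j] for j in keep)) for lbl in leaf_labels]
    )
    events = [
        IndelEvent(
            branch=name,
            kind=kind,
            site=next((final_index[c] for c in cols if c in final_index), -1),
            length=length,
        )
        for name, kind, cols, length in raw_events
    ]
    leaf_sequences = {lbl: aln[lbl].replace("-", "") for lbl in leaf_labels}
    return SimulationRecord(
        true_tree=tree,
        alignment=aln,
        leaf_sequences=leaf_sequences,
        events=events,
    )


def set_seed(master_seed: int, index: int) -> int:
    """Deterministic per-set seed derived from a master seed."""
    return int(
        np.random.SeedSequence((master_seed, index)).generate_state(1)[0]
        % (2**31)
    )


def simulate_set(config: SimulationConfig, index: int, master_seed: int
                 ) -> SimulationRecord:
    """One gene set of a multi-set dataset: fresh topology + seed ``index``
    derived from ``master_seed``."""
    cfg = SimulationConfig(
        **{**config.__dict__, "seed": set_seed(master_seed, index)}
    )
    tree = make_topology(cfg.shape, cfg.n_taxa, cfg.branch_length)
    return simulate(cfg, tree)


def generate_dataset(config: SimulationConfig, n_sets: int, out_dir) -> dict:
    """Write ``n_sets`` independent simulation records under ``out_dir``
    (per set: true alignment, ungapped sequences, true tree, event log) and
    a JSON manifest; returns the manifest."""
    if n_sets < 1:
        raise SimulationError("n_sets must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()
        },
        "n_sets": n_sets,
        "sets": [],
    }
    for i in range(n_sets):
        rec = simulate_set(config, i, config.seed)
        d = out / f"set_{i:03d}"
        d.mkdir(exist_ok=True)
        rec.alignment.to_fasta(d / "true_alignment.fasta")
        write_sequences(rec.leaf_sequences, d / "sequences.fasta")
        rec.true_tree.write(
            path=str(d / "true_tree.nwk"),
            schema="newick",
            suppress_rooting=True,
        )
        with open(d / "events.tsv", "w") as fh:
            fh.write("branch\tkind\tsite\tlength\n")
            for ev in rec.events:
                fh.write(f"{ev.branch}\t{ev.kind}\t{ev.site}\t{ev.length}\n")
        manifest["sets"].append(
            {
                "name": d.name,
                "seed": set_seed(config.seed, i),
                "n_events": len(rec.events),
                "n_columns": rec.alignment.n_columns,
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
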