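"""Heads-or-tails consistency trimming.

Aligning the same sequences in forward and reversed orientation exposes
arbitrarily placed gaps: a gap whose position was a coin-flip between tied
dynamic-programming paths tends to land elsewhere when the sequences are
reversed, while a gap demanded by the data stays put.  Columns of the
forward alignment that are inconsistent with the back-mapped reverse
alignment are removed before gap scoring (default cutoff 0.05).

The per-column consistency score is the fraction of residue pairs
co-aligned in that forward column that are also co-aligned in one column
of the back-mapped reverse alignment.  Columns with fewer than two
residues are vacuously consistent (score 1.0): they carry exactly the gap
patterns under study, and discarding them by fiat would bias downstream
gap-precision comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import dendropy
import numpy as np

from . import aligner as _aligner
from .alignment import GAP, Alignment
from .gapscore import OpeningMap

DEFAULT_CUTOFF = 0.05


class HotTrimError(ValueError):
    pass


def reverse_align(
    sequences: Dict[str, str],
    guide_tree: Optional[dendropy.Tree] = None,
    scheme: Optional[_aligner.ScoringScheme] = None,
) -> Alignment:
    """Align the reversed sequences, then flip the result back so rows read
    in forward orientation and strip-gaps reproduces the inputs."""
    reversed_seqs = {i: s[::-1] for i, s in sequences.items()}
    aln, _ = _aligner.progressive_align(reversed_seqs, guide_tree, scheme)
    return Alignment([(i, row[::-1]) for i, row in aln])


def _residue_coordinates(aln: Alignment) -> Dict[str, List[int]]:
    """Per row: residue index at each column (-1 for gaps)."""
    out = {}
    for i, row in aln:
        coords = []
        r = 0
        for c in row:
            if c == GAP:
                coords.append(-1)
            else:
                coords.append(r)
                r += 1
        out[i] = coords
    return out


def consistency_scores(forward: Alignment, backmapped: Alignment) -> np.ndarray:
    """Per-forward-column fraction of co-aligned residue pairs that are
    also co-aligned in the back-mapped alignment."""
    if set(forward.ids) != set(backmapped.ids):
        raise HotTrimError("identifier sets differ between the two alignments")
    fwd_seqs, back_seqs = forward.strip_gaps(), backmapped.strip_gaps()
    bad = sorted(i for i in fwd_seqs if fwd_seqs[i] != back_seqs[i])
    if bad:
        raise HotTrimError(
            f"gap-stripped sequences differ for {bad}; the alignments do not "
            "align the same sequences"
        )
    # column of each (sequence, residue) in the back-mapped alignment
    back_col: Dict[Tuple[str, int], int] = {}
    back_coords = _residue_coordinates(backmapped)
    for i in backmapped.ids:
        for j, r in enumerate(back_coords[i]):
            if r >= 0:
                back_col[(i, r)] = j
    fwd_coords = _residue_coordinates(forward)
    ids = forward.ids
    scores = np.ones(forward.n_columns)
    for j in range(forward.n_columns):
        members = [
            (i, fwd_coords[i][j]) for i in ids if fwd_coords[i][j] >= 0
        ]
        if len(members) < 2:
            continue  # vacuously consistent
        total = consistent = 0
        for a in range(len(members)):
            ca = back_col[members[a]]
            for b in range(a + 1, len(members)):
                total += 1
                if ca == back_col[members[b]]:
                    consistent += 1
        scores[j] = consistent / total
    return scores


@dataclass
class TrimResult:
    alignment: Alignment
    kept_columns: List[int]
    scores: np.ndarray
    cutoff: float


def trim(
    aln: Alignment, scores: np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> TrimResult:
    """Remove columns whose consistency score is below ``cutoff``."""
    if not 0.0 <= cutoff <= 1.0:
        raise HotTrimError("cutoff must be in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (aln.n_columns,):
        raise HotTrimError("one score per alignment column required")
    kept = [j for j in range(aln.n_columns) if scores[j] >= cutoff]
    if not kept:
        raise HotTrimError(
            f"trimming at cutoff {cutoff} would remove every column"
        )
    rows = [(i, "".join(row[j] for j in kept)) for i, row in aln]
    for i, r in rows:
        if set(r) <= {GAP}:
            raise HotTrimError(
                f"trimming at cutoff {cutoff} empties sequence {i!r}"
            )
    return TrimResult(
        alignment=Alignment(rows),
        kept_columns=kept,
        scores=scores,
        cutoff=cutoff,
    )


def surviving_openings(
    forward: Alignment, kept_columns: List[int]
) -> OpeningMap:
    """Gap openings of ``forward`` whose gap block survives trimming, in the
    original (untrimmed) residue coordinates.

    An opening survives when at least one column of its gap block is kept;
    its site stays anchored to the full row's residues, so the map is
    directly comparable to a reference opening map.  Two blocks merged by
    trimming still count as their original openings."""
    kept = set(kept_columns)
    out: OpeningMap = {}
    for i, row in forward:
        sites: Set[int] = set()
        residues = 0
        block_cols: List[int] = []
        block_site = -1
        for j, c in enumerate(row + "X"):  # sentinel flushes a trailing block
            if j < len(row) and c == GAP:
                if not block_cols:
                    block_site = residues
                block_cols.append(j)
            else:
                if block_cols and any(b in kept for b in block_cols):
                    sites.add(block_site)
                block_cols = []
                if j < len(row):
                    residues += 1
        out[i] = sites
    return out


@dataclass
class HotTrimReport:
    forward: Alignment
    backmapped: Alignment
    scores: np.ndarray
    trimmed: TrimResult
    surviving: OpeningMap


def hot_trim(
    sequences: Dict[str, str],
    guide_tree: Optional[dendropy.Tree] = None,
    scheme: Optional[_aligner.ScoringScheme] = None,
    cutoff: float = DEFAULT_CUTOFF,
    forward: Optional[Alignment] = None,
) -> HotTrimReport:
    """Forward/reverse align, score consistency, trim, and report the gap
    openings that survive.  A precomputed forward alignment of the same
    sequences (e.g. from an earlier pipeline stage) may be passed to avoid
    aligning twice."""
    if forward is None:
        forward, _ = _aligner.progressive_align(sequences, guide_tree, scheme)
    backmapped = reverse_align(sequences, guide_tree, scheme)
    scores = consistency_scores(forward, backmapped)
    trimmed = trim(forward, scores, cutoff)
    return HotTrimReport(
        forward=forward,
        backmapped=backmapped,
        scores=scores,
        trimmed=trimmed,
        surviving=surviving_openings(forward, trimmed.kept_columns),
    )
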