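"""Precision and accuracy of gap placement against a reference alignment.

Gap openings are recoded by their flanking residues: each maximal run of
gap characters in a row is represented by a single *opening site* — the
number of that row's residues strictly preceding the run (0 = before the
first residue, L = after the last).  Because sites are anchored in
ungapped-residue coordinates, a reference and a test alignment of the same
sequences can be compared site by site regardless of how their columns
line up.

Per (sequence, site): opening in both alignments is a true positive, only
in the test a false positive, only in the reference a false negative, in
neither a true negative.  Precision = TP/(TP+FP) — the fraction of
inserted gap openings that sit between the same residues as a true event —
and accuracy = (TP+TN)/(TP+FP+TN+FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Set

from .alignment import GAP, Alignment

OpeningMap = Dict[str, Set[int]]


class GapScoreError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> Optional[float]:
        """TP/(TP+FP); None when no openings were predicted at all."""
        denom = self.tp + self.fp
        return None if denom == 0 else self.tp / denom

    @property
    def accuracy(self) -> Optional[float]:
        denom = self.tp + self.fp + self.fn + self.tn
        return None if denom == 0 else (self.tp + self.tn) / denom


def row_opening_sites(row: str) -> Set[int]:
    """Opening sites of one gapped row (residues preceding each gap block)."""
    if set(row) == {GAP}:
        raise GapScoreError("row consists only of gaps; nothing to anchor on")
    sites: Set[int] = set()
    residues = 0
    in_gap = False
    for c in row:
        if c == GAP:
            if not in_gap:
                sites.add(residues)
                in_gap = True
        else:
            residues += 1
            in_gap = False
    return sites


def recode_openings(aln: Alignment) -> OpeningMap:
    """Per-sequence set of gap-opening sites in residue coordinates."""
    return {i: row_opening_sites(row) for i, row in aln}


def compare_opening_maps(
    reference: OpeningMap,
    test: OpeningMap,
    lengths: Dict[str, int],
    include_terminal: bool = True,
) -> ConfusionCounts:
    """Confusion counts over all (sequence, site) slots, sites 0..L each.

    ``lengths`` gives each sequence's ungapped length L.  With
    ``include_terminal=False`` the terminal slots 0 and L are excluded."""
    tp = fp = fn = tn = 0
    for sid, length in lengths.items():
        ref = reference.get(sid, set())
        tst = test.get(sid, set())
        sites = range(length + 1) if include_terminal else range(1, length)
        for s in sites:
            in_ref, in_tst = s in ref, s in tst
            if in_ref and in_tst:
                tp += 1
            elif in_tst:
                fp += 1
            elif in_ref:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def score_gaps(
    reference: Alignment,
    test: Alignment,
    include_terminal: bool = True,
) -> ConfusionCounts:
    """Score the gap openings of ``test`` against ``reference``.

    The two alignments must align the same sequences: identical identifier
    sets and identical gap-stripped rows."""
    if set(reference.ids) != set(test.ids):
        raise GapScoreError(
            "identifier sets differ: "
            f"reference-only {sorted(set(reference.ids) - set(test.ids))}, "
            f"test-only {sorted(set(test.ids) - set(reference.ids))}"
        )
    ref_seqs = reference.strip_gaps()
    test_seqs = test.strip_gaps()
    bad = sorted(i for i in ref_seqs if ref_seqs[i] != test_seqs[i])
    if bad:
        raise GapScoreError(
            f"gap-stripped sequences differ for {bad}; the alignments do not "
            "align the same sequences"
        )
    lengths = {i: len(s) for i, s in ref_seqs.items()}
    return compare_opening_maps(
        recode_openings(reference),
        recode_openings(test),
        lengths,
        include_terminal=include_terminal,
    )
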