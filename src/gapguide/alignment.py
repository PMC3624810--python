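"""Multiple sequence alignment container.

The :class:`Alignment` is the central exchange object of the package: an
ordered mapping of sequence identifiers to equal-length gapped rows over a
residue alphabet plus ``'-'``.  Invariants enforced on construction:

* all rows have the same length,
* identifiers are unique and non-empty,
* no column consists entirely of gaps.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


class AlignmentError(ValueError):
    """Raised when alignment invariants are violated."""


class Alignment:
    """An ordered set of equal-length gapped sequences."""

    def __init__(self, rows: "Dict[str, str] | Iterable[Tuple[str, str]]"):
        if isinstance(rows, dict):
            items = list(rows.items())
        else:
            items = list(rows)
        if not items:
            raise AlignmentError("alignment needs at least one sequence")
        ids = [i for i, _ in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate identifiers: {dupes}")
        if any(not i for i in ids):
            raise AlignmentError("empty identifier")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
        self._ids: List[str] = ids
        self._rows: Dict[str, str] = dict(items)
        ncol = lengths.pop()
        for j in range(ncol):
            if all(self._rows[i][j] == GAP for i in ids):
                raise AlignmentError(f"column {j} is all gaps")
        self._ncol = ncol

    # -- basic accessors -------------------------------------------------

    @property
    def ids(self) -> List[str]:
        return list(self._ids)

    @property
    def n_columns(self) -> int:
        return self._ncol

    def __len__(self) -> int:
        return len(self._ids)

    def __getitem__(self, key: str) -> str:
        return self._rows[key]

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return ((i, self._rows[i]) for i in self._ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self._ids == other._ids and self._rows == other._rows

    def __repr__(self) -> str:
        return f"<Alignment: {len(self)} sequences x {self.n_columns} columns>"

    def column(self, j: int) -> List[str]:
        return [self._rows[i][j] for i in self._ids]

    def strip_gaps(self) -> Dict[str, str]:
        """Ungapped sequence per identifier, preserving row order."""
        return {i: self._rows[i].replace(GAP, "") for i in self._ids}

    def ungapped_length(self, identifier: str) -> int:
        row = self._rows[identifier]
        return len(row) - row.count(GAP)

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """New alignment keeping ``columns`` in the given order."""
        return Alignment(
            [(i, "".join(self._rows[i][j] for j in columns)) for i in self._ids]
        )

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        return cls([(r.id, str(r.seq)) for r in records])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self._rows[i]), id=i, description="") for i in self._ids
        ]
        SeqIO.write(records, str(path), "fasta")


def read_sequences(path) -> Dict[str, str]:
    """Read unaligned FASTA into an ordered {id: sequence} mapping."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AlignmentError(f"duplicate identifier in {path}: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise AlignmentError(f"no sequences in {path}")
    return seqs


def write_sequences(seqs: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
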