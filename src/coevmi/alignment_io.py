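"""Aligned-FASTA input and species pairing.

Two ortholog alignments (one per protein) are matched by their full FASTA
header lines: species present in both files are kept, everything else is
dropped, and a user-chosen reference species supplies the residue numbering
used in all reports.  Columns where the reference row carries a gap are
excluded, so positions always refer to real residues of the reference
sequence (1-based).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

from Bio import SeqIO

from .exceptions import (
    AlignmentFormatError,
    InsufficientSpeciesError,
    MissingReferenceError,
)

logger = logging.getLogger(__name__)

GAP = "-"
#: letters accepted in input sequences; '.' is normalised to '-' on read and
#: '*' (stop) is tolerated but never counted as a residue.
_ALLOWED = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ-*")


@dataclass
class Alignment:
    """One protein's multiple sequence alignment.

    ``records`` maps the full header line to the aligned sequence (upper-case,
    gap character ``-``).  All sequences share the same column count.
    """

    records: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) > 1:
            raise AlignmentFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(next(iter(self.records.values()))) if self.records else 0

    @property
    def species(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, header: str) -> bool:
        return header in self.records


@dataclass
class PairedAlignment:
    """Two alignments restricted to their common species.

    ``seqs1``/``seqs2`` hold one aligned sequence per species, in ``species``
    order (protein-1 file order).  ``refmap1``/``refmap2`` list
    ``(alignment_column_index, reference_position)`` pairs covering exactly
    the columns where the reference species has a residue; reference
    positions are 1-based and strictly increasing.
    """

    species: list[str]
    seqs1: list[str]
    seqs2: list[str]
    refmap1: list[tuple[int, int]]
    refmap2: list[tuple[int, int]]
    reference: str = field(default="")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def column(self, protein: int, col: int) -> list[str]:
        """Residues (one per species) at alignment column ``col`` of protein 1 or 2."""
        seqs = self.seqs1 if protein == 1 else self.seqs2
        return [s[col] for s in seqs]


def _clean(seq: str) -> str:
    seq = seq.upper().replace(".", GAP)
    bad = set(seq) - _ALLOWED
    if bad:
        raise AlignmentFormatError(f"illegal characters in sequence: {sorted(bad)}")
    return seq


def read_alignment(path: str | PathLike) -> Alignment:
    """Read an aligned FASTA file.

    Lower-case residues are upper-cased and ``.`` gaps become ``-``.
    Duplicate headers keep the first occurrence (a warning is logged).
    Raises :class:`AlignmentFormatError` for empty files, ragged sequence
    lengths or non-FASTA content.
    """
    path = Path(path)
    records: dict[str, str] = {}
    with open(path) as handle:
        head = handle.read(1)
        if head != ">":
            raise AlignmentFormatError(f"{path}: not FASTA (no leading '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if header in records:
            logger.warning("%s: duplicate header %r ignored (first kept)", path, header)
            continue
        records[header] = _clean(str(rec.seq))
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records found")
    aln = Alignment(records)
    if aln.length == 0:
        raise AlignmentFormatError(f"{path}: records contain no sequence")
    return aln


def write_alignment(aln: Alignment, path: str | PathLike, width: int = 60) -> None:
    """Write an :class:`Alignment` as aligned FASTA (deterministic layout)."""
    with open(path, "w") as fh:
        for header, seq in aln.records.items():
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _build_refmap(refseq: str) -> list[tuple[int, int]]:
    refmap = []
    pos = 0
    for col, ch in enumerate(refseq):
        if ch != GAP:
            pos += 1
            refmap.append((col, pos))
    return refmap


def pair_alignments(
    a1: Alignment,
    a2: Alignment,
    ref: str,
    min_common: int = 100,
) -> PairedAlignment:
    """Intersect species of two alignments and map reference coordinates.

    Species are matched by exact full-header equality; the result keeps
    protein-1 file order.  Fails with :class:`MissingReferenceError` if
    ``ref`` is absent from either file and :class:`InsufficientSpeciesError`
    if fewer than ``min_common`` species are shared.
    """
    if ref not in a1 or ref not in a2:
        raise MissingReferenceError(f"reference species {ref!r} not in both alignments")
    common = [h for h in a1.records if h in a2.records]
    if len(common) < min_common:
        raise InsufficientSpeciesError(
            f"only {len(common)} common species; at least {min_common} required"
        )
    seqs1 = [a1.records[h] for h in common]
    seqs2 = [a2.records[h] for h in common]
    return PairedAlignment(
        species=common,
        seqs1=seqs1,
        seqs2=seqs2,
        refmap1=_build_refmap(a1.records[ref]),
        refmap2=_build_refmap(a2.records[ref]),
        reference=ref,
    )


def pair_files(
    path1: str | PathLike,
    path2: str | PathLike,
    ref: str,
    min_common: int = 100,
) -> PairedAlignment:
    """Convenience: read both FASTA files and pair them."""
    return pair_alignments(read_alignment(path1), read_alignment(path2), ref, min_common)
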