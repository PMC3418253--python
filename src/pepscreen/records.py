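"""Sequence record model, FASTA I/O and cDNA-to-protein translation.

Records are thin frozen dataclasses rather than raw ``SeqRecord`` objects so
that every stage of the screen works on a validated, uppercase alphabet with
a species tag attached.  Biopython handles the actual FASTA parsing/writing
and codon translation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable

from Bio import SeqIO

#: The 20 standard residues plus 'X' for unknown.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
#: The 20 standard residues (no unknown).
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty records, illegal residues)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with annotation text and a species tag.

    ``sequence`` is uppercase over the 20 IUPAC one-letter residues with 'X'
    permitted as unknown; 'X' scores zero in every downstream scoring
    context.
    """

    id: str
    sequence: str
    description: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        _validate_sequence(self.sequence, PROTEIN_ALPHABET, self.id)

    def __len__(self) -> int:
        return len(self.sequence)

    def with_species(self, species: str) -> "ProteinRecord":
        return replace(self, species=species)


@dataclass(frozen=True)
class NucleotideRecord:
    """A nucleotide sequence (uppercase A/C/G/T/N), e.g. a full-length cDNA."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        _validate_sequence(self.sequence, NUCLEOTIDE_ALPHABET, self.id)

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequence(sequence: str, alphabet: frozenset, record_id: str) -> None:
    if not sequence:
        raise FastaFormatError(f"record {record_id!r}: empty sequence")
    for offset, char in enumerate(sequence):
        if char not in alphabet:
            raise FastaFormatError(
                f"record {record_id!r}: illegal character {char!r} at offset {offset}"
            )


def read_fasta(path: str | os.PathLike, *, nucleotide: bool = False,
               species: str = "") -> list[ProteinRecord] | list[NucleotideRecord]:
    """Read a multi-FASTA file into validated records, preserving order.

    Sequences are uppercased and terminal '*' stop characters stripped.
    Raises :class:`FileNotFoundError` for a missing file and
    :class:`FastaFormatError` for an empty file, an empty record or an
    illegal residue (naming the record and offset).
    """
    raw = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not raw:
        raise FastaFormatError(f"{path}: no FASTA records found")
    records: list = []
    seen: set[str] = set()
    for rec in raw:
        seq = str(rec.seq).upper().strip("*")
        # SeqIO puts the id back at the front of .description; keep the rest.
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        if nucleotide:
            records.append(NucleotideRecord(id=rec.id, sequence=seq, description=desc))
        else:
            records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc,
                                         species=species))
    return records


def write_fasta(records: Iterable[ProteinRecord | NucleotideRecord],
                path: str | os.PathLike, line_width: int = 60) -> None:
    """Write records as wrapped multi-FASTA; an empty list yields an empty file."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                handle.write(rec.sequence[i:i + line_width] + "\n")


def _forward_orfs(seq: str) -> list[tuple[int, str]]:
    """Maximal ATG-initiated forward-strand ORFs as (0-based start, protein).

    Per frame, each stop-free codon run contributes its first ATG (any later
    ATG in the same run starts a strictly shorter, nested ORF).
    """
    from Bio.Data.CodonTable import standard_dna_table

    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    orfs: list[tuple[int, str]] = []
    n = len(seq)
    for frame in range(3):
        run_start: int | None = None  # codon offset of first ATG in current run
        prot: list[str] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon in stops:
                if run_start is not None and prot:
                    orfs.append((run_start, "".join(prot)))
                run_start, prot = None, []
                continue
            if run_start is None and codon == "ATG":
                run_start = i
            if run_start is not None:
                prot.append(table.get(codon, "X"))
        if run_start is not None and prot:
            orfs.append((run_start, "".join(prot)))
    return orfs


def translate_longest_orf(nt: NucleotideRecord) -> ProteinRecord:
    """Translate the longest ATG-initiated forward-strand ORF (stop excluded).

    Ties are broken toward the smallest start coordinate.  The screening
    corpus is full-length cDNA, already oriented, so only the forward strand
    is searched.  Raises :class:`ValueError` when no ATG-initiated ORF
    exists.
    """
    orfs = _forward_orfs(nt.sequence)
    if not orfs:
        raise ValueError(f"record {nt.id!r}: no ATG-initiated open reading frame")
    start, protein = max(orfs, key=lambda sp: (len(sp[1]), -sp[0]))
    return ProteinRecord(id=nt.id, sequence=protein,
                         description=nt.description or "translated ORF")
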