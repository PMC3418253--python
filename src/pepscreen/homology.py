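"""Cross-species conservation scoring by global pairwise alignment.

"Homology" is operationalised as global (Needleman–Wunsch, affine gaps)
percent identity over alignment columns, gap columns included in the
denominator; percent similarity additionally counts conservative
substitutions (Clustal strong groups).  Alignments use BLOSUM62 with
EMBOSS-needle-style gap penalties (open 10, extend 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

#: Clustal conservation groups.
STRONG_GROUPS = ("STA", "NEQK", "NHQK", "NDEQ", "QHRK",
                 "MILV", "MILF", "HY", "FYW")
WEAK_GROUPS = ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
               "NDEQHK", "NEQHRK", "FVLIM", "HFY")

GAP = "-"

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class Alignment:
    """A gapped global alignment of two sequences with its optimal score."""

    aligned_a: str
    aligned_b: str
    score: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class HomologyReport:
    """Pairwise identity/similarity between two (putatively orthologous) records."""

    id_a: str
    id_b: str
    species_a: str
    species_b: str
    percent_identity: float
    percent_similarity: float
    alignment_length: int
    column_classes: str


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # Biopython convention: first gap residue costs open, each further extend.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(a: str, b: str, matrix_name: str = "BLOSUM62",
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> Alignment:
    """Optimal global alignment with affine gaps; deterministic traceback.

    Among co-optimal alignments the first in Biopython's deterministic
    traceback order is returned; the score is the unique optimum, which is
    what the screen's identity computation and the tests' exhaustive oracle
    compare.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    return Alignment(aligned_a=aligned_a, aligned_b=aligned_b,
                     score=float(alignment.score))


def conservation_classes(aligned_a: str, aligned_b: str) -> str:
    """Clustal-style per-column classes: '*' identity, ':' strong group,
    '.' weak group, ' ' otherwise; gap columns are never conserved."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    classes = []
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            classes.append(" ")
        elif x == y:
            classes.append("*")
        elif any(x in g and y in g for g in STRONG_GROUPS):
            classes.append(":")
        elif any(x in g and y in g for g in WEAK_GROUPS):
            classes.append(".")
        else:
            classes.append(" ")
    return "".join(classes)


@lru_cache(maxsize=4096)
def pairwise_report(id_a: str, seq_a: str, id_b: str, seq_b: str,
                    species_a: str = "", species_b: str = "",
                    matrix_name: str = "BLOSUM62",
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND,
                    denominator: str = "columns") -> HomologyReport:
    """Align two sequences and derive identity/similarity percentages.

    Pure and memoised (repeated screens over one corpus re-use alignments).
    ``denominator`` selects the identity denominator: ``"columns"`` (all
    alignment columns, gaps included — the default) or ``"shorter"`` (length
    of the shorter sequence).
    """
    aln = global_align(seq_a, seq_b, matrix_name, gap_open, gap_extend)
    classes = conservation_classes(aln.aligned_a, aln.aligned_b)
    identical = classes.count("*")
    strong = classes.count(":")
    if denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    elif denominator == "columns":
        denom = aln.length
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return HomologyReport(
        id_a=id_a, id_b=id_b, species_a=species_a, species_b=species_b,
        percent_identity=100.0 * identical / denom,
        percent_similarity=100.0 * (identical + strong) / denom,
        alignment_length=aln.length,
        column_classes=classes,
    )


def meets_homology_threshold(reports: Sequence[HomologyReport],
                             threshold: float = 50.0) -> bool:
    """True iff the minimum pairwise percent identity exceeds ``threshold``."""
    if not reports:
        raise ValueError("meets_homology_threshold requires >= 1 report")
    return min(r.percent_identity for r in reports) > threshold
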