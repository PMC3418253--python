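"""Candidate peptide excision, mass prediction and MALDI peak assignment.

Residue masses are computed from residue elemental compositions and atomic
masses (monoisotopic: lightest isotope; average: abundance-weighted standard
atomic weights), so the table is reproducible from first principles.  A
peptide's mass is the sum of its residue masses plus one water.

The reported "predicted molecular weight" convention is the average mass:
MALDI-TOF in linear mode does not resolve the isotope envelope of a ~5.8 kDa
peptide, so observed peaks sit at the average [M+H]+ mass — which is also why
a small positive observed-minus-predicted delta (protonation, ~+1 Da, plus
matrix adducts) is expected and the default match tolerance is 5 Da.
Glycan or other post-translational masses are not modelled; a documented
limitation explaining larger predicted-vs-observed gaps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pepscreen.convertase import CleavageMotifHit, Fragment, segment_by_cleavage
from pepscreen.records import ProteinRecord
from pepscreen.signal_peptide import SignalPeptideCall

#: Atomic masses: (monoisotopic, average standard atomic weight).
ATOMIC_MASS = {
    "H": (1.0078250319, 1.00794),
    "C": (12.0, 12.0107),
    "N": (14.0030740052, 14.0067),
    "O": (15.9949146221, 15.9994),
    "S": (31.97207069, 32.065),
}

#: Residue (amino acid minus water) elemental compositions.
RESIDUE_FORMULA = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER_FORMULA = {"H": 2, "O": 1}


def _formula_mass(formula: Mapping[str, int], which: int) -> float:
    return sum(ATOMIC_MASS[el][which] * n for el, n in formula.items())


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue average and monoisotopic masses in Da, plus water."""

    average: Mapping[str, float]
    monoisotopic: Mapping[str, float]
    water_average: float
    water_monoisotopic: float

    @classmethod
    def standard(cls) -> "ResidueMassTable":
        return cls(
            average={r: _formula_mass(f, 1) for r, f in RESIDUE_FORMULA.items()},
            monoisotopic={r: _formula_mass(f, 0) for r, f in RESIDUE_FORMULA.items()},
            water_average=_formula_mass(WATER_FORMULA, 1),
            water_monoisotopic=_formula_mass(WATER_FORMULA, 0),
        )


STANDARD_MASS_TABLE = ResidueMassTable.standard()

DEFAULT_MASS_WINDOW = (3000.0, 10000.0)
DEFAULT_TOLERANCE_DA = 5.0


@dataclass(frozen=True)
class PeptideCandidate:
    """An excised peptide with flanking cleavage evidence and predicted masses."""

    parent_id: str
    start: int
    end: int
    sequence: str
    n_flank: str
    c_flank: str
    average_mass_da: float
    monoisotopic_mass_da: float


@dataclass(frozen=True)
class MassSpectrumPeakList:
    """Observed m/z peaks, sorted ascending and strictly positive."""

    peaks: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.peaks):
            raise ValueError("peaks must be strictly positive")
        if list(self.peaks) != sorted(self.peaks):
            raise ValueError("peaks must be sorted ascending")


@dataclass(frozen=True)
class MassAssignment:
    """A candidate-to-peak assignment; ``delta_da`` is observed - predicted."""

    candidate_id: str
    predicted_mass_da: float
    peak_mz: float | None
    delta_da: float | None


def peptide_mass(sequence: str, kind: str = "average",
                 table: ResidueMassTable = STANDARD_MASS_TABLE) -> float:
    """Mass of a peptide in Da: sum of residue masses plus one water.

    ``kind`` is ``"average"`` or ``"monoisotopic"``.  'X' (unknown residue)
    has no defined mass and raises :class:`ValueError`.
    """
    if not sequence:
        raise ValueError("peptide_mass requires a non-empty sequence")
    if "X" in sequence:
        raise ValueError("mass undefined for sequences containing 'X'")
    if kind == "average":
        residue, water = table.average, table.water_average
    elif kind == "monoisotopic":
        residue, water = table.monoisotopic, table.water_monoisotopic
    else:
        raise ValueError(f"unknown mass kind {kind!r}")
    try:
        return sum(residue[c] for c in sequence) + water
    except KeyError as exc:
        raise ValueError(f"mass undefined for residue {exc.args[0]!r}") from exc


def excise_candidates(record: ProteinRecord,
                      signal_call: SignalPeptideCall | None,
                      motif_hits: Iterable[CleavageMotifHit],
                      mass_window_da: tuple[float, float] = DEFAULT_MASS_WINDOW,
                      ) -> list[PeptideCandidate]:
    """Excise convertase/signal-delimited fragments within the mass window.

    Fragments are produced by :func:`segment_by_cleavage`; basic-linker
    fragments (the motif residues themselves) and fragments containing 'X'
    are never candidates.  The window is applied to the average mass.
    """
    lo, hi = mass_window_da
    candidates: list[PeptideCandidate] = []
    for frag in segment_by_cleavage(record.sequence, signal_call, motif_hits):
        if frag.is_linker or "X" in frag.sequence:
            continue
        avg = peptide_mass(frag.sequence, "average")
        if not (lo <= avg <= hi):
            continue
        mono = peptide_mass(frag.sequence, "monoisotopic")
        candidates.append(PeptideCandidate(
            parent_id=record.id, start=frag.start, end=frag.end,
            sequence=frag.sequence, n_flank=frag.n_flank, c_flank=frag.c_flank,
            average_mass_da=avg, monoisotopic_mass_da=mono))
    return candidates


def _candidate_masses(candidates) -> list[tuple[str, float]]:
    if isinstance(candidates, Mapping):
        return [(str(k), float(v)) for k, v in candidates.items()]
    out = []
    for c in candidates:
        out.append((f"{c.parent_id}:{c.start}-{c.end}", c.average_mass_da))
    return out


def match_masses(candidates: Sequence[PeptideCandidate] | Mapping[str, float],
                 peaks: MassSpectrumPeakList,
                 tolerance_da: float = DEFAULT_TOLERANCE_DA,
                 ) -> list[MassAssignment]:
    """Assign each candidate its nearest peak within ``tolerance_da``.

    ``candidates`` may be PeptideCandidate objects (matched on their
    predicted average mass) or a mapping of label -> predicted mass.  One
    peak may serve several candidates.  An empty peak list leaves every
    candidate unassigned.  Deltas are signed (observed - predicted).
    """
    assignments: list[MassAssignment] = []
    for label, predicted in _candidate_masses(candidates):
        best: float | None = None
        if peaks.peaks:
            best = min(peaks.peaks, key=lambda p: (abs(p - predicted), p))
        if best is not None and abs(best - predicted) <= tolerance_da:
            assignments.append(MassAssignment(candidate_id=label,
                                              predicted_mass_da=predicted,
                                              peak_mz=best,
                                              delta_da=best - predicted))
        else:
            assignments.append(MassAssignment(candidate_id=label,
                                              predicted_mass_da=predicted,
                                              peak_mz=None, delta_da=None))
    return assignments


def read_peak_list(path: str | os.PathLike, label: str = "") -> MassSpectrumPeakList:
    """Read peaks from plain text: one m/z per line, or two-column TSV
    (m/z, intensity; intensity ignored).  Blank lines and '#' comments skipped."""
    peaks: list[float] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            peaks.append(float(line.split()[0]))
    return MassSpectrumPeakList(peaks=tuple(sorted(peaks)),
                                label=label or os.path.basename(os.fspath(path)))
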