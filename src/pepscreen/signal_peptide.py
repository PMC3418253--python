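"""N-terminal secretion signal detection.

A von-Heijne-style interpretable detector: classical signal peptides carry a
short positively charged n-region, a 7–15 residue hydrophobic h-core, and a
c-region ending in small residues at the -3 and -1 positions relative to the
signal-peptidase cleavage site.  Each region contributes a component score in
[0, 1]; the combined score is a fixed weighted sum whose default operating
threshold is 0.45.

The combined score deliberately requires the hydrophobic core: with weights
0.5·h + 0.2·n + 0.3·c, a protein with no hydrophobic stretch can reach at
most 0.5 and only when both charge and cleavage-box evidence are perfect.
"""

from __future__ import annotations

from dataclasses import dataclass

from pepscreen.records import ProteinRecord

#: Kyte–Doolittle hydropathy; 'X' (unknown) scores 0 everywhere.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

#: Small residues favoured at the -3 and -1 positions of the cleavage box.
SMALL_RESIDUES = frozenset("AGSCT")

#: Fixed combination weights (h-core, n-charge, c-box).
WEIGHT_H, WEIGHT_N, WEIGHT_C = 0.5, 0.2, 0.3

#: Admissible cleavage positions (last signal residue), 1-based inclusive.
CLEAVAGE_MIN, CLEAVAGE_MAX = 10, 45

#: h-window search space: windows of 7–15 residues inside positions 1–35.
H_REGION_END = 35
H_WINDOW_MIN, H_WINDOW_MAX = 7, 15

#: Hydropathy scale maximum, used to rescale mean hydropathy into [0, 1].
_KD_MAX = 4.5

MIN_LENGTH = 15


@dataclass(frozen=True)
class SignalPeptideCall:
    """Outcome of signal-peptide prediction for one protein.

    ``cleavage_after`` is the 1-based position of the last signal-peptide
    residue and is meaningful only when ``present`` is true.  ``score`` is
    the fixed combination ``0.5·h + 0.2·n + 0.3·c`` of the component scores.
    """

    present: bool
    score: float
    cleavage_after: int | None
    n_score: float
    h_score: float
    c_score: float
    warning: str | None = None


def _h_score(seq: str) -> float:
    """Best mean hydropathy over 7–15 residue windows in positions 1–35, in [0,1]."""
    region = seq[:H_REGION_END]
    best = float("-inf")
    n = len(region)
    for width in range(H_WINDOW_MIN, H_WINDOW_MAX + 1):
        if width > n:
            break
        for start in range(0, n - width + 1):
            window = region[start:start + width]
            mean = sum(KYTE_DOOLITTLE[c] for c in window) / width
            best = max(best, mean)
    if best == float("-inf"):
        return 0.0
    return min(max(best / _KD_MAX, 0.0), 1.0)


def _n_score(seq: str) -> float:
    """1.0 when a positive residue (K/R) occurs in positions 1–5, else 0."""
    return 1.0 if any(c in "KR" for c in seq[:5]) else 0.0


def _c_profile(seq: str) -> list[tuple[int, float]]:
    """(position, c-score) for each admissible cleavage position.

    The c-score at position p averages the small-residue weights at p (the
    -1 residue) and p-2 (the -3 residue).
    """
    out = []
    hi = min(CLEAVAGE_MAX, len(seq))
    for p in range(CLEAVAGE_MIN, hi + 1):
        minus1 = seq[p - 1]
        minus3 = seq[p - 3]
        score = ((1.0 if minus1 in SMALL_RESIDUES else 0.0)
                 + (1.0 if minus3 in SMALL_RESIDUES else 0.0)) / 2.0
        out.append((p, score))
    return out


def predict_signal_peptide(record: ProteinRecord,
                           threshold: float = 0.45) -> SignalPeptideCall:
    """Score the N-terminus of ``record`` for a cleavable secretion signal.

    Deterministic.  ``present`` is true iff the combined score exceeds
    ``threshold``.  The predicted cleavage position is the admissible
    position (10–45) maximising the c-score, ties broken toward the smaller
    position.  Residues beyond position 60 never affect the call.  Sequences
    shorter than 15 residues yield ``present=False`` with score 0 and a
    warning flag rather than an error.
    """
    seq = record.sequence
    if len(seq) < MIN_LENGTH:
        return SignalPeptideCall(present=False, score=0.0, cleavage_after=None,
                                 n_score=0.0, h_score=0.0, c_score=0.0,
                                 warning="sequence shorter than 15 residues")
    h = _h_score(seq)
    n = _n_score(seq)
    profile = _c_profile(seq)
    best_pos, c = max(profile, key=lambda pc: (pc[1], -pc[0]))
    score = WEIGHT_H * h + WEIGHT_N * n + WEIGHT_C * c
    present = score > threshold
    return SignalPeptideCall(present=present, score=score,
                             cleavage_after=best_pos if present else None,
                             n_score=n, h_score=h, c_score=c)
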