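"""Transmembrane-segment detection via a hydrophobicity cross-correlation
profile with a numeric cutoff (default > 2.0).

The per-residue profile is the cross-correlation of the Kyte–Doolittle
hydropathy track with a symmetric trapezoidal 21-residue template (15-residue
flat core, 3-residue linear shoulders), expressed as a template-weighted mean
and normalised so that a 21-residue poly-leucine core in a hydrophilic
context peaks at 4.0 — placing the 2.0 operating cutoff mid-scale.  Calling
a segment means finding runs of above-cutoff positions at least 15 residues
long, after merging runs separated by fewer than 5 positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pepscreen.records import ProteinRecord
from pepscreen.signal_peptide import KYTE_DOOLITTLE, SignalPeptideCall

#: Template: 3-residue linear shoulders around a 15-residue flat core.
_SHOULDER = (0.25, 0.5, 0.75)
TEMPLATE = np.array(_SHOULDER + (1.0,) * 15 + _SHOULDER[::-1])
_HALF = len(TEMPLATE) // 2  # 10

#: Scale factor: poly-Leu (KD 3.8) weighted mean maps to a peak of 4.0.
_SCALE = 4.0 / 3.8

MIN_SEGMENT_LENGTH = 15
MERGE_GAP = 5


@dataclass(frozen=True)
class TMSegment:
    """A called transmembrane segment, 1-based inclusive coordinates."""

    start: int
    end: int
    peak_score: float

    def __len__(self) -> int:
        return self.end - self.start + 1


def das_profile(sequence: str) -> np.ndarray:
    """Per-residue hydrophobicity cross-correlation profile.

    ``profile[i]`` (0-based array for 1-based residue i+1) is the
    template-weighted mean hydropathy of the window centred on the residue,
    scaled by 4.0/3.8.  At the sequence ends the window shrinks to the
    in-bounds part and the weight normalisation shrinks with it, so the
    profile of a reversed sequence is the reverse of the profile.
    """
    kd = np.array([KYTE_DOOLITTLE[c] for c in sequence])
    n = len(kd)
    profile = np.empty(n)
    for i in range(n):
        lo = max(0, i - _HALF)
        hi = min(n, i + _HALF + 1)
        w = TEMPLATE[lo - (i - _HALF): hi - (i - _HALF)]
        profile[i] = _SCALE * float(np.dot(w, kd[lo:hi]) / w.sum())
    return profile


def detect_tm_segments(sequence: str, cutoff: float = 2.0) -> list[TMSegment]:
    """Call TM segments: above-cutoff runs, merged over gaps < 5, length >= 15.

    Returns non-overlapping segments sorted by start, each carrying the
    profile maximum inside it as ``peak_score``.
    """
    profile = das_profile(sequence)
    above = profile > cutoff
    runs: list[list[int]] = []  # [start0, end0] 0-based inclusive
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < MERGE_GAP:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    segments = []
    for s0, e0 in merged:
        if e0 - s0 + 1 >= MIN_SEGMENT_LENGTH:
            peak = float(profile[s0:e0 + 1].max())
            segments.append(TMSegment(start=s0 + 1, end=e0 + 1, peak_score=peak))
    return segments


def count_tm(record: ProteinRecord, signal_call: SignalPeptideCall | None,
             cutoff: float = 2.0) -> int:
    """Number of TM segments starting after the predicted signal peptide.

    Signal peptides are themselves hydrophobic; a segment whose start lies
    at or before the signal cleavage position is not counted as a TM.  With
    no signal call (or an absent signal) every segment counts.
    """
    segments = detect_tm_segments(record.sequence, cutoff=cutoff)
    if signal_call is not None and signal_call.present:
        boundary = signal_call.cleavage_after or 0
        segments = [s for s in segments if s.start > boundary]
    return len(segments)


def profile_tsv(sequence: str) -> str:
    """The profile as a two-column TSV (1-based position, score) for plotting."""
    lines = ["position\tscore"]
    for i, v in enumerate(das_profile(sequence), start=1):
        lines.append(f"{i}\t{v:.4f}")
    return "\n".join(lines) + "\n"
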