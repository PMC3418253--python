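"""Prohormone-convertase cleavage-motif scanning and proprotein segmentation.

Prohormone convertases (furin/PC family) cleave precursor proteins
C-terminal to basic residues, typically at dibasic lysine/arginine motifs.
The default motif set is {GKK, GRR, RKX, RRX, KR, RXKR, KXRR, RFGK}, where
'X' matches any of the 20 standard residues (never the unknown residue 'X',
which must not create cleavage evidence).

Segmentation treats each motif occurrence as an excised linker: the mature
fragments are the intervals between the signal-peptide cleavage point and
the motif boundaries, so a core peptide flanked by KR and GRR is returned
without its basic flanks — matching how convertase cleavage followed by
carboxypeptidase trimming releases mature peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from pepscreen.records import STANDARD_RESIDUES
from pepscreen.signal_peptide import SignalPeptideCall

#: The default convertase motif set, in scan order.
DEFAULT_MOTIFS: tuple[str, ...] = (
    "GKK", "GRR", "RKX", "RRX", "KR", "RXKR", "KXRR", "RFGK",
)

_WILDCARD = "X"


@dataclass(frozen=True)
class CleavageMotifHit:
    """One motif occurrence; coordinates 1-based inclusive.

    ``cleavage_after`` is the position of the last basic residue (K/R)
    within the match — the residue C-terminal to which the convertase cuts.
    """

    motif: str
    match_start: int
    match_end: int
    cleavage_after: int

    def __len__(self) -> int:
        return self.match_end - self.match_start + 1


@dataclass(frozen=True)
class Fragment:
    """A maximal interval between consecutive cut points, 1-based inclusive.

    ``n_flank`` / ``c_flank`` name the evidence at each boundary: a motif
    pattern, ``"signal"`` or ``"terminus"``.  ``is_linker`` marks fragments
    lying inside a motif match (the excised basic linker itself).
    """

    start: int
    end: int
    sequence: str
    n_flank: str
    c_flank: str
    is_linker: bool = False

    def __len__(self) -> int:
        return self.end - self.start + 1


def _pattern_matches(pattern: str, window: str) -> bool:
    if len(pattern) != len(window):
        return False
    for p, c in zip(pattern, window):
        if p == _WILDCARD:
            if c not in STANDARD_RESIDUES:  # unknown 'X' never matches
                return False
        elif c != p:
            return False
    return True


def scan_convertase_motifs(sequence: str,
                           motif_set: Sequence[str] = DEFAULT_MOTIFS,
                           ) -> list[CleavageMotifHit]:
    """Report every occurrence of every motif, including overlaps.

    Hits are sorted by (match_start, motif length descending).  A motif with
    no basic residue in its concrete match is impossible with the default
    set (every pattern fixes at least one K/R).
    """
    for motif in motif_set:
        if not motif or not (2 <= len(motif) <= 4):
            raise ValueError(f"motif {motif!r}: patterns must be 2-4 residues")
    hits: list[CleavageMotifHit] = []
    n = len(sequence)
    for start0 in range(n):
        for motif in motif_set:
            m = len(motif)
            window = sequence[start0:start0 + m]
            if len(window) < m or not _pattern_matches(motif, window):
                continue
            last_basic = max((i for i, c in enumerate(window) if c in "KR"),
                             default=None)
            if last_basic is None:
                continue
            hits.append(CleavageMotifHit(
                motif=motif,
                match_start=start0 + 1,
                match_end=start0 + m,
                cleavage_after=start0 + last_basic + 1,
            ))
    hits.sort(key=lambda h: (h.match_start, -len(h.motif)))
    return hits


def segment_by_cleavage(sequence: str,
                        signal_call: SignalPeptideCall | None,
                        hits: Iterable[CleavageMotifHit]) -> list[Fragment]:
    """Split a proprotein at signal and convertase cut points.

    Cut points (positions after which the chain is cut) are the signal
    cleavage position (when present), and for each motif hit both
    ``match_start - 1`` and ``cleavage_after`` — so the basic linker becomes
    its own fragment and the flanked mature peptide carries no motif
    residues.  Fragments tile the sequence exactly.
    """
    n = len(sequence)
    cuts: dict[int, str] = {}  # cut position -> evidence label

    def add_cut(pos: int, label: str) -> None:
        if pos < 0 or pos > n:
            raise ValueError(f"cut point {pos} outside sequence of length {n}")
        if 0 < pos < n and pos not in cuts:
            cuts[pos] = label

    if signal_call is not None and signal_call.present:
        add_cut(signal_call.cleavage_after, "signal")
    hits = sorted(hits, key=lambda h: (h.match_start, -len(h.motif)))
    for hit in hits:
        add_cut(hit.match_start - 1, hit.motif)
        add_cut(hit.cleavage_after, hit.motif)

    linker_cover = [False] * (n + 1)
    for hit in hits:
        for p in range(hit.match_start, hit.cleavage_after + 1):
            linker_cover[p] = True

    boundaries = sorted(cuts)
    fragments: list[Fragment] = []
    prev = 0
    prev_label = "terminus"
    for cut in boundaries + [n]:
        label = cuts.get(cut, "terminus")
        start, end = prev + 1, cut
        frag_seq = sequence[start - 1:end]
        is_linker = all(linker_cover[p] for p in range(start, end + 1))
        fragments.append(Fragment(start=start, end=end, sequence=frag_seq,
                                  n_flank=prev_label, c_flank=label,
                                  is_linker=is_linker))
        prev = cut
        prev_label = label
    return fragments
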