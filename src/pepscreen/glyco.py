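"""N-glycosylation sequon scanning and the heavy-glycosylation rule.

N-linked glycosylation requires the sequon N-X-[S/T] with X != P.  Each
sequon receives a deterministic potential in [0, 1]: a 0.5 base, +0.25 for a
threonine sequon (N-X-T is the stronger acceptor), and +0.25 weighted by the
fraction of small/polar residues in the +/-4 window around the asparagine —
a surface-accessibility proxy (buried hydrophobic context lowers the chance
the oligosaccharyltransferase reaches the site).  Candidate regions whose
high-potential site count exceeds a maximum are "heavily glycosylated" and
eliminated from the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

#: Small/polar residues used as the accessibility proxy.
SMALL_POLAR = frozenset("AGSTCNQDE")

DEFAULT_POTENTIAL_THRESHOLD = 0.6
DEFAULT_MAX_SITES = 2


@dataclass(frozen=True)
class GlycoSite:
    """One N-glycosylation sequon; ``asn_position`` is 1-based."""

    asn_position: int
    sequon: str
    potential: float


def scan_sequons(sequence: str) -> list[GlycoSite]:
    """All N-X-[S/T] (X != P) sequons with their potentials, in order."""
    sites: list[GlycoSite] = []
    n = len(sequence)
    for i0 in range(n - 2):
        if sequence[i0] != "N":
            continue
        x, third = sequence[i0 + 1], sequence[i0 + 2]
        if x == "P" or third not in "ST":
            continue
        lo = max(0, i0 - 4)
        hi = min(n, i0 + 5)
        context = sequence[lo:hi]
        accessibility = sum(c in SMALL_POLAR for c in context) / len(context)
        potential = 0.5 + 0.25 * (1.0 if third == "T" else 0.0) + 0.25 * accessibility
        sites.append(GlycoSite(asn_position=i0 + 1,
                               sequon=sequence[i0:i0 + 3],
                               potential=min(potential, 1.0)))
    return sites


def is_heavily_glycosylated(fragment: str,
                            threshold_potential: float = DEFAULT_POTENTIAL_THRESHOLD,
                            max_sites: int = DEFAULT_MAX_SITES) -> bool:
    """True iff the fragment has more than ``max_sites`` sites above threshold."""
    strong = [s for s in scan_sequons(fragment) if s.potential > threshold_potential]
    return len(strong) > max_sites
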