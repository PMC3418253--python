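"""Deterministic synthetic proteomes with planted propeptides and decoys.

Everything here is synthetic test/demo material.  The generator emulates the
anatomy of a secreted-peptide precursor: an N-terminal signal peptide
(charged n-region, hydrophobic h-core, A-x-A cleavage box), a convertase
motif, a hydrophilic core peptide (default 49 residues), a second convertase
motif, a hydrophilic pro-domain spacer, an optional 25-residue Leu-rich
transmembrane segment and a short tail — 319 residues in total by default,
the size of the precursor the screen is modelled on.  Decoys are built to
fail exactly one cascade stage while passing all earlier ones.

Cores and spacers are drawn from a hydrophilic alphabet containing no K, R
or N, so no convertase motif or glycosylation sequon can arise by accident
(every default motif fixes a K or R; a sequon needs N); sequons are planted
explicitly where a decoy requires them.  Orthologs are emulated by seeded
point substitution from the same alphabet, so the realised ungapped identity
is exact and no protected feature can be destroyed or created.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pepscreen.convertase import DEFAULT_MOTIFS, scan_convertase_motifs
from pepscreen.records import (
    NucleotideRecord,
    ProteinRecord,
    translate_longest_orf,
    write_fasta,
)

#: Hydrophilic residues free of motif- and sequon-forming letters (no K/R/N).
CORE_ALPHABET = "ASTQEDGHP"
#: Hydrophobic residues for h-regions and TM segments.
HYDROPHOBIC_ALPHABET = "LLLIV"  # Leu-rich

TM_LENGTH = 25
DEFAULT_TOTAL_LENGTH = 319
DEFAULT_CORE_LENGTH = 49
TAIL_LENGTH = 12

DECOY_KINDS = ("no_signal", "multi_tm", "heavy_glyco", "non_conserved",
               "well_annotated")

_HYPOTHETICAL = "hypothetical protein"


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one planted proprotein.

    ``target_identity`` is the per-ortholog ungapped identity used when the
    corpus builder emulates other species.
    """

    signal_length: int = 22
    core_length: int = DEFAULT_CORE_LENGTH
    n_flank_motif: str = "KR"
    c_flank_motif: str = "GRR"
    tm_present: bool = True
    target_identity: float = 0.85
    total_length: int = DEFAULT_TOTAL_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if not (15 <= self.signal_length <= 30):
            raise ValueError("signal_length must be in [15, 30]")
        if self.core_length < 10:
            raise ValueError("core_length too small")
        if not (0 < self.target_identity <= 1):
            raise ValueError("target_identity must be in (0, 1]")
        for motif in (self.n_flank_motif, self.c_flank_motif):
            if motif not in DEFAULT_MOTIFS:
                raise ValueError(f"flank motif {motif!r} not in the default set")


@dataclass(frozen=True)
class PlantLayout:
    """1-based inclusive coordinates of the planted features.

    ``extra_protected`` carries decoy-defining ranges (a second TM block,
    planted sequons) that ortholog mutation must also leave untouched.
    """

    signal: tuple[int, int]
    n_flank: tuple[int, int]
    core: tuple[int, int]
    c_flank: tuple[int, int]
    tm: tuple[int, int] | None
    extra_protected: tuple[tuple[int, int], ...] = ()

    def protected_ranges(self) -> tuple[tuple[int, int], ...]:
        out = [self.signal, self.n_flank, self.c_flank]
        if self.tm is not None:
            out.append(self.tm)
        out.extend(self.extra_protected)
        return tuple(out)


def _random_run(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _signal(rng: np.random.Generator, length: int) -> str:
    """M + charged n-region + hydrophobic h-core + A-Q-A cleavage box."""
    h_len = length - 6
    charged = "".join(rng.choice(["K", "R"], size=2))
    return "M" + charged + _random_run(rng, HYDROPHOBIC_ALPHABET, h_len) + "AQA"


def generate_proprotein(spec: PlantSpec, record_id: str = "plant",
                        description: str = _HYPOTHETICAL,
                        ) -> tuple[ProteinRecord, PlantLayout]:
    """Build one planted proprotein; deterministic given ``spec.seed``.

    Rejection sampling keeps the core/spacer free of accidental motif hits
    outside the planted flanks (with the motif-free alphabet this converges
    immediately; the loop guards custom alphabets).
    """
    rng = np.random.default_rng(spec.seed)
    sl = spec.signal_length
    tm_len = TM_LENGTH if spec.tm_present else 0
    fixed = sl + len(spec.n_flank_motif) + spec.core_length \
        + len(spec.c_flank_motif) + tm_len + TAIL_LENGTH
    spacer_len = spec.total_length - fixed
    if spacer_len < 0:
        raise ValueError("total_length too small for the requested layout")

    n_flank_len = len(spec.n_flank_motif)
    c_flank_len = len(spec.c_flank_motif)
    core_start = sl + n_flank_len + 1
    core_end = core_start + spec.core_length - 1
    c_start = core_end + 1
    c_end = c_start + c_flank_len - 1
    tm_start = c_end + spacer_len + 1
    layout = PlantLayout(
        signal=(1, sl),
        n_flank=(sl + 1, sl + n_flank_len),
        core=(core_start, core_end),
        c_flank=(c_start, c_end),
        tm=(tm_start, tm_start + tm_len - 1) if spec.tm_present else None,
    )
    for _ in range(100):
        core = _random_run(rng, CORE_ALPHABET, spec.core_length)
        spacer = _random_run(rng, CORE_ALPHABET, spacer_len)
        tail = _random_run(rng, CORE_ALPHABET, TAIL_LENGTH)
        tm = _random_run(rng, HYDROPHOBIC_ALPHABET, tm_len)
        seq = (_signal(rng, sl) + spec.n_flank_motif + core
               + spec.c_flank_motif + spacer + tm + tail)
        # no stray motifs inside the core (planted flanks aside)
        if not scan_convertase_motifs(core):
            record = ProteinRecord(id=record_id, sequence=seq,
                                   description=description)
            return record, layout
    raise ValueError("could not generate a motif-free core in 100 attempts")


def mutate_to_identity(record: ProteinRecord, target_identity: float,
                       seed: int,
                       protected_ranges: Sequence[tuple[int, int]] = (),
                       ) -> ProteinRecord:
    """Emulate an ortholog by seeded point substitution.

    Substitutes exactly ``round((1 - target_identity) * length)`` positions,
    chosen without replacement, preferring positions outside the protected
    (1-based inclusive) ranges; replacement residues come from the
    hydrophilic motif-free alphabet, always differing from the original, so
    the realised ungapped identity is exact.
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity < 0.2:
        raise ValueError("target_identity below 0.2 refused: "
                         "alignment gating becomes meaningless")
    rng = np.random.default_rng(seed)
    n = len(record.sequence)
    k = round((1.0 - target_identity) * n)
    protected = set()
    for lo, hi in protected_ranges:
        protected.update(range(lo - 1, hi))  # to 0-based
    free = [i for i in range(n) if i not in protected]
    if k <= len(free):
        chosen = rng.choice(free, size=k, replace=False)
    else:
        spill = rng.choice(sorted(protected), size=k - len(free), replace=False)
        chosen = np.concatenate([np.array(free, dtype=int), spill])
    seq = list(record.sequence)
    for i in sorted(int(i) for i in chosen):
        options = [c for c in CORE_ALPHABET if c != seq[i]]
        seq[i] = str(rng.choice(options))
    return ProteinRecord(id=record.id, sequence="".join(seq),
                         description=record.description, species=record.species)


def generate_decoy(kind: str, seed: int) -> tuple[ProteinRecord, PlantLayout]:
    """A decoy constructed to fail exactly the named cascade stage."""
    if kind not in DECOY_KINDS:
        raise ValueError(f"unrecognized decoy kind {kind!r}")
    spec = PlantSpec(tm_present=False, seed=seed)
    rec_id = f"decoy_{kind}"

    if kind == "no_signal":
        record, layout = generate_proprotein(spec, rec_id)
        rng = np.random.default_rng(seed + 1)
        # hydrophilic N-terminus, no K/R in the first residues: no h-core,
        # no n-charge -> combined signal score bounded well below 0.45
        sl = spec.signal_length
        new_nterm = "M" + _random_run(rng, "DEQSTG", sl - 1)
        seq = new_nterm + record.sequence[sl:]
        return ProteinRecord(id=rec_id, sequence=seq,
                             description=_HYPOTHETICAL), layout

    if kind == "well_annotated":
        record, layout = generate_proprotein(spec, rec_id,
                                             description="serum albumin precursor")
        return record, layout

    if kind == "multi_tm":
        record, layout = generate_proprotein(
            PlantSpec(tm_present=True, seed=seed), rec_id)
        # plant a second TM inside the spacer, 30 residues upstream of the first
        tm_start, tm_end = layout.tm
        second_start = tm_start - TM_LENGTH - 30
        rng = np.random.default_rng(seed + 2)
        tm2 = _random_run(rng, HYDROPHOBIC_ALPHABET, TM_LENGTH)
        seq = (record.sequence[:second_start - 1] + tm2
               + record.sequence[second_start - 1 + TM_LENGTH:])
        layout = replace(layout, extra_protected=(
            (second_start, second_start + TM_LENGTH - 1),))
        return ProteinRecord(id=rec_id, sequence=seq,
                             description=_HYPOTHETICAL), layout

    if kind == "heavy_glyco":
        record, layout = generate_proprotein(spec, rec_id)
        core_lo, core_hi = layout.core
        seq = list(record.sequence)
        # three N-G-T sequons spaced through the core: each potential > 0.6
        protected = []
        for offset in (4, 20, 36):
            pos = core_lo - 1 + offset
            seq[pos:pos + 3] = list("NGT")
            protected.append((pos + 1, pos + 3))
        layout = replace(layout, extra_protected=tuple(protected))
        return ProteinRecord(id=rec_id, sequence="".join(seq),
                             description=_HYPOTHETICAL), layout

    # non_conserved: the architecture is fine; the corpus builder mutates its
    # orthologs down to ~35% identity so the homology gate eliminates it.
    record, layout = generate_proprotein(spec, rec_id)
    return record, layout


def generate_corpus(seed: int,
                    species: Sequence[str] = ("mouse", "rat", "human"),
                    n_planted: int = 1,
                    decoy_kinds: Sequence[str] = DECOY_KINDS,
                    target_identity: float = 0.85,
                    non_conserved_identity: float = 0.35,
                    ) -> tuple[dict[str, list[ProteinRecord]], pd.DataFrame]:
    """A multi-species corpus of planted proproteins and decoys.

    The first species is the reference; every record has an ortholog in each
    other species (decoy-defining features protected during mutation;
    ``non_conserved`` orthologs are mutated to ``non_conserved_identity``).
    Record ids follow the ``<base>_<species>`` suffix convention the screen
    uses for ortholog pairing.  Returns the corpus and a truth table
    (base id, kind, planted coordinates).
    """
    if not species:
        raise ValueError("at least one species required")
    corpus: dict[str, list[ProteinRecord]] = {sp: [] for sp in species}
    truth_rows = []
    ref = species[0]

    def add_family(base: str, record: ProteinRecord, layout: PlantLayout,
                   kind: str, identity: float) -> None:
        corpus[ref].append(
            ProteinRecord(id=f"{base}_{ref}", sequence=record.sequence,
                          description=record.description, species=ref))
        for j, sp in enumerate(species[1:], start=1):
            ortho = mutate_to_identity(
                record, identity, seed=_subseed(seed, base, j),
                protected_ranges=layout.protected_ranges())
            corpus[sp].append(
                ProteinRecord(id=f"{base}_{sp}", sequence=ortho.sequence,
                              description=record.description, species=sp))
        lo, hi = layout.core
        truth_rows.append({"base_id": base, "kind": kind,
                           "core_start": lo, "core_end": hi,
                           "target_identity": identity})

    for i in range(n_planted):
        spec = PlantSpec(target_identity=target_identity,
                         seed=_subseed(seed, "plant", i))
        record, layout = generate_proprotein(spec, record_id=f"plant{i}")
        add_family(f"plant{i}", record, layout, "planted", target_identity)

    for kind in decoy_kinds:
        record, layout = generate_decoy(kind, seed=_subseed(seed, kind, 0))
        identity = non_conserved_identity if kind == "non_conserved" \
            else target_identity
        add_family(f"decoy_{kind}", record, layout, kind, identity)

    truth = pd.DataFrame(truth_rows)
    return corpus, truth


#: no ATG; 3' UTR carries stop codons in all three frames.
_UTR5 = "GGCAGGCC"
_UTR3 = "CTAG" * 6


def encode_cdna(record: ProteinRecord, seed: int = 0) -> NucleotideRecord:
    """Back-translate a protein into a synthetic full-length cDNA.

    Codons are drawn per residue (seeded) from the standard genetic code;
    the construct is 5' UTR + ATG-initiated CDS + stop + stop-rich 3' UTR
    and is re-drawn until its longest open reading frame is exactly the CDS
    (random synonymous choice makes frame-shifted ORFs terminate quickly).
    """
    from Bio.Data.CodonTable import standard_dna_table

    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(standard_dna_table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    rng = np.random.default_rng(seed)
    for _ in range(20):
        cds = "".join(str(rng.choice(by_aa[aa])) for aa in record.sequence)
        nt = NucleotideRecord(id=f"{record.id}_cdna",
                              sequence=_UTR5 + cds + "TAA" + _UTR3,
                              description=f"synthetic cDNA of {record.id}")
        if translate_longest_orf(nt).sequence == record.sequence:
            return nt
    raise ValueError("could not build a cDNA whose longest ORF is the CDS")


def _subseed(seed: int, tag: str, index: int) -> int:
    """A stable derived seed below 2**31."""
    h = 2166136261
    for ch in f"{seed}:{tag}:{index}":
        h = ((h ^ ord(ch)) * 16777619) % 2**32
    return h % (2**31 - 1)


def write_corpus(corpus: Mapping[str, Sequence[ProteinRecord]],
                 truth: pd.DataFrame, outdir: str) -> None:
    """Write one multi-FASTA per species plus the truth table TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for sp, records in corpus.items():
        write_fasta(records, os.path.join(outdir, f"{sp}.faa"))
    truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
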