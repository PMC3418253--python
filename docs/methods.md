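# Methods

`pepscreen` implements a thresholded, staged screen for secreted-peptide
precursors, together with the downstream steps used to verify a prediction:
propeptide excision, mass prediction and MALDI peak assignment.  This note
records the models behind each stage, the defaults and why they were
chosen, what the synthetic fixtures do and do not emulate, and the known
limitations.  Coordinates everywhere are 1-based and inclusive.

## Signal-peptide detection

Classical cleavable signal peptides are ~15–30 residues with three regions:
a short positively charged n-region, a hydrophobic h-core and a polar
c-region ending in small residues at −3 and −1 relative to the signal
peptidase site.  The detector scores each region separately:

- **h** — the maximum mean Kyte–Doolittle hydropathy over all windows of
  7–15 residues inside positions 1–35, divided by 4.5 (the scale maximum)
  and clipped to [0,1].  Any monotone rescaling preserves the detector's
  ordering; this one puts a poly-Leu core at ≈0.84.
- **n** — 1 if K or R occurs in positions 1–5, else 0.
- **c** — at each admissible cleavage position p in 10–45, the mean of two
  indicator weights: residue p (the −1 position) and residue p−2 (the −3
  position) each score 1 when in {A,G,S,C,T}.  The predicted cleavage
  position is the argmax, ties broken toward the smaller position.

The combined score is the fixed convex-like combination
`0.5·h + 0.2·n + 0.3·c`; a record is called signal-bearing when the score
exceeds the configured threshold (default 0.45, the conventional operating
point for a discrimination score on this task).  The weights make the
hydrophobic core necessary: with h = 0 the score cannot exceed 0.5, and only
reaches it with perfect charge and cleavage-box evidence.  Residues beyond
position 60 can never affect the call (all component windows end by
position 45).  Sequences shorter than 15 residues return an absent call
with a warning flag rather than an error, since screening corpora contain
fragments.

This is a deliberately interpretable detector, not a reimplementation of
any neural-network predictor; it preserves the decision semantics of a
signal-peptide gate with a 0.45 cutoff, and the fixture suite verifies that
planted signal peptides score above and hydrophilic N-termini score below
that point.  Signal-anchor versus cleaved-signal discrimination and
organism-specific model variants are out of scope.

## Transmembrane segments

The per-residue profile is a cross-correlation of the Kyte–Doolittle track
with a symmetric trapezoidal 21-residue template (15-residue flat core,
3-residue linear shoulders, weights 0.25/0.5/0.75), computed as a
template-weighted mean and multiplied by 4.0/3.8 so that a 21-residue
poly-leucine stretch in a hydrophilic context peaks at exactly 4.0.  That
normalisation places the conventional cutoff of 2.0 mid-scale: a segment
must sustain a weighted-mean hydropathy of ≈1.9 to be called.  At sequence
ends the window shrinks and the weight normalisation shrinks with it, which
keeps the profile of a reversed sequence equal to the reversed profile.

Segments are maximal runs of above-cutoff positions, merged across gaps
shorter than 5 positions, and retained when at least 15 residues long —
the minimum span of a membrane-crossing helix.  `count_tm` excludes
segments starting at or before the predicted signal cleavage position,
because a signal peptide is itself hydrophobic and must not be
double-counted as a TM domain.

The screen's TM rule eliminates records with ≥ 2 TM segments.  For a lone
TM segment two readings are implemented behind `tm_rule_reading`:
`"single"` (default) additionally eliminates single-TM records lacking any
convertase motif; `"signal"` eliminates records whose signal region
doubles as a TM anchor and that lack a motif.  The default reading reflects
the biological rationale that a peptide can be proteolytically released
from a single-pass membrane precursor only if cleavage motifs exist.
Membrane topology (in/out orientation) is not modelled.

## Convertase motif scanning and segmentation

Prohormone convertases cleave C-terminal to basic residues at
lysine/arginine-patterned motifs.  The default motif set is
`GKK, GRR, RKX, RRX, KR, RXKR, KXRR, RFGK`, where X matches any of the 20
standard residues but never the unknown residue 'X' (unknowns must not
create cleavage evidence).  The set is user-extensible in the
configuration, since dibasic motifs are a family rather than a closed list.
Every occurrence of every motif is reported, including overlapping and
nested matches, sorted by start position then motif length descending;
`cleavage_after` is the position of the last K/R within the match (the
furin/PC convention of cutting after the basic residues).

Segmentation treats each motif occurrence as an excised linker: cut points
are the signal cleavage position plus, for each hit, both the position
before the match and the position after its last basic residue.  The basic
linker therefore becomes its own fragment (flagged `is_linker`) and a core
peptide flanked by, say, KR and GRR is returned without motif residues —
mirroring convertase cleavage followed by carboxypeptidase trimming of the
exposed basic residues.  Fragments tile the parent sequence exactly; each
carries its N- and C-flank evidence (motif pattern, `signal` or
`terminus`).

## N-glycosylation

Sites are N-X-[S/T] sequons with X ≠ P.  Each receives a deterministic
potential: 0.5 base, +0.25 for a threonine acceptor (N-X-T is the stronger
sequon), +0.25 times the fraction of small/polar residues
({A,G,S,T,C,N,Q,D,E}) in the ±4 window around the asparagine — a simple
surface-accessibility proxy — clamped to [0,1].  A candidate region is
"heavily glycosylated" when more than `glyco_max_sites` (default 2) sites
exceed the potential threshold (default 0.6).  "Heavy" has no standard
quantitative definition; more than two strong sites on a ≤10 kDa peptide
region was fixed as the default and is configurable and logged in every
report.  By default the rule is applied to the excised candidate peptides
(`glyco_scope = "peptide"`); a whole-protein mode exists for corpora where
peptide boundaries are unreliable.  A record is eliminated only when it has
at least one excised candidate and all of them are heavy — a record with no
candidate in the mass window is not vacuously eliminated, which keeps the
cascade monotone under threshold relaxation.  O-glycosylation is not
modelled.

## Homology

Conservation is operationalised as global pairwise alignment
(Needleman–Wunsch with affine gaps) under BLOSUM62 with gap penalties
10 (open) / 0.5 (extend) — the EMBOSS-needle defaults.  Percent identity is
identical columns over all alignment columns, gaps included in the
denominator; a `"shorter"`-sequence denominator is available by
configuration.  Percent similarity additionally counts Clustal strong-group
substitutions; per-column classes use the Clustal convention
(`*` identity, `:` strong group, `.` weak group, space otherwise; gap
columns are never conserved).  The gate passes when the minimum pairwise
identity against orthologs in every other required species exceeds the
threshold (default 50%); a missing ortholog counts as identity 0.  Ortholog
pairing uses the `<base>_<species>` record-id suffix convention, documented
at the CLI.  Alignment itself is delegated to Biopython's
`PairwiseAligner`; the test suite checks its optimal scores against an
exhaustive enumeration of all affine-gap alignments on short sequences.

## Masses and MALDI assignment

Residue masses are computed from residue elemental compositions and two
atomic-mass sets: monoisotopic (lightest isotope) and average (standard
atomic weights), with a peptide's mass being the residue sum plus one
water.  The reported "predicted molecular weight" convention is the
**average** mass: linear-mode MALDI-TOF does not resolve the isotope
envelope of a ~5.8 kDa peptide, so observed peaks track the average [M+H]+
mass.  That is also why the default match tolerance is 5 Da and observed −
predicted deltas of about +1 to +3 Da are expected (protonation plus matrix
adducts).  Assignment is nearest-peak within tolerance; one peak may serve
several candidates; deltas are signed.  Candidate excision applies the
default 3–10 kDa window — the size window enforced experimentally by
centrifugal filtration of culture media — to the average mass of every
non-linker fragment.  Post-translational modification masses (glycans,
etc.) are not modelled; an endogenous peptide can therefore run heavier
than its prediction.

The test suite pins the mass table against an independent
atomic-composition oracle (pyteomics, elemental formula of the whole
peptide) to 1e-4 Da monoisotopic and 0.02 Da average on random peptides.

## Scoring and ranking

Five stage scores, each in [0,1]: the signal score; convertase cleavage
density `min(1, distinct cleavage points downstream / 4)` (mature
proproteins typically carry 2–4 processing sites); TM penalty
`max(0, 1 − count/2)`; glycosylation `1 − heavy fraction`; homology
`min pairwise identity / 100`.  The combined score is their weighted mean
(equal weights by default, configurable).  Survivors are ranked by combined
score descending with record-id tiebreak, making reports byte-deterministic
for a fixed corpus and configuration.  The per-stage score normalisations
are declared conventions of this package: staged screens of this kind rank
"according to the score assigned from each step" without a canonical
numeric definition.

## Synthetic fixtures

The generator plants precursors with the full anatomy the screen targets:
M + charged n-region + Leu-rich h-core + A-Q-A cleavage box (signal, 22
residues by default), an N-flank motif (KR), a 49-residue hydrophilic core
peptide, a C-flank motif (GRR), a hydrophilic pro-domain spacer, an
optional 25-residue Leu-rich TM segment and a short tail — 319 residues in
total by default, matching the precursor/peptide sizes the pipeline is
modelled on.  Cores and spacers are drawn from a hydrophilic alphabet with
no K, R or N, so convertase motifs and sequons cannot arise by accident
(every default motif fixes a K or R; sequons need N); a rejection-sampling
guard re-draws the core if a custom alphabet ever produces a stray motif.

Decoys fail exactly one stage while passing all earlier ones: a
hydrophilic N-terminus (no signal), a well-annotated description, a second
planted TM block, three planted N-G-T sequons in the core, or orthologs
mutated to ~35% identity.  Orthologs are emulated by seeded point
substitution of exactly `round((1 − identity)·length)` positions, chosen
outside protected feature ranges and replaced from the same motif-free
alphabet — realised ungapped identity is exact to one residue, and
planted/decoy-defining features cannot be created or destroyed.  The
default planted family uses 85% target identity across three species
(comfortably above the 50% gate); the four-species conservation
demonstration uses 92%, because two orthologs mutated independently at rate
1−t share ≈ t² identity with each other (0.92² ≈ 85%), keeping all pairs
above the 80% conservation level that motivates the demonstration.

A back-translation helper emits synthetic full-length cDNAs (5' UTR, seeded
synonymous codon choice, stop, stop-rich 3' UTR) re-drawn until the longest
ATG-initiated forward-strand ORF is exactly the coding sequence, so the
ORF-translation entry point is testable without downloads.

What the fixtures do **not** emulate: realistic proteome length and
composition distributions, nucleotide-level evolution (orthologs differ
only by substitutions, never indels), paralogy, alternative splicing, or
annotation noise.  Passing the fixture suite therefore demonstrates that
the cascade's decision logic and bookkeeping are correct — not that the
thresholds would achieve any particular sensitivity/specificity on a real
proteome snapshot, whose candidate counts also depend on the database
vintage.

## Numerical and degenerate-input choices

- Ties: cleavage-box argmax toward the smaller position; motif hits sorted
  by (start, length descending); ranking tiebreak by record id; ORF ties by
  smallest start.
- 'X' (unknown residue): hydropathy 0, never matches a motif wildcard, has
  no defined mass (fragments containing X are never mass candidates).
- Short sequences: signal prediction warns instead of erroring below 15
  residues; profiles of short sequences shrink their windows at the ends.
- Empty corpus: an empty result with zero counts, not an error; a missing
  required species or duplicate record id is an error.
- All randomness (fixtures only — the screen itself is deterministic) flows
  through seeded NumPy generators; derived seeds stay below 2³¹.

## Problem sizes in the shipped checks

The bundled tests and the acceptance script run entirely on generated
corpora: 18-record three-species corpora for end-to-end checks, 20 corpus
seeds for the recovery rate, 100 random configurations for cascade
monotonicity, 1,000 random sequences for the motif-scanner oracle and
exhaustive alignment enumeration up to length 8.  These sizes exercise
every code path while keeping the whole suite under a minute on one CPU.
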