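# pepscreen

An in-silico screen for novel secreted bioactive peptides (neuropeptide-like
precursors) in multi-species protein corpora, for computational biologists
who want a transparent, fully scriptable version of the classic
secretome-mining recipe.

Peptide hormones and neuropeptides are released from larger precursor
proteins that share a recognisable anatomy: an N-terminal signal peptide
that routes the protein into the secretory pathway, prohormone-convertase
cleavage motifs (dibasic K/R patterns) that flank the mature peptide, at
most a single transmembrane segment, little N-glycosylation on the peptide
region, and strong cross-species conservation. `pepscreen` turns each of
those features into an explicit, thresholded stage and runs them as a
cascade:

1. **Signal peptide** — an interpretable von-Heijne-style detector.  The
   score combines an h-region term (best mean Kyte–Doolittle hydropathy over
   7–15-residue windows in positions 1–35, rescaled to [0,1]), an n-region
   charge term (K/R in positions 1–5) and a (−3,−1) small-residue cleavage
   box term: `score = 0.5·h + 0.2·n + 0.3·c`, operating threshold 0.45.
2. **Annotation filter** — keep poorly annotated records (descriptions
   matching `hypothetical`, `uncharacterized`, `Rik`, `open reading frame`).
3. **Convertase motifs** — scan for `GKK, GRR, RKX, RRX, KR, RXKR, KXRR,
   RFGK` (X = any standard residue) downstream of the signal peptide;
   cleavage is placed C-terminal to the last basic residue of a match.
4. **Transmembrane rule** — a DAS-style hydrophobicity cross-correlation
   profile (21-residue trapezoidal template, cutoff > 2.0, minimum segment
   15 residues) counts TM segments outside the signal region; two or more
   eliminate the record, and a lone TM is tolerated only alongside
   convertase motifs (peptides can be proteolytically released from
   membrane-anchored precursors).
5. **Glycosylation** — N-X-[S/T] (X≠P) sequons receive a deterministic
   potential in [0,1]; candidate peptide regions with more than 2 sites
   above 0.6 are "heavily glycosylated" and eliminated.
6. **Homology** — global Needleman–Wunsch alignment (BLOSUM62, gap open 10 /
   extend 0.5) against orthologs in the other species; the minimum pairwise
   percent identity must exceed 50%.

Survivors are scored (weighted mean of the five normalised stage scores)
and ranked.  The package also excises the convertase-flanked candidate
peptides, predicts their average and monoisotopic masses from residue
elemental compositions, and assigns predictions to observed MALDI-TOF m/z
peak lists — the standard way secretion of a predicted peptide is verified
in culture media.

A deterministic fixture generator (`pepscreen.synthetic`) builds
multi-species corpora with planted precursors — 319-residue proproteins
carrying a 49-residue convertase-flanked core peptide and an optional
C-terminal TM segment — among stage-specific decoys, so the whole cascade is
testable without downloading any database.

## Worked example

Generate a three-species corpus (1 planted conserved precursor family + 5
decoy families) and screen it:

```bash
pepscreen fixtures --seed 17 --out fixtures
pepscreen run --species mouse=fixtures/mouse.faa \
              --species rat=fixtures/rat.faa \
              --species human=fixtures/human.faa --out results
```

stderr reports the survivor count after each stage:

```
[pepscreen] input: 18
[pepscreen] signal_peptide: 15     # no-signal decoys eliminated
[pepscreen] annotation: 12         # well-annotated decoys eliminated
[pepscreen] convertase: 12
[pepscreen] tm: 9                  # multi-TM decoys eliminated
[pepscreen] glycosylation: 6       # heavily glycosylated decoys eliminated
[pepscreen] homology: 3            # non-conserved decoys eliminated
```

and `results/screen.tsv` ranks exactly the planted family first:

```
rank  id            species  base_id  elimination_stage  combined_score
1     plant0_mouse  mouse    plant0                      0.7591
2     plant0_human  human    plant0                      0.7340
3     plant0_rat    rat      plant0                      0.7340
      decoy_heavy_glyco_human  human  decoy_heavy_glyco  glycosylation
      ...
```

Mass verification against an observed spectrum: a predicted average mass of
5805.6982 Da matched against the peaks observed in media from transfected
cells (`5083.73, 5671.25, 5808.66, 8412.02, 8586.64` m/z) is assigned to
the 5808.66 peak with a signed delta of +2.96 Da (protonation plus matrix
adducts in linear-mode MALDI), and to no peak of the control-cell list at
the default 5 Da tolerance:

```python
>>> from pepscreen import MassSpectrumPeakList, match_masses
>>> peaks = MassSpectrumPeakList(peaks=(5083.73, 5671.25, 5808.66, 8412.02, 8586.64))
>>> match_masses({"peptide_Lv": 5805.6982}, peaks)
[MassAssignment(candidate_id='peptide_Lv', predicted_mass_da=5805.6982,
                peak_mz=5808.66, delta_da=2.9618...)]
```

## Layout

- `src/pepscreen/records.py` — records, FASTA I/O, longest-ORF translation
- `src/pepscreen/signal_peptide.py` — signal-peptide detector
- `src/pepscreen/membrane.py` — hydrophobicity profile, TM segments
- `src/pepscreen/convertase.py` — motif scanning, proprotein segmentation
- `src/pepscreen/glyco.py` — sequon scanning, heavy-glycosylation rule
- `src/pepscreen/homology.py` — global alignment, conservation classes
- `src/pepscreen/mass.py` — excision, mass prediction, peak matching
- `src/pepscreen/pipeline.py` — cascade, scoring, ranking, reports
- `src/pepscreen/synthetic.py` — fixture generator (planted + decoys)
- `src/pepscreen/cli.py` — `pepscreen run | mass | fixtures`

See `docs/methods.md` for the model details, parameter defaults and
limitations.
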