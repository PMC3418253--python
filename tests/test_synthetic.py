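"""Generator invariants: determinism, planted anatomy, ortholog identity."""

import time

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepscreen import ProteinRecord, count_tm, predict_signal_peptide
from pepscreen.records import PROTEIN_ALPHABET
from pepscreen.synthetic import (
    DECOY_KINDS,
    PlantSpec,
    generate_corpus,
    generate_decoy,
    generate_proprotein,
    mutate_to_identity,
)


class TestGenerateProprotein:
    def test_deterministic_given_seed(self):
        a, _ = generate_proprotein(PlantSpec(seed=17))
        b, _ = generate_proprotein(PlantSpec(seed=17))
        assert a.sequence == b.sequence

    def test_total_length_and_layout(self):
        rec, layout = generate_proprotein(PlantSpec(seed=3))
        assert len(rec.sequence) == 319
        lo, hi = layout.core
        assert hi - lo + 1 == 49
        assert rec.description == "hypothetical protein"

    def test_without_tm_no_tm_called(self):
        rec, _ = generate_proprotein(PlantSpec(seed=4, tm_present=False))
        assert count_tm(rec, predict_signal_peptide(rec)) == 0

    def test_sequences_use_valid_alphabet(self):
        for seed in range(5):
            rec, _ = generate_proprotein(PlantSpec(seed=seed))
            assert set(rec.sequence) <= PROTEIN_ALPHABET


class TestMutateToIdentity:
    def test_identity_one_returns_same_sequence(self):
        rec, _ = generate_proprotein(PlantSpec(seed=5))
        assert mutate_to_identity(rec, 1.0, seed=1).sequence == rec.sequence

    def test_exact_substitution_count(self):
        rec, _ = generate_proprotein(PlantSpec(seed=5))
        ortho = mutate_to_identity(rec, 0.8, seed=2)
        n_diff = sum(a != b for a, b in zip(rec.sequence, ortho.sequence))
        assert n_diff == round(0.2 * len(rec.sequence))

    def test_protected_ranges_untouched(self):
        rec, layout = generate_proprotein(PlantSpec(seed=5))
        ortho = mutate_to_identity(rec, 0.5, seed=3,
                                   protected_ranges=layout.protected_ranges())
        for lo, hi in layout.protected_ranges():
            assert ortho.sequence[lo - 1:hi] == rec.sequence[lo - 1:hi]

    def test_low_target_refused(self):
        rec, _ = generate_proprotein(PlantSpec(seed=5))
        with pytest.raises(ValueError):
            mutate_to_identity(rec, 0.1, seed=1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           target=st.floats(0.5, 1.0))
    def test_realized_identity_within_one_residue(self, seed, target):
        rec, _ = generate_proprotein(PlantSpec(seed=seed % 100))
        ortho = mutate_to_identity(rec, target, seed=seed)
        n = len(rec.sequence)
        realized = sum(a == b for a, b in
                       zip(rec.sequence, ortho.sequence)) / n
        assert abs(realized - target) <= 1.0 / n + 1e-9


class TestDecoys:
    def test_unrecognized_kind(self):
        with pytest.raises(ValueError):
            generate_decoy("confetti", seed=1)

    @pytest.mark.parametrize("kind", DECOY_KINDS)
    def test_decoy_records_valid(self, kind):
        rec, _ = generate_decoy(kind, seed=9)
        assert set(rec.sequence) <= PROTEIN_ALPHABET

    def test_no_signal_decoy_fails_signal_stage(self):
        rec, _ = generate_decoy("no_signal", seed=9)
        assert not predict_signal_peptide(rec).present

    def test_multi_tm_decoy_has_two_tms(self):
        rec, _ = generate_decoy("multi_tm", seed=9)
        assert count_tm(rec, predict_signal_peptide(rec)) == 2

    def test_well_annotated_decoy_misses_keywords(self):
        rec, _ = generate_decoy("well_annotated", seed=9)
        assert "hypothetical" not in rec.description
        assert predict_signal_peptide(rec).present


class TestEncodeCdna:
    @pytest.mark.parametrize("seed", [0, 1, 11])
    def test_longest_orf_recovers_protein(self, seed):
        from pepscreen.records import translate_longest_orf
        from pepscreen.synthetic import encode_cdna

        rec, _ = generate_proprotein(PlantSpec(seed=seed))
        cdna = encode_cdna(rec, seed=seed)
        assert translate_longest_orf(cdna).sequence == rec.sequence


class TestCorpus:
    def test_species_and_id_convention(self, corpus):
        assert set(corpus) == {"mouse", "rat", "human"}
        for sp, records in corpus.items():
            assert all(r.id.endswith(f"_{sp}") for r in records)
            assert all(r.species == sp for r in records)

    def test_fifty_records_generated_quickly(self):
        t0 = time.time()
        corpus, _ = generate_corpus(seed=99, n_planted=12)
        n = sum(len(v) for v in corpus.values())
        assert n >= 50
        assert time.time() - t0 < 10.0
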