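"""Global alignment vs exhaustive enumeration; conservation classes; gating."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from pepscreen import (
    conservation_classes,
    global_align,
    meets_homology_threshold,
    pairwise_report,
)
from pepscreen.homology import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, HomologyReport
from pepscreen.synthetic import PlantSpec, generate_proprotein, mutate_to_identity

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def oracle_best_score(a, b, gap_open=DEFAULT_GAP_OPEN,
                      gap_extend=DEFAULT_GAP_EXTEND):
    """Enumerate every global alignment path and return the optimal score.

    DP-free: recursion over (i, j, previous move), scoring affine gaps as
    open for the first gap residue and extend for each continuation.
    """

    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = BLOSUM62[a[i], b[j]] + rec(i + 1, j + 1, "m")
            best = max(best, s)
        if i < len(a):
            cost = gap_extend if prev == "d" else gap_open
            best = max(best, -cost + rec(i + 1, j, "d"))
        if j < len(b):
            cost = gap_extend if prev == "i" else gap_open
            best = max(best, -cost + rec(i, j + 1, "i"))
        return best

    return rec(0, 0, "m")


def test_identity_alignment_all_stars():
    aln = global_align("HEAGAWGHEE", "HEAGAWGHEE")
    assert aln.aligned_a == aln.aligned_b == "HEAGAWGHEE"
    assert conservation_classes(aln.aligned_a, aln.aligned_b) == "*" * 10


def test_completely_different_sequences_zero_identity():
    rep = pairwise_report("a", "AAAA", "b", "TTTT")
    assert rep.percent_identity == 0.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_align("", "AAA")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_score_matches_exhaustive_enumeration(seed):
    """Optimal affine-gap score equals brute-force path enumeration (<= 6 aa)."""
    rng = np.random.default_rng(seed)
    alphabet = list("ACDE")  # reduced 4-letter alphabet
    for _ in range(8):
        a = "".join(rng.choice(alphabet, size=int(rng.integers(1, 7))))
        b = "".join(rng.choice(alphabet, size=int(rng.integers(1, 7))))
        assert global_align(a, b).score == pytest.approx(oracle_best_score(a, b))


def test_strong_group_column_classes():
    assert conservation_classes("K", "R") == ":"  # both in QHRK
    assert conservation_classes("A-", "AT") == "* "  # gaps never conserved
    assert conservation_classes("A", "V") == "."  # weak group ATV only


def test_similarity_at_least_identity():
    rng = np.random.default_rng(21)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(10):
        a = "".join(rng.choice(aa, size=30))
        b = "".join(rng.choice(aa, size=30))
        rep = pairwise_report("a", a, "b", b)
        assert rep.percent_similarity >= rep.percent_identity
        assert len(rep.column_classes) == rep.alignment_length


def test_self_identity_is_100():
    rng = np.random.default_rng(22)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(5):
        a = "".join(rng.choice(aa, size=int(rng.integers(1, 60))))
        assert pairwise_report("a", a, "a", a).percent_identity == 100.0


def test_score_symmetric_under_swap():
    rng = np.random.default_rng(23)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(10):
        a = "".join(rng.choice(aa, size=int(rng.integers(5, 40))))
        b = "".join(rng.choice(aa, size=int(rng.integers(5, 40))))
        assert global_align(a, b).score == global_align(b, a).score


class TestThresholdGate:
    def _reports(self, identities):
        return [HomologyReport(id_a="a", id_b=f"b{i}", species_a="",
                               species_b="", percent_identity=pid,
                               percent_similarity=pid, alignment_length=100,
                               column_classes="*" * 100)
                for i, pid in enumerate(identities)]

    def test_all_above_threshold(self):
        assert meets_homology_threshold(self._reports([92, 88, 85]), 50)

    def test_minimum_rule(self):
        assert not meets_homology_threshold(self._reports([92, 40]), 50)

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            meets_homology_threshold([], 50)

    def test_mutated_ortholog_identity_near_target(self):
        rec, layout = generate_proprotein(PlantSpec(seed=5))
        ortho = mutate_to_identity(rec, 0.8, seed=6,
                                   protected_ranges=layout.protected_ranges())
        rep = pairwise_report(rec.id, rec.sequence, "o", ortho.sequence)
        assert abs(rep.percent_identity - 80.0) <= 5.0
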