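"""Peptide masses vs an atomic-composition oracle; excision; peak matching."""

import numpy as np
import pytest
from pyteomics import mass as pyteomics_mass

from pepscreen import (
    MassSpectrumPeakList,
    ProteinRecord,
    excise_candidates,
    match_masses,
    peptide_mass,
    predict_signal_peptide,
    read_peak_list,
    scan_convertase_motifs,
)
from pepscreen.synthetic import PlantSpec, generate_proprotein

AA = list("ACDEFGHIKLMNPQRSTVWY")

# peak lists observed by MALDI-TOF on media from transfected vs control cells
TRANSFECTED_PEAKS = (5083.73, 5671.25, 5808.66, 8412.02, 8586.64)
CONTROL_PEAKS = (5071.45, 5375.00, 5491.28, 5665.46)
PREDICTED_MW = 5805.6982


class TestPeptideMass:
    def test_glycine_matches_atomic_composition(self):
        # free glycine is C2H5NO2
        assert peptide_mass("G", "average") == pytest.approx(
            pyteomics_mass.calculate_mass(sequence="G", average=True), abs=1e-3)
        assert peptide_mass("G", "monoisotopic") == pytest.approx(
            pyteomics_mass.calculate_mass(sequence="G"), abs=1e-5)

    def test_dipeptide_additivity(self):
        water = peptide_mass("G", "average") * 2 - peptide_mass("GG", "average")
        assert water == pytest.approx(18.0153, abs=1e-3)

    def test_oracle_agreement_on_random_peptides(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            pep = "".join(rng.choice(AA, size=int(rng.integers(1, 60))))
            assert peptide_mass(pep, "average") == pytest.approx(
                pyteomics_mass.calculate_mass(sequence=pep, average=True),
                abs=0.02)
            assert peptide_mass(pep, "monoisotopic") == pytest.approx(
                pyteomics_mass.calculate_mass(sequence=pep), abs=1e-4)

    def test_split_additivity(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            pep = "".join(rng.choice(AA, size=int(rng.integers(2, 50))))
            cut = int(rng.integers(1, len(pep)))
            for kind, water in (("average", 18.01528), ("monoisotopic", 18.010565)):
                whole = peptide_mass(pep, kind)
                parts = peptide_mass(pep[:cut], kind) + peptide_mass(pep[cut:], kind)
                assert whole == pytest.approx(parts - water, abs=1e-6)

    def test_average_at_least_monoisotopic(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            pep = "".join(rng.choice(AA, size=int(rng.integers(2, 80))))
            assert peptide_mass(pep, "average") >= peptide_mass(pep, "monoisotopic")

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("AXA", "average")


class TestExcision:
    def _pieces(self, planted):
        rec, _ = planted
        call = predict_signal_peptide(rec)
        hits = scan_convertase_motifs(rec.sequence)
        return rec, call, hits

    def test_planted_core_is_sole_candidate(self, planted):
        rec, call, hits = self._pieces(planted)
        cands = excise_candidates(rec, call, hits)
        assert len(cands) == 1
        assert len(cands[0].sequence) == 49
        assert (cands[0].n_flank, cands[0].c_flank) == ("KR", "GRR")
        assert 3000 <= cands[0].average_mass_da <= 10000
        assert cands[0].average_mass_da >= cands[0].monoisotopic_mass_da

    def test_small_fragments_excluded_by_window(self, planted):
        rec, call, hits = self._pieces(planted)
        # default window drops the signal fragment (~2 kDa) and linkers
        cands = excise_candidates(rec, call, hits, mass_window_da=(3000, 10000))
        assert all(len(c.sequence) >= 25 for c in cands)

    def test_unbounded_window_yields_all_nonlinker_fragments(self, planted):
        from pepscreen import segment_by_cleavage
        rec, call, hits = self._pieces(planted)
        frags = [f for f in segment_by_cleavage(rec.sequence, call, hits)
                 if not f.is_linker]
        cands = excise_candidates(rec, call, hits, mass_window_da=(0, 1e9))
        assert len(cands) == len(frags)

    def test_candidates_subset_of_fragments(self, planted):
        from pepscreen import segment_by_cleavage
        rec, call, hits = self._pieces(planted)
        frag_ivals = {(f.start, f.end)
                      for f in segment_by_cleavage(rec.sequence, call, hits)}
        cands = excise_candidates(rec, call, hits)
        assert {(c.start, c.end) for c in cands} <= frag_ivals


class TestPeakMatching:
    def test_prediction_assigned_to_nearby_transfected_peak(self):
        peaks = MassSpectrumPeakList(peaks=TRANSFECTED_PEAKS, label="transfected")
        (a,) = match_masses({"candidate": PREDICTED_MW}, peaks)
        assert a.peak_mz == 5808.66
        assert a.delta_da == pytest.approx(2.96, abs=0.01)

    def test_prediction_unassigned_against_control_peaks(self):
        peaks = MassSpectrumPeakList(peaks=CONTROL_PEAKS, label="control")
        (a,) = match_masses({"candidate": PREDICTED_MW}, peaks)
        assert a.peak_mz is None

    def test_zero_tolerance_exact_match(self):
        peaks = MassSpectrumPeakList(peaks=(1000.0,))
        (a,) = match_masses({"c": 1000.0}, peaks, tolerance_da=0.0)
        assert a.peak_mz == 1000.0 and a.delta_da == 0.0

    def test_empty_peak_list_leaves_unassigned(self):
        peaks = MassSpectrumPeakList(peaks=())
        (a,) = match_masses({"c": 5000.0}, peaks)
        assert a.peak_mz is None

    def test_assignment_count_monotone_in_tolerance(self):
        peaks = MassSpectrumPeakList(peaks=(1000.0, 2000.0, 3000.0))
        masses = {"a": 1001.0, "b": 2010.0, "c": 2999.5}
        counts = [sum(x.peak_mz is not None
                      for x in match_masses(masses, peaks, tolerance_da=t))
                  for t in (0.0, 0.5, 1.0, 5.0, 10.0, 100.0)]
        assert counts == sorted(counts)

    def test_read_peak_list_formats(self, tmp_path):
        p1 = tmp_path / "plain.txt"
        p1.write_text("5083.73\n5671.25\n# comment\n\n5808.66\n")
        p2 = tmp_path / "two_col.tsv"
        p2.write_text("5083.73\t120\n5671.25\t80\n5808.66\t45\n")
        assert read_peak_list(p1).peaks == read_peak_list(p2).peaks == \
            (5083.73, 5671.25, 5808.66)
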