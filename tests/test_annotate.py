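"""Spectrum cleanup, formula enumeration, fragmentation and annotation
scores."""

import pytest

from tpscreen.annotate import (
    ann_similarity,
    annotate_fragments,
    compound_annotation_score,
    enumerate_formulas,
    fragment_structure,
    remove_background,
)
from tpscreen.chem import StructureRecord, parse_formula, rdbe
from tpscreen.model import Ms2Spectrum

from _oracles import enumerate_formulas_nested

BOUNDS = {"C": 20, "H": 40, "N": 5, "O": 8, "S": 2, "F": 6}


class TestBackgroundRemoval:
    target = Ms2Spectrum("f", 200.0, [(100.0, 100.0), (150.0, 1000.0)])
    flanking = [Ms2Spectrum("f-pre", 200.0, [(100.0004, 90.0)])]

    def test_background_peak_removed(self):
        out = remove_background(self.target, self.flanking,
                                background_factor=2.0)
        assert [round(m, 1) for m, _ in out.peaks] == [150.0]

    def test_peak_without_flanking_match_retained(self):
        out = remove_background(self.target, [Ms2Spectrum("x", 200.0,
                                                          [(60.0, 1e6)])])
        assert len(out.peaks) == 2

    def test_empty_flanking_only_floor(self):
        spectrum = Ms2Spectrum("f", 200.0, [(100.0, 5.0), (150.0, 1000.0)])
        out = remove_background(spectrum, [], rel_intensity_floor=0.01)
        assert [m for m, _ in out.peaks] == [150.0]

    def test_never_grows_and_idempotent(self):
        once = remove_background(self.target, self.flanking)
        twice = remove_background(once, self.flanking)
        assert len(once.peaks) <= len(self.target.peaks)
        assert twice.peaks == once.peaks


class TestEnumerateFormulas:
    def test_aniline_found(self):
        hits = {f.render() for f, _ in enumerate_formulas(
            94.0651, tol_mda=5.0, bounds=BOUNDS)}
        assert "C6H7N" in hits

    def test_impossibly_tight_tolerance_empty(self):
        assert enumerate_formulas(94.10, tol_mda=0.01, bounds=BOUNDS) == []

    def test_all_results_satisfy_rdbe(self):
        for f, _ in enumerate_formulas(201.1234, tol_mda=5.0,
                                       bounds=BOUNDS):
            assert rdbe(f) >= 0

    def test_sorted_by_absolute_error(self):
        errors = [abs(e) for _, e in enumerate_formulas(226.1438,
                                                        tol_mda=5.0,
                                                        bounds=BOUNDS)]
        assert errors == sorted(errors)

    @pytest.mark.parametrize("mz", [
        94.0651, 99.0553, 139.05, 174.0219, 226.1438, 287.91, 299.9])
    def test_matches_nested_loop_oracle(self, mz):
        got = {f.render() for f, _ in enumerate_formulas(mz, tol_mda=5.0,
                                                         bounds=BOUNDS)}
        assert got == enumerate_formulas_nested(mz, 5.0, BOUNDS)


ANILINE_FORMULA = parse_formula("C6H7N")


class TestFragmentAnnotation:
    def test_phenyl_cation_assigned(self):
        spectrum = Ms2Spectrum("f", 94.0651, [(77.0386, 100.0)])
        ann = annotate_fragments(spectrum, ANILINE_FORMULA)
        assert ann.assignments[0].formula.render() == "C6H5"
        assert abs(ann.assignments[0].error_mda) < 5.0

    def test_peak_heavier_than_precursor_unassigned(self):
        spectrum = Ms2Spectrum("f", 94.0651, [(150.0, 100.0)])
        ann = annotate_fragments(spectrum, ANILINE_FORMULA)
        assert ann.assignments[0].formula is None
        assert ann.explained_intensity_fraction == 0.0

    def test_fully_assigned_explains_everything(self):
        spectrum = Ms2Spectrum("f", 94.0651, [(77.0386, 100.0),
                                              (51.0229, 40.0)])
        ann = annotate_fragments(spectrum, ANILINE_FORMULA)
        assert all(a.formula is not None for a in ann.assignments)
        assert ann.explained_intensity_fraction == 1.0

    def test_assignments_are_subformulas(self):
        spectrum = Ms2Spectrum("f", 174.0219, [(108.0444, 50.0),
                                               (93.0578, 100.0),
                                               (80.0, 10.0)])
        precursor = parse_formula("C6H7NO3S")
        ann = annotate_fragments(spectrum, precursor)
        for a in ann.assignments:
            if a.formula is not None:
                assert precursor.contains(a.formula)


class TestFragmenter:
    def test_ethanol_depth_one(self):
        frags = fragment_structure(
            StructureRecord.from_smiles("ethanol", "CCO"), depth=1)
        # C-C cut: CH3 + CH3O; C-O cut: C2H5 + OH; plus the intact molecule
        assert frags.formulas() == {"CH3", "CH3O", "C2H5", "HO", "C2H6O"}

    def test_depth_zero_intact_only(self):
        frags = fragment_structure(
            StructureRecord.from_smiles("ethanol", "CCO"), depth=0)
        assert frags.formulas() == {"C2H6O"}

    def test_fragment_count_monotone_in_depth(self):
        s = StructureRecord.from_smiles("smx",
                                        "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1")
        sizes = [len(fragment_structure(s, depth=d).fragments)
                 for d in (0, 1, 2)]
        assert sizes == sorted(sizes)

    def test_ring_bonds_break_pairwise(self):
        benzene = StructureRecord.from_smiles("benzene", "c1ccccc1")
        frags = fragment_structure(benzene, depth=1)
        # single ring-bond cuts cannot split; pair cuts give C2/C3/C4 pieces
        assert {"C2H2", "C3H3", "C4H4"} <= frags.formulas()

    def test_oversized_budget_flags_partial(self):
        s = StructureRecord.from_smiles(
            "fle", "O=C(NCC1CCCCN1)c1cc(OCC(F)(F)F)ccc1OCC(F)(F)F")
        frags = fragment_structure(s, depth=3, max_fragments=30)
        assert frags.partial


class TestScores:
    def test_self_consistent_spectrum_scores_high(self):
        s = StructureRecord.from_smiles("smx",
                                        "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1")
        frags = fragment_structure(s, depth=2)
        masses = sorted((m for _, m in frags.fragments), reverse=True)[:6]
        spectrum = Ms2Spectrum("f", 255.0, sorted(
            (m + 1.007276, 100.0) for m in masses))
        score = compound_annotation_score(spectrum, s)
        assert score.value >= 0.9

    def test_missing_spectrum_is_absent_not_zero(self):
        s = StructureRecord.from_smiles("a", "Nc1ccccc1")
        assert compound_annotation_score(None, s).absent

    def test_ann_similarity_identity_disjoint_symmetry(self):
        a = {"C6H5", "C6H7N"}
        b = {"CH3", "C2H5"}
        assert ann_similarity(a, a) == 1.0
        assert ann_similarity(a, b) == 0.0
        assert ann_similarity(a, {"C6H5"}) == ann_similarity({"C6H5"}, a)
        assert 0.0 <= ann_similarity(a, {"C6H5", "CH3"}) <= 1.0
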