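"""Formula algebra, masses, isotope patterns and structure metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tpscreen.chem import (
    FormulaError,
    MolecularFormula,
    StructureRecord,
    adduct_mz,
    formula_add,
    formula_subtract,
    isotope_pattern,
    monoisotopic_mass,
    parse_formula,
    predict_logp,
    structure_fit,
    structure_similarity,
)

from _oracles import isotope_pattern_multinomial, mcs_size_bruteforce


class TestParseRender:
    @pytest.mark.parametrize("text,counts", [
        ("C6H7N", {"C": 6, "H": 7, "N": 1}),
        ("C17H20F6N2O3", {"C": 17, "H": 20, "F": 6, "N": 2, "O": 3}),
        ("HO", {"H": 1, "O": 1}),
    ])
    def test_parse(self, text, counts):
        assert parse_formula(text).counts == counts

    def test_alphabet_violation_names_symbol(self):
        with pytest.raises(FormulaError, match="Cl"):
            parse_formula("C6H7ClN2O")

    @pytest.mark.parametrize("bad", ["", "C0H4", "Xx2", "c6h6", "C6 H6"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    formula_strategy = st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "S", "F"]),
        st.integers(min_value=1, max_value=40), min_size=1)

    @given(formula_strategy)
    @settings(max_examples=100, deadline=None)
    def test_render_parse_roundtrip(self, counts):
        f = MolecularFormula.from_counts(counts)
        assert parse_formula(f.render()).counts == f.counts

    @given(formula_strategy, formula_strategy)
    @settings(max_examples=100, deadline=None)
    def test_add_subtract_inverse(self, a, b):
        fa = MolecularFormula.from_counts(a)
        fb = MolecularFormula.from_counts(b)
        assert formula_subtract(formula_add(fa, fb), fb).counts == fa.counts


class TestFormulaAlgebra:
    def test_metoprolol_plus_peroxide(self):
        result = formula_add(parse_formula("C15H25NO3"),
                             parse_formula("H2O2"))
        assert result.render() == "C15H27NO5"

    def test_flecainide_minus_c2hf3(self):
        result = formula_subtract(parse_formula("C17H20F6N2O3"),
                                  parse_formula("C2HF3"))
        assert result.render() == "C15H19F3N2O3"

    def test_self_subtraction_empty_rejected(self):
        f = parse_formula("C6H6")
        with pytest.raises(FormulaError):
            formula_subtract(f, f)

    def test_deficient_element_named(self):
        with pytest.raises(FormulaError, match="F"):
            formula_subtract(parse_formula("C6H6"), parse_formula("CF"))

    @given(TestParseRender.formula_strategy,
           TestParseRender.formula_strategy)
    @settings(max_examples=60, deadline=None)
    def test_mass_additivity(self, a, b):
        fa = MolecularFormula.from_counts(a)
        fb = MolecularFormula.from_counts(b)
        assert monoisotopic_mass(formula_add(fa, fb)) == pytest.approx(
            monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-9)


class TestMassAndAdduct:
    # neutral monoisotopic mass and [M+H]+ of the worked TP examples
    @pytest.mark.parametrize("formula,mass,mh", [
        ("C6H7N", 93.0578, 94.0651),          # aniline
        ("C4H6N2O", 98.0480, 99.0553),        # 3-amino-5-methylisoxazole
        ("C6H7NO3S", 173.0147, 174.0219),     # sulfanilic acid
        ("C12H19NO3", 225.1365, 226.1438),    # des-isopropyl metoprolol
        ("C15H19F3N2O3", 332.1348, 333.1420),  # flecainide - C2HF3
    ])
    def test_reference_masses(self, formula, mass, mh):
        m = monoisotopic_mass(parse_formula(formula))
        assert m == pytest.approx(mass, abs=5e-4)
        assert adduct_mz(m) == pytest.approx(mh, abs=5e-4)

    def test_unsupported_adduct(self):
        with pytest.raises(FormulaError, match=r"\[M\+Na\]\+"):
            adduct_mz(100.0, "[M+Na]+")


class TestIsotopePattern:
    def test_single_carbon_m1(self):
        # 13C/12C abundance ratio
        assert isotope_pattern(parse_formula("C")).abundance(1) \
            == pytest.approx(0.0107 / 0.9893, rel=1e-9)

    def test_h2_m2_negligible(self):
        assert isotope_pattern(parse_formula("H2")).abundance(2) \
            == pytest.approx((0.000115 / 0.999885) ** 2, rel=1e-9)

    @pytest.mark.parametrize("formula", [
        "C10H11N3O3S",   # sulfamethoxazole
        "C6H7N", "C4H6N2O", "C8H10N4O2", "C9H8O4", "C7H5NO3S",
    ])
    def test_convolution_matches_multinomial_oracle(self, formula):
        f = parse_formula(formula)
        oracle = isotope_pattern_multinomial(f.counts)
        pattern = isotope_pattern(f)
        for offset in (1, 2):
            assert pattern.abundance(offset) == pytest.approx(
                oracle[offset], rel=1e-6)

    def test_parent_m2_below_six_percent(self):
        # low M+2 abundance is what makes the isotopologue channel usable
        # for quantifying otherwise saturating parent signals
        for formula in ("C17H20F6N2O3", "C15H25NO3", "C10H11N3O3S",
                        "C11H12N2O"):
            assert isotope_pattern(parse_formula(formula)).abundance(2) < 0.06

    def test_union_formula_is_convolution_of_parts(self):
        a = parse_formula("C6H7N")
        b = parse_formula("C4H6N2O")
        pa = isotope_pattern(a, 4)
        pb = isotope_pattern(b, 4)
        pu = isotope_pattern(formula_add(a, b), 4)
        # relative patterns multiply under convolution when both are
        # normalised to the monoisotopic peak
        va = np.array([pa.abundance(i) for i in range(5)])
        vb = np.array([pb.abundance(i) for i in range(5)])
        conv = np.convolve(va, vb)[:5]
        for i in range(5):
            assert pu.abundance(i) == pytest.approx(conv[i], rel=1e-6)

    def test_low_max_offset_rejected(self):
        with pytest.raises(ValueError):
            isotope_pattern(parse_formula("C6H6"), max_offset=1)


ANILINE = "Nc1ccccc1"
SMX = "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1"


class TestStructureMetrics:
    def test_similarity_identity_and_symmetry(self):
        a = StructureRecord.from_smiles("a", ANILINE)
        b = StructureRecord.from_smiles("b", SMX)
        assert structure_similarity(a, a) == 1.0
        assert structure_similarity(a, b) == structure_similarity(b, a)
        assert 0.0 <= structure_similarity(a, b) < 1.0

    def test_methane_vs_decane_below_one(self):
        a = StructureRecord.from_smiles("methane", "C")
        b = StructureRecord.from_smiles("decane", "CCCCCCCCCC")
        assert 0.0 <= structure_similarity(a, b) < 1.0

    def test_unparseable_smiles_named(self):
        with pytest.raises(Exception, match="bad-record"):
            StructureRecord.from_smiles("bad-record", "C1CC")

    def test_aniline_substructure_of_smx(self):
        fit = structure_fit(StructureRecord.from_smiles("a", ANILINE),
                            StructureRecord.from_smiles("p", SMX))
        assert fit.value == 1.0
        assert fit.fit_in_candidate == 1.0
        assert fit.fit_in_parent < 1.0

    def test_fit_identity(self):
        s = StructureRecord.from_smiles("s", SMX)
        assert structure_fit(s, s).value == 1.0

    def test_disjoint_elements_zero(self):
        a = StructureRecord.from_smiles("hc", "CCCC")
        b = StructureRecord.from_smiles("pf", "FC(F)(F)C(F)(F)F")
        # MCS still matches the carbon skeleton; force disjoint elements
        c = StructureRecord.from_smiles("o", "OO")
        assert structure_fit(c, a).value == 0.0

    @pytest.mark.parametrize("sa,sb", [
        (ANILINE, SMX),
        ("CCO", "CCCO"),
        ("c1ccccc1C(=O)O", "c1ccccc1C=O"),
        ("CC(C)NCC(O)CO", "CC(C)NCCO"),
        ("Cc1cc(N)no1", SMX),
    ])
    def test_mcs_matches_bruteforce(self, sa, sb):
        a = StructureRecord.from_smiles("a", sa)
        b = StructureRecord.from_smiles("b", sb)
        expected = mcs_size_bruteforce(a.mol, b.mol)
        assert structure_fit(a, b).mcs_atoms == expected

    def test_logp_deterministic_and_ordered(self):
        decane = StructureRecord.from_smiles("d", "CCCCCCCCCC")
        methanol = StructureRecord.from_smiles("m", "CO")
        assert predict_logp(decane) == predict_logp(
            StructureRecord.from_smiles("d2", "CCCCCCCCCC"))
        assert predict_logp(decane) > predict_logp(methanol)

    def test_flecainide_most_lipophilic_parent(self):
        # the distinctly higher lipophilicity of flecainide is what makes
        # the elution-order filter effective for its candidates
        fle = StructureRecord.from_smiles(
            "FLE", "O=C(NCC1CCCCN1)c1cc(OCC(F)(F)F)ccc1OCC(F)(F)F")
        others = [StructureRecord.from_smiles("MET",
                                              "CC(C)NCC(O)COc1ccc(CCOC)cc1"),
                  StructureRecord.from_smiles("SMX", SMX),
                  StructureRecord.from_smiles("PHE",
                                              "CC1=CC(=O)N(c2ccccc2)N1C")]
        assert all(fle.logp > o.logp + 1.5 for o in others)

    def test_structure_record_consistency(self):
        s = StructureRecord.from_smiles("SMX", SMX)
        assert s.formula.render() == "C10H11N3O3S"
        assert s.monoisotopic_mass == pytest.approx(
            monoisotopic_mass(s.formula), abs=1e-4)
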