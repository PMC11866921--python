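"""Candidate filtering, metrics, thresholds and top-N ranking for
unknown features."""

import numpy as np
import pandas as pd
import pytest

from tpscreen.chem import StructureRecord, parse_formula
from tpscreen._elements import KNOWN_ELEMENTS
from tpscreen.model import Parent
from tpscreen.ranking import (
    CandidateScore,
    combine_score,
    derive_thresholds,
    element_filter,
    elution_order_filter,
    formula_fit,
    rank_candidates,
    score_proposed_structures,
)

SMX_PARENT = Parent("SMX", StructureRecord.from_smiles(
    "SMX", "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1"), rt=6.4, response_factor=1.0)


def _cand_df(rows):
    return pd.DataFrame(rows, columns=["group_id", "candidate_id", "kind",
                                       "smiles", "formula"])


class TestElementFilter:
    def test_forbidden_elements(self):
        df = _cand_df([
            ("g", "chloro", "formula", "", "C7H7ClN2O"),
            ("g", "aniline", "formula", "", "C6H7N"),
        ])
        out = element_filter(df, ("Cl", "Br", "Si", "P"))
        assert list(out["candidate_id"]) == ["aniline"]

    def test_empty_forbidden_is_identity(self):
        df = _cand_df([("g", "chloro", "formula", "", "C7H7ClN2O")])
        assert element_filter(df, ()).equals(df)


class TestElutionOrderFilter:
    def _df(self, smiles):
        return _cand_df([("g", "cand", "compound", smiles,
                          StructureRecord.from_smiles("c", smiles)
                          .formula.render())])

    def test_contradiction_beyond_tolerance_removed(self):
        # very lipophilic candidate but the feature elutes well before the
        # parent
        hydrophobe = "CCCCCCCCCCCCCCCC"
        out = elution_order_filter(self._df(hydrophobe), SMX_PARENT,
                                   feature_rt=3.0, tol_logp=2.0)
        assert out.empty

    def test_contradiction_within_tolerance_kept(self):
        mild = "CCCCCO"
        out = elution_order_filter(self._df(mild), SMX_PARENT,
                                   feature_rt=3.0, tol_logp=2.0)
        assert len(out) == 1

    def test_consistent_direction_kept(self):
        hydrophobe = "CCCCCCCCCCCCCCCC"
        out = elution_order_filter(self._df(hydrophobe), SMX_PARENT,
                                   feature_rt=11.0, tol_logp=2.0)
        assert len(out) == 1

    def test_formula_candidates_fail_open(self):
        df = _cand_df([("g", "f", "formula", "", "C6H7N")])
        out = elution_order_filter(df, SMX_PARENT, feature_rt=1.0)
        assert len(out) == 1


class TestFormulaFit:
    def test_aniline_fully_contained(self):
        assert formula_fit(parse_formula("C6H7N"),
                           parse_formula("C10H11N3O3S")) == 1.0

    def test_one_extra_oxygen(self):
        # 28 of the candidate's 29 atoms are available in the parent
        fit = formula_fit(parse_formula("C10H11N3O4S"),
                          parse_formula("C10H11N3O3S"))
        assert fit == pytest.approx(28 / 29)

    def test_identity(self):
        f = parse_formula("C10H11N3O3S")
        assert formula_fit(f, f) == 1.0


def _scores(values, metric="fit_compound"):
    out = []
    for i, v in enumerate(values):
        s = CandidateScore(group_id="g", candidate_id=f"c{i}",
                           kind="compound", fit_formula=1.0)
        setattr(s, metric, v)
        out.append(s)
    return out


class TestThresholds:
    def test_linear_interpolation_convention(self):
        thr = derive_thresholds(_scores([0.6, 0.7, 0.8, 0.9, 1.0]),
                                percentile=5.0, method="linear")
        assert thr["fit_compound"] == pytest.approx(0.62)

    def test_lower_convention_retains_calibration(self):
        values = [0.6, 0.7, 0.8, 0.9, 1.0]
        thr = derive_thresholds(_scores(values), percentile=5.0,
                                method="lower")
        assert thr["fit_compound"] == 0.6
        assert all(v >= thr["fit_compound"] for v in values)

    def test_percentile_zero_is_minimum(self):
        thr = derive_thresholds(_scores([0.6, 0.7, 0.8, 0.9, 1.0]),
                                percentile=0.0, method="linear")
        assert thr["fit_compound"] == 0.6

    def test_identical_scores_threshold_equals_them(self):
        thr = derive_thresholds(_scores([0.5] * 6), percentile=5.0)
        assert thr["fit_compound"] == 0.5

    def test_too_few_suspects_disables(self):
        log = []
        assert derive_thresholds(_scores([0.5] * 3), log=log) is None
        assert any("disabled" in line for line in log)


class TestCombiner:
    def test_mean_of_present_components(self):
        s = CandidateScore(group_id="g", candidate_id="c", kind="compound",
                           fit_formula=1.0, fit_compound=0.5,
                           sim_suspects=0.7)
        assert combine_score(s.components()) \
            == pytest.approx((1.0 + 0.5 + 0.7) / 3)

    def test_absent_components_renormalised(self):
        s = CandidateScore(group_id="g", candidate_id="c", kind="compound",
                           fit_formula=0.8, fit_compound=0.4)
        assert combine_score(s.components()) == pytest.approx(0.6)

    def test_order_invariance(self):
        comps = {"a": 0.2, "b": 0.9, "c": 0.4}
        assert combine_score(comps) == combine_score(
            dict(reversed(list(comps.items()))))


class TestRankCandidates:
    def test_top_n_rule(self, config):
        # 40 candidates all clearing the thresholds -> exactly 25 retained
        rows = []
        for i in range(40):
            rows.append(("g", f"c{i:02d}", "formula", "",
                         "C10H11N3O3S" if i % 2 else "C9H9N3O3S"))
        ranked = rank_candidates("g", _cand_df(rows), SMX_PARENT, [],
                                 feature_rt=6.4, spectrum=None,
                                 thresholds=None, config=config)
        assert len(ranked) == config["ranking"]["top_n"] == 25
        assert [c.rank for c in ranked] == list(range(1, 26))

    def test_ranks_unique_and_deterministic(self, config):
        rows = [("g", f"c{i}", "formula", "", "C6H7N") for i in range(5)]
        a = rank_candidates("g", _cand_df(rows), SMX_PARENT, [], 6.4, None,
                            None, config)
        b = rank_candidates("g", _cand_df(rows), SMX_PARENT, [], 6.4, None,
                            None, config)
        assert [c.candidate_id for c in a] == [c.candidate_id for c in b]
        assert len({c.rank for c in a}) == len(a)

    def test_filters_commute(self, config):
        rows = [
            ("g", "keep", "compound", "Nc1ccccc1", "C6H7N"),
            ("g", "chloro", "compound", "Clc1ccccc1", "C6H5Cl"),
            ("g", "grease", "compound", "CCCCCCCCCCCCCCCC", "C16H34"),
        ]
        df = _cand_df(rows)
        ef_then_rt = elution_order_filter(
            element_filter(df, ("Cl",)), SMX_PARENT, 3.0)
        rt_then_ef = element_filter(
            elution_order_filter(df, SMX_PARENT, 3.0), ("Cl",))
        assert sorted(ef_then_rt["candidate_id"]) \
            == sorted(rt_then_ef["candidate_id"])

    def test_raising_threshold_never_adds(self, config):
        rows = [("g", f"c{i}", "formula", "",
                 f"C{6+i}H{7+i*2}NO{i}") for i in range(1, 6)]
        low = rank_candidates("g", _cand_df(rows), SMX_PARENT, [], 6.4,
                              None, {"fit_formula": 0.2}, config)
        high = rank_candidates("g", _cand_df(rows), SMX_PARENT, [], 6.4,
                               None, {"fit_formula": 0.8}, config)
        assert {c.candidate_id for c in high} \
            <= {c.candidate_id for c in low}


class TestProposedStructures:
    def test_formula_mismatch_rejected(self, config):
        proposal = StructureRecord.from_smiles("p", "Nc1ccccc1")
        with pytest.raises(ValueError, match="does not match"):
            score_proposed_structures(
                "g", parse_formula("C7H9N"), [proposal], SMX_PARENT, [],
                None, config)

    def test_empty_proposals(self, config):
        assert score_proposed_structures(
            "g", parse_formula("C6H7N"), [], SMX_PARENT, [], None,
            config) == []

    def test_true_structure_outscores_decoys_on_own_spectrum(self, config):
        """The planted structure should top proposal scoring when the
        spectrum was generated from its own fragments."""
        from tpscreen.annotate import fragment_structure
        from tpscreen.model import Ms2Spectrum
        true = StructureRecord.from_smiles("true", "Nc1ccc(cc1)S(=O)(=O)O")
        # isomeric decoys (same C6H7NO3S formula, different connectivity)
        decoy_smiles = ["Oc1ccc(cc1)S(N)(=O)=O", "Nc1ccc(cc1)OS(=O)O",
                        "Oc1ccc(O)c(c1)S(N)=O"]
        frags = fragment_structure(true, depth=2)
        masses = sorted((m for _, m in frags.fragments), reverse=True)[:6]
        spectrum = Ms2Spectrum("g", 174.0, sorted(
            (m + 1.007276, 100.0) for m in masses))
        proposals = [true] + [
            StructureRecord.from_smiles(f"d{i}", s)
            for i, s in enumerate(decoy_smiles)]
        formula = true.formula
        usable = [p for p in proposals if p.formula.counts == formula.counts]
        assert len(usable) >= 3
        scored = score_proposed_structures("g", formula, usable, SMX_PARENT,
                                           [], spectrum, config)
        true_score = next(s for s in scored if s.candidate_id == "true")
        # fragment-mass matching cannot always separate isomers (ties are
        # possible), but no decoy may strictly outscore the true structure
        assert true_score.ann_compound == max(s.ann_compound for s in scored)
        assert true_score.tp_score == max(s.tp_score for s in scored)
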