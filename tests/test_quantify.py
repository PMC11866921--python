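"""Calibration invariants, pooled t statistics, semi-quantitation and
molar mass balances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tpscreen.chem import parse_formula, molar_mass
from tpscreen.quantify import (
    CalibrationError,
    fit_calibration,
    mass_balance,
    parent_rf_predictor,
    pooled_t,
    quantify,
    removal_stats,
    semi_quantify,
)

SERIES = [(12.5, 1250.0), (25.0, 2500.0), (50.0, 5000.0),
          (100.0, 10000.0), (200.0, 20000.0)]


class TestCalibration:
    def test_perfect_line_accepted_and_inverted(self):
        curve = fit_calibration(SERIES, "std")
        assert curve.accepted
        assert curve.slope == pytest.approx(100.0)
        assert curve.r_squared == pytest.approx(1.0)
        q = quantify(5000.0, curve)
        assert q.value_ugL == pytest.approx(50.0)
        assert not q.extrapolated

    def test_four_points_rejected(self):
        curve = fit_calibration(SERIES[:4], "std")
        assert not curve.accepted and "points" in curve.rejection_reason

    def test_large_residual_rejected(self):
        bent = SERIES[:-1] + [(200.0, 20000.0 * 1.45)]
        curve = fit_calibration(bent, "std")
        assert not curve.accepted
        assert "residual" in curve.rejection_reason \
            or "R²" in curve.rejection_reason

    def test_low_r2_rejected(self):
        noisy = [(c, r * (1 + 0.25 * (-1) ** i))
                 for i, (c, r) in enumerate(SERIES)]
        curve = fit_calibration(noisy, "std")
        assert not curve.accepted

    def test_rejected_curve_cannot_quantify(self):
        curve = fit_calibration(SERIES[:4], "std")
        with pytest.raises(CalibrationError, match="rejected"):
            quantify(100.0, curve)

    def test_extrapolation_flagged(self):
        curve = fit_calibration(SERIES, "std")
        assert quantify(100000.0, curve).extrapolated

    def test_adding_perfect_point_never_rejects(self):
        curve = fit_calibration(SERIES, "std")
        assert curve.accepted
        extended = SERIES + [(400.0, curve.slope * 400.0
                              + curve.intercept)]
        assert fit_calibration(extended, "std").accepted


class TestPooledT:
    def test_worked_example(self):
        # groups (90,100) vs (70,80): pooled t = 2.828, df = 2, p ~ 0.105
        t, df, p = pooled_t([90.0, 100.0], [70.0, 80.0])
        assert t == pytest.approx(2.8284271247, abs=1e-9)
        assert df == 2
        assert p == pytest.approx(0.1055728090, abs=1e-6)

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2,
                    max_size=6),
           st.lists(st.floats(min_value=-100, max_value=100), min_size=2,
                    max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_reference(self, a, b):
        if np.var(a) + np.var(b) == 0:
            return
        t, df, p = pooled_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(float(ref.statistic), rel=1e-9, abs=1e-9)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9, abs=1e-9)


class TestRemoval:
    def test_percent_removal(self):
        r = removal_stats([150.0, 150.0], [33.0, 33.0], "P", "U")
        assert r.removal_percent == pytest.approx(78.0)

    def test_identical_groups_not_significant(self):
        r = removal_stats([100.0, 100.0], [100.0, 100.0], "P", "U")
        assert r.removal_percent == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert r.significant is False

    def test_single_replicate_untestable(self):
        r = removal_stats([100.0], [60.0], "P", "U")
        assert r.removal_percent == pytest.approx(40.0)
        assert r.significant is None


SMX_FORMULA = parse_formula("C10H11N3O3S")


class TestSemiQuant:
    def test_standard_path(self):
        curve = fit_calibration(SERIES, "std")
        q = semi_quantify("tp", 5000.0, SMX_FORMULA, curve=curve)
        assert q.provenance == "standard"
        assert q.conc_uM == pytest.approx(50.0 / molar_mass(SMX_FORMULA))
        assert q.uncertainty_factor == 1.0

    def test_predicted_path_with_parent_rf(self):
        q = semi_quantify("tp", 5000.0, SMX_FORMULA,
                          rf_predictor=parent_rf_predictor(100.0))
        assert q.provenance == "predicted"
        assert q.conc_ugL == pytest.approx(50.0)
        assert q.uncertainty_factor == 5.0

    def test_no_route_fails_by_name(self):
        with pytest.raises(CalibrationError, match="tp"):
            semi_quantify("tp", 5000.0, SMX_FORMULA)


class TestMassBalance:
    def _quant(self, analyte, uM):
        from tpscreen.quantify import SemiQuant
        return SemiQuant(analyte_id=analyte, conc_ugL=0.0, conc_uM=uM,
                         provenance="standard", uncertainty_factor=1.0)

    def test_no_tps_zero_percent(self):
        b = mass_balance("P", "U", 1.0, [])
        assert b.explained_fraction_percent == 0.0

    def test_full_molar_conversion_100_percent(self):
        b = mass_balance("P", "U", 0.5, [self._quant("tp", 0.5)])
        assert b.explained_fraction_percent == pytest.approx(100.0)

    def test_undefined_for_no_removal(self):
        b = mass_balance("P", "U", 0.0, [self._quant("tp", 0.5)])
        assert not b.defined

    def test_shared_tp_split_mode(self):
        b = mass_balance("P", "U", 1.0, [self._quant("shared", 0.5)],
                         shared_tps={"shared"}, shared_mode="split")
        assert b.explained_fraction_percent == pytest.approx(25.0)
        assert any("split" in n for n in b.notes)

    def test_excluded_tp_itemised_but_not_summed(self):
        b = mass_balance("P", "U", 1.0,
                         [self._quant("a", 0.3), self._quant("b", 0.2)],
                         excluded_tps={"b"})
        assert b.explained_fraction_percent == pytest.approx(30.0)
        assert len(b.tp_contributions) == 2

    def test_noiseless_balance_recovers_planted_yield(self):
        """With exact response factors and no noise the summed TP molar
        formation equals the planted total yield."""
        from tpscreen.simulate import default_simulation_spec, simulate
        spec = default_simulation_spec(seed=9, n_noise_features=0,
                                       noise_sigma=0.0)
        spec.mz_jitter_mda = 0.0
        result = simulate(spec)
        design, features, truth = (result.design, result.features,
                                   result.truth)
        cond, level = "UH", 150.0
        cols = [s.sample_id for s in design.select(
            exposure_h=2, sample_type="mixture", condition=cond)
            if s.mixture_level == level]
        for parent in result.parents:
            ps = next(p for p in spec.parents
                      if p.parent.parent_id == parent.parent_id)
            removal = ps.removal[cond]
            if removal == 0:
                continue
            removed_uM = (level / molar_mass(parent.structure.formula)) \
                * removal
            quants = []
            expected_yield = 0.0
            for tp in spec.tp_defs:
                if tp.parent_id != parent.parent_id:
                    continue
                gid = tp.feature_id or f"T_{tp.tp_id}"
                row = truth[(truth["group_id"] == gid)
                            & (truth["tp_id"] == tp.tp_id)].iloc[0]
                formula = parse_formula(row["formula"])
                # per-TP response: share of the feature intensity planted
                # by this parent (shared features carry both parents)
                mw_p = molar_mass(parent.structure.formula)
                tp_uM = (level / mw_p) * removal \
                    * tp.yields.get(cond, 0.0)
                response = tp.response_factor * tp_uM * molar_mass(formula)
                if response <= 0:
                    continue
                q = semi_quantify(
                    tp.tp_id, response, formula,
                    rf_predictor=lambda _a, rf=tp.response_factor: rf)
                quants.append(q)
                expected_yield += tp.yields.get(cond, 0.0)
            balance = mass_balance(parent.parent_id, cond, removed_uM,
                                   quants)
            assert balance.explained_fraction_percent == pytest.approx(
                100.0 * expected_yield, abs=0.5)

    def test_rf_perturbation_stays_in_factor_five_band(self):
        """Response factors wrong by up to 5x keep the balance within the
        documented factor-5 uncertainty band."""
        rng = np.random.default_rng(0)
        true_uM = 0.4
        removed_uM = 1.0
        for _ in range(50):
            factor = float(np.exp(rng.uniform(np.log(1 / 5), np.log(5))))
            response = 100.0 * true_uM * molar_mass(SMX_FORMULA)
            q = semi_quantify(
                "tp", response, SMX_FORMULA,
                rf_predictor=lambda _a, f=factor: 100.0 * f)
            b = mass_balance("P", "U", removed_uM, [q])
            explained = b.explained_fraction_percent
            assert 100.0 * true_uM / 5.0 - 1e-9 <= explained \
                <= 100.0 * true_uM * 5.0 + 1e-9
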