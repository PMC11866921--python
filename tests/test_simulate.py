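"""Synthetic degradation experiments: determinism, linearity, and the
statistical contrast between planted TPs and background features."""

import numpy as np
import pytest

from tpscreen.config import default_config
from tpscreen.prioritize import regress_concentration
from tpscreen.simulate import (
    SimulationSpec,
    TPDef,
    default_parents,
    default_simulation_spec,
    default_tp_defs,
    simulate,
)


def _mixture_cols(design, level, exposure=2.0):
    return [s.sample_id for s in design.select(exposure_h=exposure,
                                               sample_type="mixture")
            if s.mixture_level == level and s.condition in ("U", "UH", "UHN")]


class TestDeterminismAndLinearity:
    def test_same_seed_identical_tables(self):
        a = simulate(default_simulation_spec(seed=11, n_noise_features=50))
        b = simulate(default_simulation_spec(seed=11, n_noise_features=50))
        assert a.features.df.equals(b.features.df)
        assert a.truth.equals(b.truth)
        assert [(s.feature_group_id, s.peaks) for s in a.spectra] \
            == [(s.feature_group_id, s.peaks) for s in b.spectra]

    def test_different_seed_differs(self):
        a = simulate(default_simulation_spec(seed=11, n_noise_features=50))
        b = simulate(default_simulation_spec(seed=12, n_noise_features=50))
        assert not a.features.df.equals(b.features.df)

    def test_noiseless_tp_intensity_exactly_linear(self):
        spec = default_simulation_spec(seed=1, n_noise_features=10,
                                       noise_sigma=0.0)
        result = simulate(spec)
        tp_rows = result.truth[result.truth["kind"] == "tp"]
        gid = tp_rows.iloc[0]["group_id"]
        row = result.features.row(gid)
        lo = np.mean([row[c] for c in _mixture_cols(result.design, 25.0)])
        hi = np.mean([row[c] for c in _mixture_cols(result.design, 150.0)])
        assert hi == pytest.approx(6.0 * lo, rel=1e-12)

    def test_zero_yield_leaves_only_parents_and_noise(self):
        spec = default_simulation_spec(seed=2, n_noise_features=20)
        for tp in spec.tp_defs:
            tp.yields = {c: 0.0 for c in tp.yields}
        result = simulate(spec)
        tp_gids = result.truth.loc[result.truth["kind"] == "tp", "group_id"]
        sample_cols = result.features.sample_columns
        for gid in tp_gids:
            assert float(result.features.row(gid)[sample_cols].max()) == 0.0

    def test_zero_hour_samples_lack_tps(self):
        result = simulate(default_simulation_spec(seed=3,
                                                  n_noise_features=10))
        zero_cols = [s.sample_id for s in result.design.samples
                     if s.exposure_h == 0]
        tp_gids = result.truth.loc[result.truth["kind"] == "tp", "group_id"]
        for gid in tp_gids:
            assert float(result.features.row(gid)[zero_cols].max()) == 0.0

    def test_infeasible_yields_rejected(self):
        parents = default_parents()
        tps = default_tp_defs()
        tps.append(TPDef(tp_id="greedy", parent_id="SMX",
                         smiles="Nc1ccccc1",
                         yields={"U": 0.95}, rt=3.0, response_factor=100.0))
        with pytest.raises(ValueError, match="exceeds 1"):
            SimulationSpec(parents=parents, tp_defs=tps)

    def test_saturation_cap_truncates(self):
        spec = default_simulation_spec(seed=4, n_noise_features=5,
                                       saturation_cap=1000.0)
        result = simulate(spec)
        assert float(result.features.df[
            result.features.sample_columns].to_numpy().max()) <= 1000.0


class TestStatisticalStructure:
    def test_tp_regression_r2_improves_as_noise_vanishes(self):
        r2 = {}
        for sigma in (0.4, 0.05, 0.0):
            result = simulate(default_simulation_spec(
                seed=5, n_noise_features=5, noise_sigma=sigma))
            tp_gids = set(result.truth.loc[result.truth["kind"] == "tp",
                                           "group_id"])
            regs = regress_concentration(
                result.features.subset(tp_gids), result.design)
            r2[sigma] = np.median([r.r_squared for r in regs
                                   if r.n_points > 0])
        assert r2[0.0] == pytest.approx(1.0, abs=1e-12)
        assert r2[0.05] > r2[0.4]

    def test_noise_features_exchangeable_across_arms(self):
        """Permutation test: background intensities carry no concentration
        information, so the observed arm-mean spread is typical of random
        relabelings (checked at alpha=0.01 on the error-rate average)."""
        result = simulate(default_simulation_spec(seed=6,
                                                  n_noise_features=60,
                                                  noise_sigma=0.2))
        rng = np.random.default_rng(0)
        design = result.design
        arms = {level: _mixture_cols(design, level)
                for level in (25.0, 75.0, 150.0)}
        cols = [c for cs in arms.values() for c in cs]
        sizes = [len(arms[l]) for l in (25.0, 75.0, 150.0)]
        noise_gids = result.truth.loc[result.truth["kind"] == "noise",
                                      "group_id"]
        rejections = 0
        for gid in noise_gids:
            values = result.features.row(gid)[cols].to_numpy(dtype=float)
            splits = np.split(np.arange(len(values)),
                              np.cumsum(sizes)[:-1])
            observed = np.var([values[s].mean() for s in splits])
            null = []
            for _ in range(200):
                perm = rng.permutation(values)
                null.append(np.var([perm[s].mean() for s in splits]))
            p = (1 + sum(v >= observed for v in null)) / 201
            rejections += p <= 0.01
        assert rejections / len(noise_gids) <= 0.05

    def test_planted_tp_prioritization_recall(self, config):
        result = simulate(default_simulation_spec(seed=8,
                                                  n_noise_features=500))
        from tpscreen.prioritize import prioritize
        out = prioritize(result.features, result.design, result.parents,
                         config)
        truth = result.truth
        tp = set(truth.loc[truth["kind"] == "tp", "group_id"])
        noise = set(truth.loc[truth["kind"] == "noise", "group_id"])
        kept = set(out.features.df["group_id"])
        assert len(tp & kept) / len(tp) >= 0.95
        assert len(noise - kept) / len(noise) >= 0.98
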