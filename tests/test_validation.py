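"""Essentiality screening, multiclass MCC, flux calls, parameter importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from contextgem import fixtures as fx
from contextgem import reconstruction as rc
from contextgem import validation as vl


class TestEssentiality:
    def test_planted_truth_on_isozyme_fixture(self, isozyme):
        model, truth = isozyme
        genes = sorted({g.id for g in model.genes})
        report = vl.essentiality_screen(model, genes)
        assert report.predicted_essential == truth["essential_genes"]

    def test_gene_absent_from_model_nonessential(self, isozyme):
        model, _ = isozyme
        report = vl.essentiality_screen(model, ["not_a_gene"])
        assert report.predicted_essential == set()
        assert not report.table.loc["not_a_gene", "in_model"]

    def test_bounds_restored_between_knockouts(self, isozyme):
        model, _ = isozyme
        before = {r.id: r.bounds for r in model.reactions}
        vl.essentiality_screen(model, sorted({g.id for g in model.genes}))
        after = {r.id: r.bounds for r in model.reactions}
        assert before == after

    def test_non_growing_wildtype_raises(self, chain):
        model, _ = chain
        model.reactions.EX_A0.bounds = (0.0, 0.0)
        with pytest.raises(ValueError, match="does not grow"):
            vl.essentiality_screen(model, ["g1"])

    def test_lethality_fraction_threshold(self, chain):
        model, truth = chain
        # add a weak bypass for R2: knocking out g2 leaves 0.05% of wild type
        import cobra

        bypass = cobra.Reaction("R2b")
        a1 = model.metabolites.get_by_id("A1")
        a2 = model.metabolites.get_by_id("A2")
        bypass.add_metabolites({a1: -1, a2: 1})
        bypass.bounds = (0.0, truth["max_growth"] * 0.0005)
        model.add_reactions([bypass])
        report = vl.essentiality_screen(model, ["g2"])
        assert report.predicted_essential == {"g2"}  # 0.05% < 0.1% rule
        relaxed = vl.essentiality_screen(model, ["g2"], lethality_fraction=0.0001)
        assert relaxed.predicted_essential == set()

    def test_essentiality_mcc_modes(self, isozyme):
        model, truth = isozyme
        genes = sorted({g.id for g in model.genes}) + ["offmodel1", "offmodel2"]
        report = vl.essentiality_screen(model, genes)
        ceres = pd.Series(
            {g: (-2.0 if g in truth["essential_genes"] else 0.1) for g in genes}
        )
        experimental = vl.discretize_ceres(ceres, -0.75)
        assert vl.essentiality_mcc(report, experimental) == pytest.approx(1.0)
        assert vl.essentiality_mcc(report, experimental, model_genes_only=True) == pytest.approx(1.0)


class TestCeres:
    def test_threshold_grid_constant(self):
        assert vl.CERES_THRESHOLDS == (-1.5, -1.25, -1.0, -0.75, -0.5)
        assert np.allclose(np.diff(vl.CERES_THRESHOLDS), 0.25)

    def test_discretization(self):
        scores = pd.Series({"a": -2.0, "b": 0.0, "c": -0.75})
        calls = vl.discretize_ceres(scores, -0.75)
        assert calls.to_dict() == {"a": True, "b": False, "c": True}

    def test_missing_scores_excluded(self):
        scores = pd.Series({"a": -2.0, "b": np.nan})
        with pytest.warns(UserWarning, match="missing"):
            calls = vl.discretize_ceres(scores, -1.0)
        assert list(calls.index) == ["a"]


class TestMCC:
    def test_perfect_inverted_constant(self):
        y = [1, 0, 1, 1, 0, 0]
        assert vl.mcc(y, y) == pytest.approx(1.0)
        assert vl.mcc([1 - v for v in y], y) == pytest.approx(-1.0)
        assert vl.mcc([1] * 6, y) == 0.0

    def test_matches_sklearn_binary_and_multiclass(self):
        rng = np.random.default_rng(0)
        for n_classes in (2, 3, 4):
            for _ in range(20):
                a = rng.integers(0, n_classes, 40)
                p = rng.integers(0, n_classes, 40)
                assert vl.mcc(list(p), list(a)) == pytest.approx(
                    matthews_corrcoef(a, p), abs=1e-12
                )

    def test_three_class_hand_value(self):
        # counts: c=4 correct of s=6; p=(2,2,2), t=(3,2,1)
        actual = ["x", "x", "x", "y", "y", "z"]
        pred = ["x", "x", "y", "y", "z", "z"]
        c, s = 4.0, 6.0
        p = np.array([2.0, 2.0, 2.0])
        t = np.array([3.0, 2.0, 1.0])
        expected = (c * s - p @ t) / np.sqrt((s**2 - p @ p) * (s**2 - t @ t))
        assert vl.mcc(pred, actual) == pytest.approx(expected)

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(5)
        a = list(rng.integers(0, 3, 30))
        p = list(rng.integers(0, 3, 30))
        relabel = {0: "u", 1: "v", 2: "w"}
        assert vl.mcc(p, a) == pytest.approx(
            vl.mcc([relabel[x] for x in p], [relabel[x] for x in a])
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            vl.mcc([1, 0], [1])


class TestFluxCalls:
    def test_three_way_discretization(self):
        v = pd.Series({"r1": 5.0, "r2": -2.0, "r3": 0.0, "r4": 5e-7})
        calls = vl.discretize_flux(v, tol=1e-6)
        assert calls.to_dict() == {
            "r1": "forward_active", "r2": "reverse_active", "r3": "null", "r4": "null",
        }

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        v = pd.Series(rng.normal(0, 3, 20))
        calls = vl.discretize_flux(v)
        flipped = vl.discretize_flux(-v)
        swap = {"forward_active": "reverse_active", "reverse_active": "forward_active", "null": "null"}
        assert list(flipped) == [swap[c] for c in calls]

    def test_compare_identical_and_partial(self):
        calls = pd.Series(["forward_active"] * 9 + ["null"], index=[f"r{i}" for i in range(10)])
        assert vl.compare_flux_activity(calls, calls) == pytest.approx(1.0)
        measured = calls.copy()
        measured.iloc[0] = "null"
        got = vl.compare_flux_activity(calls, measured)
        expected = vl.mcc(list(calls), list(measured))
        assert got == pytest.approx(expected)

    def test_sign_map_reconciles_direction(self):
        pred = pd.Series({"r1": "forward_active", "r2": "reverse_active"})
        meas = pd.Series({"r1": "reverse_active", "r2": "forward_active"})
        sign = pd.Series({"r1": -1, "r2": -1})
        assert vl.compare_flux_activity(pred, meas, sign_map=sign) == pytest.approx(1.0)

    def test_disjoint_reactions_error(self):
        with pytest.raises(ValueError, match="overlap"):
            vl.compare_flux_activity(
                pd.Series({"a": "null"}), pd.Series({"b": "null"})
            )


class TestParameterImportance:
    @staticmethod
    def _sample_configs(n, rng):
        grid = rc.parameter_grid()
        idx = rng.choice(len(grid), size=n, replace=False)
        return [grid[i] for i in idx]

    def test_recovers_planted_algorithm_effect(self):
        rng = np.random.default_rng(0)
        configs = self._sample_configs(100, rng)
        scores = np.array(
            [0.1 * (c.algorithm == "tINIT") for c in configs]
        ) + rng.normal(0, 0.01, 100)
        table = vl.parameter_importance(configs, scores)
        row = table.loc["algorithm=tINIT"]
        assert abs(row["coef"] - 0.1) <= 3 * row["stderr"]

    def test_constant_scores_zero_coefficients(self):
        rng = np.random.default_rng(1)
        configs = self._sample_configs(60, rng)
        table = vl.parameter_importance(configs, np.full(60, 0.42))
        assert table.loc["intercept=", "coef"] == pytest.approx(0.42, abs=1e-8)
        others = table.drop(index="intercept=")
        assert np.allclose(others["coef"], 0.0, atol=1e-8)

    def test_single_valued_parameter_excluded(self):
        rng = np.random.default_rng(2)
        configs = [c for c in self._sample_configs(80, rng) if c.algorithm == "FASTCORE"]
        table = vl.parameter_importance(configs, np.arange(len(configs), dtype=float))
        assert not any(ix.startswith("algorithm=") for ix in table.index)

    def test_mismatched_lengths(self):
        rng = np.random.default_rng(3)
        configs = self._sample_configs(10, rng)
        with pytest.raises(ValueError, match="equal length"):
            vl.parameter_importance(configs, np.zeros(5))
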