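"""Base population, burn-in, breeding cycles and the experiment driver."""

import numpy as np
import pandas as pd
import pytest

from rrsim import (BREEDING_SIZES, SchemeConfig, cycle_gs, cycle_trad,
                   run_burnin, run_comparison, run_experiment)
from rrsim.exceptions import ConfigurationError
from rrsim.prediction import GramCache
from rrsim.schemes import N_TESTERS, _select_unique_parents


class TestSizeTable:
    @pytest.mark.parametrize("label,L,HI,HO,P", [
        ("I", 64, 4096, 384, 10),
        ("II", 128, 16384, 768, 20),
        ("III", 192, 36864, 1152, 30),
    ])
    def test_breeding_size_arithmetic(self, label, L, HI, HO, P):
        size = BREEDING_SIZES[label]
        assert (size.lines, size.hybrids_insilico, size.hybrids_obtained,
                size.parents) == (L, HI, HO, P)
        assert size.hybrids_insilico == size.lines ** 2
        assert size.hybrids_obtained == 2 * size.lines * N_TESTERS

    def test_unknown_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            SchemeConfig(scheme="BLUP_RRS")
        with pytest.raises(ConfigurationError):
            SchemeConfig(size="IV")


class TestUniqueParentWalk:
    def test_walk_fills_each_pool_in_rank_order(self):
        aside = np.array([1, 1, 2, 3, 4])
        bside = np.array([9, 8, 8, 7, 6])
        sel_a, sel_b = _select_unique_parents(aside, bside, 3)
        assert sel_a == [1, 2, 3]
        assert sel_b == [9, 8, 7]

    def test_exhausted_list_raises_when_strict(self):
        with pytest.raises(Exception):
            _select_unique_parents(np.array([1, 1]), np.array([2, 2]), 3)


class TestBasePopulation:
    def test_pool_composition(self, base_pools):
        pool_a, pool_b = base_pools
        for pool, label in [(pool_a, "A"), (pool_b, "B")]:
            assert len(pool.parents) == 10
            assert len(pool.testers) == N_TESTERS
            assert pool.parents.is_fully_inbred().all()
            assert pool.testers.is_fully_inbred().all()
            assert (pool.parents.pool == label).all()
        # pools are disjoint founder sets
        assert not np.intersect1d(pool_a.parents.ids, pool_b.parents.ids).size

    def test_testers_are_top_parents(self, base_pools):
        pool_a, _ = base_pools
        assert np.array_equal(pool_a.testers.ids, pool_a.parents.ids[:N_TESTERS])

    def test_pairwise_cross_count(self):
        from math import comb
        assert comb(384, 2) == 73_536
        assert comb(4, 2) == 6


@pytest.fixture(scope="module")
def burned(full_state, base_pools):
    gmap, _, arch = full_state
    pool_a, pool_b = base_pools
    return run_burnin(pool_a.copy(), pool_b.copy(), arch, gmap,
                      np.random.default_rng(5))


class TestBurnin:
    def test_training_set_is_final_cycle_hybrids(self, burned):
        _, _, ts0, data = burned
        assert len(ts0) == 384                        # size-I HO set
        assert set(ts0.tags) == {0}
        assert np.array_equal(ts0.y, data.phenotypes)

    def test_pool_invariants_after_burnin(self, burned):
        pool_a, pool_b, _, _ = burned
        assert len(pool_a.parents) == 10
        assert len(pool_b.parents) == 10
        assert pool_a.parents.is_fully_inbred().all()


class TestTradCycle:
    def test_testcross_count_and_static_testers(self, full_state, base_pools):
        gmap, _, arch = full_state
        pool_a, pool_b = base_pools
        rng = np.random.default_rng(31)
        tester_ids = pool_b.testers.ids.copy()
        a, b = pool_a.copy(), pool_b.copy()
        for cycle in (1, 2):
            a, b, data = cycle_trad(a, b, arch, gmap, BREEDING_SIZES["I"], rng,
                                    generation=cycle)
            assert len(data.true_values) == 384       # 2 pools x 64 lines x 3
            assert np.array_equal(b.testers.ids, tester_ids)

    def test_drift_selects_without_regard_to_phenotype(self, full_state, base_pools):
        gmap, _, arch = full_state
        pool_a, pool_b = base_pools
        a, b, data = cycle_trad(pool_a.copy(), pool_b.copy(), arch, gmap,
                                BREEDING_SIZES["I"], np.random.default_rng(32),
                                select_random=True, generation=1)
        # drift parents are not the phenotypically best ones
        order = np.argsort(-data.phenotypes)
        best_a, _ = _select_unique_parents(data.aside_ids[order],
                                           data.bside_ids[order], 10)
        assert set(a.parents.ids) != set(best_a)

    def test_tester_update_uses_parents_of_best_hybrids(self, full_state, base_pools):
        gmap, _, arch = full_state
        pool_a, pool_b = base_pools
        a, b, data = cycle_trad(pool_a.copy(), pool_b.copy(), arch, gmap,
                                BREEDING_SIZES["I"], np.random.default_rng(33),
                                update_testers=True, generation=1)
        assert np.array_equal(a.testers.ids, a.parents.ids[:N_TESTERS])
        assert np.array_equal(b.testers.ids, b.parents.ids[:N_TESTERS])


@pytest.fixture(scope="module")
def gs_inputs(full_state, base_pools):
    gmap, _, arch = full_state
    pool_a, pool_b = base_pools
    a, b, ts0, _ = run_burnin(pool_a.copy(), pool_b.copy(), arch, gmap,
                              np.random.default_rng(6))
    return gmap, arch, a, b, ts0


class TestGsCycle:
    def test_realized_set_is_top_of_prediction_grid(self, gs_inputs):
        gmap, arch, a, b, ts0 = gs_inputs
        size = BREEDING_SIZES["I"]
        na, nb, ts, data = cycle_gs(a.copy(), b.copy(), arch, gmap, size, ts0,
                                    "A", np.random.default_rng(41), generation=1,
                                    gram_cache=GramCache())
        assert len(data.true_values) == size.hybrids_obtained
        assert np.all(np.diff(data.predicted) <= 1e-12)  # descending predictions

    def test_parents_follow_prediction_ranking_not_phenotype(self, gs_inputs):
        gmap, arch, a, b, ts0 = gs_inputs
        size = BREEDING_SIZES["I"]
        na, nb, ts, data = cycle_gs(a.copy(), b.copy(), arch, gmap, size, ts0,
                                    "A", np.random.default_rng(42), generation=1,
                                    gram_cache=GramCache())
        # expected parents recomputed from the prediction-ranked hybrid list
        exp_a, exp_b = _select_unique_parents(data.aside_ids, data.bside_ids,
                                              size.parents)
        assert list(na.parents.ids) == exp_a
        assert list(nb.parents.ids) == exp_b
        # permuting phenotypes cannot change the parent choice
        assert not np.array_equal(np.argsort(-data.phenotypes),
                                  np.arange(len(data.phenotypes)))

    def test_training_set_window_advances(self, gs_inputs):
        gmap, arch, a, b, ts0 = gs_inputs
        size = BREEDING_SIZES["I"]
        ts = ts0
        cache = GramCache()
        rng = np.random.default_rng(43)
        aa, bb = a.copy(), b.copy()
        for cycle in range(1, 5):
            aa, bb, ts, _ = cycle_gs(aa, bb, arch, gmap, size, ts, "A", rng,
                                     generation=cycle, gram_cache=cache)
        assert set(ts.tags) == {2, 3, 4}


@pytest.fixture(scope="module")
def small_cfg(small_genome_config):
    return SchemeConfig(scheme="TRAD_RRS", size="I", n_cycles=2,
                        n_replicates=1, master_seed=99,
                        genome=small_genome_config, n_base_parents=60)


class TestExperimentDriver:
    def test_same_master_seed_is_bit_identical(self, small_cfg):
        df1 = run_experiment(small_cfg)
        df2 = run_experiment(small_cfg)
        pd.testing.assert_frame_equal(df1, df2)

    def test_arms_share_cycle_zero_state(self, small_cfg):
        df = run_comparison(small_cfg, [("TRAD_RRS", "I"), ("DRIFT_RRS", "I"),
                                        ("GS_A_RRS", "I")])
        c0 = df[df.cycle == 0]
        for metric in ["mean_hybrid_gv", "best_hybrid_gv", "va_pool_A", "fst"]:
            assert c0[metric].nunique() == 1

    def test_row_count_is_replicates_by_cycles(self, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, n_replicates=2, n_cycles=3)
        df = run_experiment(cfg)
        assert len(df) == 2 * (3 + 1)     # cycles 0..3 per replicate

    def test_config_yaml_roundtrip(self, tmp_path, small_cfg):
        path = tmp_path / "cfg.yaml"
        small_cfg.to_yaml(path)
        again = SchemeConfig.from_yaml(path)
        assert again == small_cfg
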