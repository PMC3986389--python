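"""Behavioural rules, exercised through deterministic micro-fixtures."""

import numpy as np
import pytest

from restensim.agents import (maybe_recruit_leukocytes, step_ec,
                              step_leukocytes, step_platelets, step_smc)
from restensim.config import RateTable
from restensim.cytokines import concentration_fields, window_counts
from restensim.fixtures import blank_state, fixture_names, make_fixture, \
    place_quanta
from restensim.state import INTIMA, LUMEN


def _zero_fields(state):
    z = np.zeros((state.grid_size, state.grid_size))
    return z, z.copy()


class TestPlatelets:
    def test_activation_next_to_injury(self):
        state, exp = make_fixture("platelet_activation")
        step_platelets(state)
        assert len(state.activated_platelets) == exp["expect_activated"]
        assert len(state.latent_platelets) == 0

    def test_latent_platelet_without_trigger_stays_latent(self):
        state, exp = make_fixture("platelet_inert")
        for _ in range(10):
            step_platelets(state)
        assert len(state.activated_platelets) == exp["expect_activated"]
        assert len(state.latent_platelets) == 1

    def test_activated_platelets_do_not_move(self):
        state, _ = make_fixture("neutrophil_attach")
        x0 = state.activated_platelets.x.copy()
        for _ in range(5):
            step_platelets(state)
        assert (state.activated_platelets.x == x0).all()

    def test_lifespan_draw_between_20_and_40_steps(self):
        # 5-10 days at 4 steps/day
        state = blank_state(grid_size=21, platelet_pool=300)
        state.lumen_mask[:] = True
        state.ring_mask[:] = False
        from restensim.geometry import _replenish_platelets
        _replenish_platelets(state, initial=True)
        spans = state.latent_platelets.lifespan
        assert spans.min() >= 20 and spans.max() <= 40
        assert len(spans) == 300

    def test_expired_platelets_replaced_by_fresh_latents(self):
        state = blank_state(grid_size=21, platelet_pool=5,
                            platelet_influx_per_step=5)
        state.lumen_mask[:] = True
        state.latent_platelets.add([10] * 5, [10] * 5, [1] * 5)
        step_platelets(state)   # originals reach their lifespan
        step_platelets(state)   # ... expire, and the influx refills the pool
        assert len(state.latent_platelets) == 5
        assert state.latent_platelets.age.max() <= 1  # all freshly arrived


class TestRecruitment:
    def test_zero_field_recruits_nothing(self):
        state = blank_state()
        state.smc_region[:] = INTIMA
        tgf = window_counts(state.local_counts("tgfb"))
        assert maybe_recruit_leukocytes(state, tgf) == 0
        assert len(state.monocytes) == 0

    def test_threshold_crossing_spawns_both_kinds(self):
        state = blank_state(grid_size=21, recruit_rate=1.0)
        state.smc_region[10, 10] = INTIMA
        place_quanta(state, "tgfb", 10, 10, 1)
        tgf = window_counts(state.local_counts("tgfb"))
        assert maybe_recruit_leukocytes(state, tgf) == 1
        assert len(state.monocytes) == 1
        assert len(state.neutrophils) == 1

    def test_spawn_count_matches_rate_times_steps(self):
        state = blank_state(grid_size=21, recruit_rate=1.0)
        state.smc_region[10, 10] = INTIMA
        place_quanta(state, "tgfb", 10, 10, 1)
        tgf = window_counts(state.local_counts("tgfb"))
        for _ in range(10):
            maybe_recruit_leukocytes(state, tgf)
        assert len(state.monocytes) == 10


class TestLeukocytes:
    def test_migration_speed_is_7_units_per_step(self):
        rates = RateTable()
        assert rates.leukocyte_migration_units_per_step == pytest.approx(7.2)

    def test_neutrophil_attaches_to_thrombus(self):
        state, exp = make_fixture("neutrophil_attach")
        step_leukocytes(state)
        assert bool(state.neutrophils.flag[0]) is exp["expect_attached"]
        x0 = state.neutrophils.x.copy()
        step_leukocytes(state)
        assert (state.neutrophils.x == x0).all()  # attached = immobile

    def test_monocyte_matures_into_macrophage_in_tissue(self):
        state, exp = make_fixture("monocyte_maturation")
        step_leukocytes(state)
        assert len(state.macrophages) == exp["expect_macrophages"]
        assert len(state.monocytes) == exp["expect_monocytes"]

    def test_lifespans_in_steps(self):
        rates = RateTable()
        assert rates.lifespan_steps(rates.monocyte_lifespan_days) == 12
        assert rates.lifespan_steps(rates.macrophage_lifespan_days) == 180
        assert rates.lifespan_steps(rates.neutrophil_lifespan_days) == 20

    def test_expired_leukocytes_removed(self):
        state = blank_state()
        state.monocytes.add([4], [4], [2])
        for _ in range(3):
            step_leukocytes(state)
        assert len(state.monocytes) == 0


class TestSMC:
    def test_division_probability_from_doubling_time(self):
        # (1+p)^5 = 2 for a 30 h doubling at 6 h steps
        p = RateTable().division_prob_per_step
        assert p == pytest.approx(2 ** 0.2 - 1)
        assert (1 + p) ** 5 == pytest.approx(2.0)

    def test_migration_step_is_2_4_units(self):
        assert RateTable().smc_migration_units_per_step == pytest.approx(2.4)

    def test_no_divisions_below_threshold(self):
        state, exp = make_fixture("threshold_below")
        for _ in range(100):
            tgf, tnf = concentration_fields(state)
            step_smc(state, tgf, tnf)
        assert state.smc[exp["patch"]] == exp["smc_before"]

    def test_divisions_fire_at_threshold(self):
        state, exp = make_fixture("threshold_at")
        tgf, tnf = concentration_fields(state)
        assert tgf[exp["patch"]] == pytest.approx(3.0, rel=1e-3)
        grew = False
        for _ in range(100):
            step_smc(state, tgf, tnf)
            if state.smc[exp["patch"]] > exp["smc_before"]:
                grew = True
                break
        assert grew

    def test_apoptosis_cap_15_percent(self):
        state, exp = make_fixture("apoptosis_cap")
        tgf, tnf = concentration_fields(state)
        assert tnf[exp["patch"]] == pytest.approx(4.0, rel=1e-3)
        step_smc(state, tgf, tnf)
        deaths = exp["smc_before"] - state.smc.sum()  # crowding only relocates
        assert 0 <= deaths <= exp["max_deaths"]

    def test_crowding_displaces_surplus_lumen_ward(self):
        state, exp = make_fixture("crowding")
        tgf, tnf = _zero_fields(state)
        step_smc(state, tgf, tnf)
        assert state.smc[exp["patch"]] == exp["expect_remaining"]
        assert state.smc.sum() == exp["expect_remaining"] + exp["expect_displaced"]
        # the displaced cell sits closer to the vessel axis
        xs, ys = np.nonzero(state.smc)
        r = np.hypot(xs - state.center[0], ys - state.center[1])
        assert r.min() < np.hypot(exp["patch"][0] - state.center[0],
                                  exp["patch"][1] - state.center[1])

    def test_capacity_never_exceeded_after_step(self):
        state = blank_state(grid_size=15)
        state.smc_region[:] = INTIMA
        state.lumen_mask[:] = False
        state.smc[6:9, 6:9] = 14
        place_quanta(state, "tgfb", 7, 7, 30)
        for _ in range(10):
            tgf, tnf = concentration_fields(state)
            step_smc(state, tgf, tnf)
        assert state.smc.max() <= state.rates.smc_patch_capacity

    def test_zero_tgfb_population_non_increasing(self):
        state = blank_state()
        state.smc_region[:] = INTIMA
        state.lumen_mask[:] = False
        state.smc[2:7, 2:7] = 5
        total0 = state.smc.sum()
        tgf, tnf = _zero_fields(state)
        for _ in range(50):
            step_smc(state, tgf, tnf)
        assert state.smc.sum() <= total0


class TestEC:
    def test_frontier_tracks_smc_advance(self):
        state, exp = make_fixture("ec_frontier")
        col = exp["front_column"]
        assert state.ec[:, col - 1].any()
        # advance the front one column toward the open side
        state.smc[:, col - 1] = 3
        tgf, tnf = _zero_fields(state)
        step_ec(state, tgf, tnf)
        assert state.ec[:, col - 2].any()
        assert not state.ec[:, col - 1].any()  # old lining patch is now tissue

    def test_fixed_point_without_changes(self):
        state, exp = make_fixture("ec_frontier")
        before = state.ec.copy()
        tgf, tnf = _zero_fields(state)
        state.rng = np.random.default_rng(0)
        # disable spontaneous turnover to probe the pure re-seating rule
        state.rates.ec_turnover_prob = 0.0
        step_ec(state, tgf, tnf)
        assert (state.ec == before).all()

    def test_full_occlusion_signalled(self):
        state = blank_state()
        state.smc[:, :] = 5  # tissue everywhere, axis included
        tgf, tnf = _zero_fields(state)
        assert step_ec(state, tgf, tnf) is True
        assert state.occluded


class TestImmobileAgents:
    def test_struts_and_plaque_never_change(self):
        state, exp = make_fixture("strut_immobility")
        strut0, plaque0 = state.strut.copy(), state.plaque.copy()
        tgf, tnf = _zero_fields(state)
        for _ in range(25):
            step_platelets(state)
            step_leukocytes(state)
            step_smc(state, tgf, tnf)
            step_ec(state, tgf, tnf)
        assert (state.strut == strut0).all()
        assert (state.plaque == plaque0).all()


def test_every_fixture_builds():
    for name in fixture_names():
        state, expectations = make_fixture(name)
        assert state.grid_size >= 9
        assert isinstance(expectations, dict)


def test_unknown_fixture_rejected():
    with pytest.raises(KeyError):
        make_fixture("not-a-fixture")
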