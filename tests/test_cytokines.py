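"""Cytokine release, transport, decay and concentration measurement."""

import numpy as np
import pytest

from restensim.config import PATCH_MM, RateTable
from restensim.cytokines import (diffuse_and_decay, hoop_stress_factor,
                                 local_concentration, release_tgfb,
                                 release_tnfa, serum_concentration,
                                 window_counts)
from restensim.fixtures import blank_state, place_quanta


@pytest.mark.parametrize("r, t, expected", [
    (1.45, 1.45, 1.0),      # normalised at the default 1:1 geometry
    (1.0, 1.0, 1.0),
    (1.16, 1.45, 0.8),      # radius down 20 % at fixed wall
    (2.0, 1.0, 2.0),
])
def test_hoop_stress_factor(r, t, expected):
    assert hoop_stress_factor(r, t) == pytest.approx(expected)


def test_hoop_stress_rejects_nonpositive():
    with pytest.raises(ValueError):
        hoop_stress_factor(0.0, 1.0)


class TestLocalConcentration:
    quantum = RateTable().quantum_pg
    c = RateTable().patch_thickness_mm

    def test_empty_field_is_zero(self):
        grid = np.zeros((9, 9), dtype=int)
        assert local_concentration(grid, self.quantum, self.c).max() == 0.0

    def test_single_quantum_is_half_ng_ml(self):
        # with C = 1.067 mm: 0.012 pg / (1.067 x 9 x 0.0025 mm^3) = 0.5 ng/ml
        grid = np.zeros((9, 9), dtype=int)
        grid[4, 4] = 1
        conc = local_concentration(grid, self.quantum, self.c)
        assert conc[4, 4] == pytest.approx(0.5, rel=1e-3)

    def test_six_quanta_reach_proliferation_threshold(self):
        grid = np.zeros((9, 9), dtype=int)
        grid[4, 4] = 6
        conc = local_concentration(grid, self.quantum, self.c)
        assert conc[4, 4] == pytest.approx(3.0, rel=1e-3)

    def test_uniform_field_matches_analytic_value_on_interior(self):
        grid = np.full((9, 9), 2, dtype=int)
        conc = local_concentration(grid, self.quantum, self.c)
        expected = 18 * self.quantum / (self.c * 9 * PATCH_MM**2)
        assert np.allclose(conc[1:-1, 1:-1], expected)

    def test_edge_patch_uses_truncated_volume(self):
        # a corner window holds 4 patches; concentration scales with 1/V
        grid = np.full((9, 9), 1, dtype=int)
        conc = local_concentration(grid, self.quantum, self.c)
        corner = 4 * self.quantum / (self.c * 4 * PATCH_MM**2)
        assert conc[0, 0] == pytest.approx(corner)


def test_serum_concentration_scales_linearly():
    assert serum_concentration(0, 0.012, 1.067, 150) == 0.0
    one = serum_concentration(100, 0.012, 1.067, 150)
    two = serum_concentration(200, 0.012, 1.067, 150)
    assert two == pytest.approx(2 * one)


class TestRelease:
    def test_no_cells_no_release(self):
        state = blank_state()
        assert release_tgfb(state) == 0
        assert release_tnfa(state) == 0

    def test_injured_cells_release_tgfb(self):
        state = blank_state(release_fraction=1.0, injury_release_factor=1.0)
        state.lumen_mask[:] = False
        state.smc[4, 4] = 2
        state.injured[4, 4] = True
        emitted = release_tgfb(state)
        assert emitted == 2  # prob 1: one quantum per exposed cell per step
        assert state.tgfb_emitted_this_step == 2

    def test_release_gated_by_hoop_stress(self):
        state = blank_state(release_fraction=1.0)
        state.lumen_mask[:] = False
        state.smc[4, 4] = 2
        state.injured[4, 4] = True
        state.current_min_ld_mm = 0.5 * state.config.lumen_diameter_mm  # deep narrowing
        assert release_tgfb(state) == 0

    def test_uninjured_quiet_tissue_does_not_release(self):
        state = blank_state(release_fraction=1.0)
        state.lumen_mask[:] = False
        state.smc[4, 4] = 5  # no injury anywhere, monolayer intact
        assert release_tgfb(state) == 0

    def test_release_autoregulation_shuts_down_saturated_patch(self):
        state = blank_state(release_fraction=1.0, injury_release_factor=1.0,
                            tgfb_inhibition_ng_ml=3.0)
        state.lumen_mask[:] = False
        state.smc[4, 4] = 2
        state.injured[4, 4] = True
        place_quanta(state, "tgfb", 4, 4, 10)  # 5 ng/ml locally
        assert release_tgfb(state) == 0

    def test_tnfa_requires_tgfb_presence(self):
        state = blank_state(tnfa_release_fraction=1.0)
        state.monocytes.add([4], [4], [12])
        assert release_tnfa(state) == 0
        place_quanta(state, "tgfb", 4, 4, 1)
        assert release_tnfa(state) == 1

    def test_tnfa_rate_identical_across_leukocyte_kinds(self):
        counts = {}
        for kind in ("monocytes", "neutrophils", "macrophages"):
            state = blank_state(seed=7, tnfa_release_fraction=1.0)
            place_quanta(state, "tgfb", 4, 4, 1)
            getattr(state, kind).add([4] * 3, [4] * 3, [100] * 3)
            counts[kind] = release_tnfa(state)
        assert counts["monocytes"] == counts["neutrophils"] \
            == counts["macrophages"] == 3


class TestDiffusionAndDecay:
    def test_mass_conserved_without_decay(self):
        state = blank_state(cytokine_lifetime_steps=10_000,
                            tgfb_clearance_ng_ml=0.0)
        state.lumen_mask[:] = False
        place_quanta(state, "tgfb", 4, 4, 50)
        for _ in range(20):
            diffuse_and_decay(state)
        m = state.mass["tgfb"]
        assert len(state.tgfb) + m["decayed"] + m["consumed"] == m["emitted"]
        assert len(state.tgfb) == 50

    def test_pulse_expires_after_lifetime(self):
        state = blank_state(cytokine_lifetime_steps=4)
        place_quanta(state, "tgfb", 4, 4, 25)
        for _ in range(5):
            diffuse_and_decay(state)
        assert len(state.tgfb) == 0
        assert state.mass["tgfb"]["decayed"] + state.mass["tgfb"]["consumed"] == 25

    def test_single_step_displacement_at_most_one_patch(self):
        state = blank_state(grid_size=15, cytokine_lifetime_steps=100)
        state.lumen_mask[:] = False
        place_quanta(state, "tgfb", 7, 7, 200)
        diffuse_and_decay(state)
        d = np.maximum(np.abs(state.tgfb.x - 7), np.abs(state.tgfb.y - 7))
        assert d.max() <= 1

    def test_random_walk_msd_matches_enumeration(self):
        """One step over the uniform 9-neighbourhood: E[dx^2] = 2/3, so the
        mean squared displacement is E[dx^2 + dy^2] = 4/3."""
        state = blank_state(grid_size=31, seed=3, cytokine_lifetime_steps=10_000,
                            tgfb_clearance_ng_ml=0.0)
        state.lumen_mask[:] = False
        place_quanta(state, "tgfb", 15, 15, 10_000)
        diffuse_and_decay(state)
        msd = np.mean((state.tgfb.x - 15.0) ** 2 + (state.tgfb.y - 15.0) ** 2)
        assert msd == pytest.approx(4.0 / 3.0, rel=0.05)

    def test_clearance_bounds_local_concentration(self):
        state = blank_state(grid_size=15, cytokine_lifetime_steps=10_000,
                            tgfb_clearance_ng_ml=2.0)
        state.lumen_mask[:] = False
        place_quanta(state, "tgfb", 7, 7, 300)
        for _ in range(3):
            diffuse_and_decay(state)
        win = window_counts(state.tgfb.counts(state.grid_size))
        # 2.0 ng/ml = 4 quanta per window, allow sampling slack
        assert win.max() <= 10
        m = state.mass["tgfb"]
        assert len(state.tgfb) + m["decayed"] + m["consumed"] == m["emitted"]


def test_injury_factor_monotone_in_peak_field():
    """A larger injury release factor never lowers the peak local TGF-beta
    (paired runs, common seed)."""
    peaks = []
    for factor in (1.0, 3.0):
        state = blank_state(seed=11, release_fraction=0.3,
                            injury_release_factor=factor,
                            tgfb_clearance_ng_ml=50.0,
                            tgfb_inhibition_ng_ml=50.0)
        state.lumen_mask[:] = False
        state.smc[3:6, 3:6] = 3
        state.injured[4, 4] = True
        peak = 0.0
        for _ in range(30):
            release_tgfb(state)
            diffuse_and_decay(state)
            win = window_counts(state.tgfb.counts(state.grid_size))
            peak = max(peak, win.max() * state.rates.ng_ml_per_local_quantum)
        peaks.append(peak)
    assert peaks[1] >= peaks[0]
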