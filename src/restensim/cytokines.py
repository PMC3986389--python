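"""Cytokine release, diffusion, decay and concentration measurement.

Both species (TGF-beta, anti-inflammatory; TNF-alpha, pro-inflammatory) are
represented as discrete quanta of 0.012 pg — one nominal emission per cell
per 6 h step, matching a release rate of 0.02 pg per 10 hours per cell.
Concentrations are measured over a patch and its 8 neighbours with the
volume V = C x AP (C = 1.067 mm), which makes one local quantum worth
0.5 ng/ml, so the 3 ng/ml proliferation and 4 ng/ml apoptosis sensitivities
correspond to 6 and 8 local quanta.

TGF-beta release is stretch-modulated: the thin-wall hoop stress ratio r/t
(normalised to 1 at the default 1:1 radius:wall geometry) scales the
per-cell emission probability and, below a calibrated cutoff, shuts
stretch-driven release off entirely.  That cutoff is what ends TGF-beta
release — and hence defines lumen-diameter stabilization — in runs where
injury-driven signalling would otherwise persist.
"""

from __future__ import annotations

import numpy as np

from .config import PATCH_MM
from .state import Particles, SimulationState

from ._grid import box_sum3, dilate8, max3, window_sizes as _cached_window_sizes


def hoop_stress_factor(lumen_radius_mm: float, wall_thickness_mm: float) -> float:
    """Thin-wall (Laplace) hoop stress ratio r/t, normalised to 1 at r = t."""
    if lumen_radius_mm <= 0 or wall_thickness_mm <= 0:
        raise ValueError("radius and wall thickness must be positive")
    return lumen_radius_mm / wall_thickness_mm


def window_counts(count_grid: np.ndarray) -> np.ndarray:
    """Sum of counts over each patch's 9-patch local environment (truncated
    at the grid edge)."""
    return box_sum3(count_grid)


def window_sizes(grid_size: int) -> np.ndarray:
    return _cached_window_sizes((grid_size, grid_size))


def local_concentration(count_grid: np.ndarray, quantum_pg: float,
                        patch_thickness_mm: float) -> np.ndarray:
    """Local concentration (ng/ml) on every patch: window count x quantum mass
    over V = C x n x a^2, with the window size n reduced at grid edges."""
    counts = window_counts(count_grid)
    n = window_sizes(count_grid.shape[0])
    volume_mm3 = patch_thickness_mm * n * PATCH_MM**2
    return counts * quantum_pg / volume_mm3  # pg/mm^3 == ng/ml


def serum_concentration(total_quanta: int, quantum_pg: float,
                        patch_thickness_mm: float, grid_size: int) -> float:
    """Grid-wide mass over the whole-section reference volume (ng/ml)."""
    volume_mm3 = patch_thickness_mm * grid_size * grid_size * PATCH_MM**2
    return total_quanta * quantum_pg / volume_mm3


def _emit(state: SimulationState, particles: Particles, key: str,
          emitter_counts: np.ndarray, prob: np.ndarray | float) -> int:
    """Bernoulli emission of quanta from per-patch emitter counts."""
    if np.isscalar(prob):
        p = np.full_like(emitter_counts, float(prob), dtype=np.float64)
    else:
        p = np.asarray(prob, dtype=np.float64)
    np.clip(p, 0.0, 1.0, out=p)
    occupied = emitter_counts > 0
    if not np.any(occupied):
        return 0
    born = np.zeros_like(emitter_counts)
    born[occupied] = state.rng.binomial(emitter_counts[occupied], p[occupied])
    total = int(born.sum())
    if total:
        xs, ys = np.nonzero(born)
        reps = born[xs, ys]
        particles.add(np.repeat(xs, reps), np.repeat(ys, reps),
                      state.rates.cytokine_lifetime_steps)
        state.mass[key]["emitted"] += total
    return total


def tgfb_release_active(state: SimulationState) -> bool:
    """Stretch gate: TGF-beta release requires hoop stress above the cutoff.

    The live lumen radius comes from the running minimum-diameter
    measurement; the wall thickness is the initial (stent-fixed) thickness.
    Greater procedural injury sustains release at lower stress.
    """
    factor = hoop_stress_factor(state.current_min_ld_mm / 2.0,
                                state.config.wall_thickness())
    return factor * state.injury_severity() > state.rates.hoop_gate


def release_tgfb(state: SimulationState) -> int:
    """One release round: activated platelets plus SMCs/ECs on or next to
    unhealed injuries or endothelial gaps emit TGF-beta quanta.

    Per-cell emission probability = release_fraction x injury factor x hoop
    stress factor x global injury severity, capped at 1 (the nominal Table
    rate of one quantum per cell-step).
    """
    rates = state.rates
    state.tgfb_emitted_this_step = 0
    if not tgfb_release_active(state):
        return 0
    if not np.any(state.injured):
        # release is injury-driven: a fully healed vessel stops secreting,
        # even where the monolayer is still re-arranging
        return 0
    hoop = hoop_stress_factor(state.current_min_ld_mm / 2.0,
                              state.config.wall_thickness())
    severity = state.injury_severity()
    base = rates.release_fraction * hoop * severity

    gaps = state.ring_mask & ~state.ec
    injury_zone = dilate8(state.injured)
    gap_zone = dilate8(gaps)
    active = injury_zone | gap_zone

    # SMCs and the endothelial lining at the wound surface; only a few
    # cells per patch secrete into the section plane (exposure cap)
    emitters = np.where(active, np.minimum(state.smc, rates.max_emitters_per_patch), 0)
    emitters = emitters.astype(np.int64) + (active & state.ec).astype(np.int64)
    prob = np.full(emitters.shape, base, dtype=np.float64)
    prob[injury_zone] = base * rates.injury_release_factor
    # autoregulation: secretion shuts down where the local concentration is
    # already high (product inhibition), bounding the field
    saturated = window_counts(state.local_counts("tgfb")) * \
        rates.ng_ml_per_local_quantum >= rates.tgfb_inhibition_ng_ml * severity
    prob[saturated] = 0.0
    total = _emit(state, state.tgfb, "tgfb", emitters, prob)

    # activated platelets (the thrombus) release while they live
    if len(state.activated_platelets):
        plt_counts = np.minimum(state.activated_platelets.counts(state.grid_size),
                                rates.max_emitters_per_patch)
        total += _emit(state, state.tgfb, "tgfb", plt_counts,
                       min(1.0, base * rates.injury_release_factor))
    state.tgfb_emitted_this_step = total
    if total > 0:
        state.last_tgfb_emission_step = state.step_index
    return total


def release_tnfa(state: SimulationState) -> int:
    """Monocytes, neutrophils and macrophages emit TNF-alpha (same nominal
    rate for all three kinds) wherever local TGF-beta is present."""
    tgf_local = window_counts(state.local_counts("tgfb"))
    emitters = np.zeros((state.grid_size, state.grid_size), dtype=np.int64)
    for kind in (state.monocytes, state.neutrophils, state.macrophages):
        if len(kind):
            emitters += kind.counts(state.grid_size)
    emitters[tgf_local <= 0] = 0
    severity = state.injury_severity()
    prob = np.full(emitters.shape, state.rates.tnfa_release_fraction)
    saturated = window_counts(state.local_counts("tnfa")) * \
        state.rates.ng_ml_per_local_quantum >= \
        state.rates.tnfa_inhibition_ng_ml * severity
    prob[saturated] = 0.0
    return _emit(state, state.tnfa, "tnfa", emitters, prob)


def diffuse_and_decay(state: SimulationState) -> None:
    """Unbiased one-patch random walk and finite-lifetime clearance.

    Quanta move to one of the 9 patches of their local environment (staying
    put included) but may not drift into the open lumen interior — tissue
    and the lumen-adjacent boundary remain accessible.  Quanta older than
    the configured lifetime are removed; mass bookkeeping stays exact.
    """
    interior = state.lumen_mask & ~state.ring_mask  # open blood-flow region
    rates = state.rates
    severity = state.injury_severity()  # saturable uptake: inflamed tissue clears less
    clearance = {"tgfb": rates.tgfb_clearance_ng_ml * severity,
                 "tnfa": rates.tnfa_clearance_ng_ml * severity}
    for key, particles in (("tgfb", state.tgfb), ("tnfa", state.tnfa)):
        if not len(particles):
            continue
        particles.age += 1
        expired = particles.age > rates.cytokine_lifetime_steps
        n_dead = int(expired.sum())
        if n_dead:
            state.mass[key]["decayed"] += n_dead
            particles.keep(~expired)
        n = len(particles)
        if n == 0:
            continue
        dx = state.rng.integers(-1, 2, size=n)
        dy = state.rng.integers(-1, 2, size=n)
        nx = np.clip(particles.x + dx, 0, state.grid_size - 1)
        ny = np.clip(particles.y + dy, 0, state.grid_size - 1)
        blocked = interior[nx, ny]
        particles.x = np.where(blocked, particles.x, nx)
        particles.y = np.where(blocked, particles.y, ny)

        # receptor-mediated uptake: tissue consumes cytokine in excess of
        # the saturation level, bounding local concentrations
        level = clearance[key]
        if level > 0 and len(particles):
            counts = particles.counts(state.grid_size)
            win = window_counts(counts)
            cap_quanta = level / rates.ng_ml_per_local_quantum
            over = win > cap_quanta
            if np.any(over):
                # thin against the highest window a quantum contributes to,
                # or rim quanta keep re-filling the hot window
                wmax = max3(win)
                w = wmax[particles.x, particles.y]
                p_keep = np.where(w > cap_quanta, cap_quanta / w, 1.0)
                keep = state.rng.random(len(particles)) < p_keep
                state.mass[key]["consumed"] = state.mass[key].get("consumed", 0) \
                    + int((~keep).sum())
                particles.keep(keep)


def concentration_fields(state: SimulationState):
    """Local TGF-beta and TNF-alpha concentration grids (ng/ml)."""
    q = state.rates.quantum_pg
    c = state.rates.patch_thickness_mm
    tgf = local_concentration(state.local_counts("tgfb"), q, c)
    tnf = local_concentration(state.local_counts("tnfa"), q, c)
    return tgf, tnf
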