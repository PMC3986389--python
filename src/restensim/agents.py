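"""Per-step stochastic behavioural rules for every cellular agent type.

Platelets circulate and form thrombus at injuries; leukocytes are recruited
by TGF-beta, chemotax toward wounds at 1 um/min, attach to thrombus
(neutrophils) or mature into macrophages (monocytes); smooth muscle cells
divide under TGF-beta, die under TNF-alpha (capped at 15 % of the local
population per exposure), migrate lumen-ward from the media, and overflow
crowded patches toward the lumen; the endothelial lining tracks the
advancing tissue frontier as a single-cell monolayer.
"""

from __future__ import annotations



import numpy as np
from scipy import ndimage

from ._grid import dilate8
from .config import STEPS_PER_DAY
from .state import INTIMA, LUMEN, MEDIA, Particles, SimulationState

_STRUCT8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# platelets
# ---------------------------------------------------------------------------

def step_platelets(state: SimulationState) -> None:
    """Random walk of latent platelets, contact activation, thrombus growth,
    lifespan turnover with replenishment of the circulating pool."""
    from .geometry import _replenish_platelets

    lp, ap = state.latent_platelets, state.activated_platelets

    # age and cull both pools; the circulating supply is topped back up below
    for pool in (lp, ap):
        if len(pool):
            pool.age += 1
            pool.keep(pool.age <= pool.lifespan)

    if len(lp):
        n = len(lp)
        dx = state.rng.integers(-1, 2, size=n)
        dy = state.rng.integers(-1, 2, size=n)
        nx = np.clip(lp.x + dx, 0, state.grid_size - 1)
        ny = np.clip(lp.y + dy, 0, state.grid_size - 1)
        ok = state.lumen_mask[nx, ny]
        lp.x = np.where(ok, nx, lp.x)
        lp.y = np.where(ok, ny, lp.y)

        # activation: injury site, or wound-anchored activated platelet, in
        # the local environment (free-floating aggregates wash away and do
        # not seed new activation)
        trigger = state.injured.copy()
        if len(ap):
            near_injury = dilate8(state.injured)
            anchored = near_injury[ap.x, ap.y]
            trigger[ap.x[anchored], ap.y[anchored]] = True
        near = dilate8(trigger)
        hit = near[lp.x, lp.y]
        if np.any(hit):
            ap.add(lp.x[hit], lp.y[hit], lp.lifespan[hit] - lp.age[hit])
            lp.keep(~hit)

    _replenish_platelets(state)


# ---------------------------------------------------------------------------
# leukocytes
# ---------------------------------------------------------------------------

def maybe_recruit_leukocytes(state: SimulationState, tgf_window_counts: np.ndarray) -> int:
    """Spawn circulating monocytes and neutrophils while intimal TGF-beta
    exceeds the femtomolar-scale detection threshold."""
    rates = state.rates
    intimal = (state.smc_region == INTIMA) | ((state.smc_region == LUMEN) & (state.smc > 0))
    if not np.any(tgf_window_counts[intimal] >= rates.recruitment_threshold_quanta):
        return 0
    rate = rates.recruit_rate
    n = int(rate) + int(state.rng.random() < (rate - int(rate)))
    if n <= 0:
        return 0
    interior = state.lumen_mask & ~state.ring_mask
    idx = np.flatnonzero(interior.ravel())
    if idx.size == 0:
        return 0
    for pool, days in ((state.monocytes, rates.monocyte_lifespan_days),
                       (state.neutrophils, rates.neutrophil_lifespan_days)):
        take = state.rng.choice(idx, size=n, replace=True)
        x, y = np.unravel_index(take, state.lumen_mask.shape)
        pool.add(x, y, rates.lifespan_steps(days))
    return n


def _chemotax(state: SimulationState, pool: Particles, mobile: np.ndarray,
              target_idx, passable: np.ndarray, substeps: int) -> None:
    """Biased random walk: `substeps` one-patch moves, each aimed at the
    nearest wound with probability chemotaxis_bias, otherwise random."""
    bias = state.rates.chemotaxis_bias
    ix, iy = target_idx
    for _ in range(substeps):
        if not np.any(mobile):
            break
        x, y = pool.x, pool.y
        tx = ix[x, y].astype(np.float64) - x
        ty = iy[x, y].astype(np.float64) - y
        norm = np.hypot(tx, ty)
        norm[norm == 0] = 1.0
        aimed_dx = np.rint(tx / norm).astype(np.int64)
        aimed_dy = np.rint(ty / norm).astype(np.int64)
        rand_dx = state.rng.integers(-1, 2, size=len(pool))
        rand_dy = state.rng.integers(-1, 2, size=len(pool))
        aim = state.rng.random(len(pool)) < bias
        dx = np.where(aim, aimed_dx, rand_dx)
        dy = np.where(aim, aimed_dy, rand_dy)
        nx = np.clip(x + dx, 0, state.grid_size - 1)
        ny = np.clip(y + dy, 0, state.grid_size - 1)
        ok = mobile & passable[nx, ny]
        pool.x = np.where(ok, nx, x)
        pool.y = np.where(ok, ny, y)


def step_leukocytes(state: SimulationState) -> None:
    """Move monocytes/neutrophils/macrophages 360 um per step toward the
    nearest wound; neutrophils attach to thrombus; monocytes crossing into
    wall tissue mature into macrophages, a fraction of which take up
    residence at the nearest stent strut (foreign-body response)."""
    rates = state.rates
    substeps = int(round(rates.leukocyte_migration_units_per_step))  # 7 patches ~ 7.2 units

    # wounds: unhealed injuries and the thrombus
    targets = state.injured.copy()
    ap = state.activated_platelets
    if len(ap):
        targets[ap.x, ap.y] = True
    if np.any(targets):
        _, target_idx = ndimage.distance_transform_edt(~targets, return_indices=True)
    else:
        target_idx = (state.xx, state.yy)  # no wound: aim at self = pure random walk

    passable = ~state.strut & ~state.plaque

    for pool in (state.monocytes, state.neutrophils, state.macrophages):
        if len(pool):
            pool.age += 1
            pool.keep(pool.age <= pool.lifespan)

    if len(state.neutrophils):
        _chemotax(state, state.neutrophils, ~state.neutrophils.flag, target_idx,
                  passable, substeps)
        if len(ap):
            thrombus = np.zeros((state.grid_size, state.grid_size), dtype=bool)
            thrombus[ap.x, ap.y] = True
            near = dilate8(thrombus)
            state.neutrophils.flag |= near[state.neutrophils.x, state.neutrophils.y]

    if len(state.monocytes):
        mono = state.monocytes
        _chemotax(state, mono, np.ones(len(mono), dtype=bool), target_idx,
                  passable, substeps)
        in_tissue = (state.smc[mono.x, mono.y] > 0) | np.isin(
            state.smc_region[mono.x, mono.y], (INTIMA, MEDIA))
        if np.any(in_tissue):
            x, y = mono.x[in_tissue], mono.y[in_tissue]
            n_new = x.size
            at_strut = state.rng.random(n_new) < rates.macrophage_strut_fraction
            if np.any(at_strut) and np.any(state.strut):
                _, strut_idx = ndimage.distance_transform_edt(
                    ~state.strut, return_indices=True)
                sx = strut_idx[0][x[at_strut], y[at_strut]]
                sy = strut_idx[1][x[at_strut], y[at_strut]]
                x = np.concatenate([sx, x[~at_strut]])
                y = np.concatenate([sy, y[~at_strut]])
                flags = np.concatenate([np.ones(int(at_strut.sum()), bool),
                                        np.zeros(int((~at_strut).sum()), bool)])
            else:
                flags = np.zeros(n_new, dtype=bool)
            state.macrophages.add(x, y, rates.lifespan_steps(
                rates.macrophage_lifespan_days), flags)
            mono.keep(~in_tissue)

    if len(state.macrophages):
        _chemotax(state, state.macrophages, ~state.macrophages.flag, target_idx,
                  passable, substeps)


# ---------------------------------------------------------------------------
# smooth muscle cells
# ---------------------------------------------------------------------------

def _capped_deaths(state: SimulationState, n: np.ndarray) -> np.ndarray:
    """Stochastic deaths, hard-capped at 15 % of each local population."""
    cap = state.rates.apoptosis_cap_frac
    draws = state.rng.binomial(n, cap)
    return np.minimum(draws, np.ceil(cap * n).astype(np.int64))


def _allowed_mask(state: SimulationState) -> np.ndarray:
    """Patches SMCs may occupy: the wall plus lumen patches that touch tissue
    (the advancing neointimal front); never struts or plaque."""
    return ~state.strut & ~state.plaque & (~state.lumen_mask | state.ring_mask)


def step_smc(state: SimulationState, tgfb_field: np.ndarray,
             tnfa_field: np.ndarray) -> None:
    """Proliferation, apoptosis, lumen-ward migration and crowding overflow.

    `tgfb_field` / `tnfa_field` are local-concentration grids in ng/ml for
    the current step.
    """
    rates = state.rates
    smc = state.smc
    p_div = rates.division_prob_per_step

    # (a) proliferation where local TGF-beta reaches the sensitivity threshold
    prolif = (tgfb_field >= rates.tgfb_prolif_threshold_ng_ml) & (smc > 0)
    if np.any(prolif):
        births = np.zeros_like(smc)
        births[prolif] = state.rng.binomial(smc[prolif], p_div)
        births[prolif & state.injured] *= 2  # injured intimal SMCs replicate twice
        smc += births

    # (b) apoptosis where local TNF-alpha reaches its threshold, 15 % cap
    apop = (tnfa_field >= rates.tnfa_apoptosis_threshold_ng_ml) & (smc > 0)
    if np.any(apop):
        deaths = np.zeros_like(smc)
        deaths[apop] = _capped_deaths(state, smc[apop])
        smc -= deaths

    allowed = _allowed_mask(state)

    # (c) proliferating medial SMCs migrate toward the lumen (20 um/h)
    medial = (state.smc_region == MEDIA) & prolif & (smc > 0)
    if np.any(medial):
        xs, ys = np.nonzero(medial)
        movers = state.rng.binomial(smc[xs, ys], rates.medial_migration_prob)
        sel = movers > 0
        if np.any(sel):
            xs, ys, movers = xs[sel], ys[sel], movers[sel]
            step_units = rates.smc_migration_units_per_step  # 2.4 units
            dist = np.floor(step_units) + (
                state.rng.random(xs.size) < (step_units % 1.0))
            ux = state.center[0] - xs
            uy = state.center[1] - ys
            norm = np.hypot(ux, uy)
            norm[norm == 0] = 1.0
            for back in range(int(np.ceil(step_units)) + 1):
                d = np.maximum(dist - back, 0)
                tx = np.clip(np.rint(xs + ux / norm * d), 0,
                             state.grid_size - 1).astype(np.int64)
                ty = np.clip(np.rint(ys + uy / norm * d), 0,
                             state.grid_size - 1).astype(np.int64)
                ok = allowed[tx, ty]
                if back == 0:
                    fx, fy, unresolved = tx.copy(), ty.copy(), ~ok
                else:
                    fx[unresolved] = tx[unresolved]
                    fy[unresolved] = ty[unresolved]
                    unresolved &= ~ok
                if not np.any(unresolved):
                    break
            stay = (fx == xs) & (fy == ys) | unresolved
            np.subtract.at(smc, (xs[~stay], ys[~stay]), movers[~stay])
            np.add.at(smc, (fx[~stay], fy[~stay]), movers[~stay])

    # (d) crowding: surplus above the 15-cell capacity is pushed lumen-ward
    _resolve_crowding(state, allowed)


_OFFSETS = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            if (dx, dy) != (0, 0)]


def _resolve_crowding(state: SimulationState, allowed: np.ndarray) -> None:
    """Push surplus cells off over-capacity patches.

    Surplus flows to the least-occupied allowed neighbour, with a strong
    preference for neighbours closer to the vessel axis (the mechanical
    push is lumen-ward) — a biased sandpile that spreads while any local
    capacity exists.  Lateral spill lets tissue seal around strut faces.
    """
    cap = state.rates.smc_patch_capacity
    smc = state.smc
    radius = state.radius
    n = state.grid_size
    for _ in range(200):
        xs, ys = np.nonzero(smc > cap)
        if xs.size == 0:
            break
        excess = smc[xs, ys] - cap
        best_key = np.full(xs.size, np.inf)
        best_tx = xs.copy()
        best_ty = ys.copy()
        jitter = state.rng.random((xs.size, len(_OFFSETS)))
        for k, (dx, dy) in enumerate(_OFFSETS):
            tx = np.clip(xs + dx, 0, n - 1)
            ty = np.clip(ys + dy, 0, n - 1)
            occ = smc[tx, ty].astype(np.float64)
            centerward = radius[tx, ty] < radius[xs, ys]
            key = (occ >= cap) * 1e6 + ~centerward * 1e3 + occ + jitter[:, k]
            key[~allowed[tx, ty] | ((tx == xs) & (ty == ys))] = np.inf
            better = key < best_key
            best_key[better] = key[better]
            best_tx[better], best_ty[better] = tx[better], ty[better]
        movable = np.isfinite(best_key)
        if not np.any(movable):
            break  # wedged between struts/plaque on all sides
        np.subtract.at(smc, (xs[movable], ys[movable]), excess[movable])
        np.add.at(smc, (best_tx[movable], best_ty[movable]), excess[movable])


# ---------------------------------------------------------------------------
# endothelial lining
# ---------------------------------------------------------------------------

def step_ec(state: SimulationState, tgfb_field: np.ndarray,
            tnfa_field: np.ndarray) -> bool:
    """Re-seat the endothelial monolayer on the lumen-facing frontier of the
    tissue, apply TNF-alpha-driven EC loss, and clear injuries where the
    monolayer has been restored.  Returns True when the lumen is occluded.
    """
    rates = state.rates
    state.refresh_lumen_geometry()
    if state.occluded:
        state.ec[:] = False
        return True

    ring = state.ring_mask
    ec_prev = state.ec
    ec = ec_prev & ring  # lining still on the frontier stays in place

    # fill monolayer gaps: sliding/relocation from an adjacent (possibly
    # overrun) EC, or TGF-driven respawn
    gaps = ring & ~ec
    if np.any(gaps):
        slide = dilate8(ec_prev)
        candidates = gaps & (slide | (tgfb_field >= rates.tgfb_prolif_threshold_ng_ml))
        xs, ys = np.nonzero(candidates)
        fill = state.rng.random(xs.size) < rates.ec_reseat_prob
        ec[xs[fill], ys[fill]] = True

    # EC apoptosis under TNF-alpha (per-cell, same 15 % exposure cap)
    exposed = ec & (tnfa_field >= rates.tnfa_apoptosis_threshold_ng_ml)
    if np.any(exposed):
        xs, ys = np.nonzero(exposed)
        die = state.rng.random(xs.size) < rates.apoptosis_cap_frac
        ec[xs[die], ys[die]] = False

    # spontaneous monolayer turnover: the regenerating endothelium is leaky,
    # so transient micro-gaps appear anywhere on the ring at a low rate
    if rates.ec_turnover_prob > 0:
        xs, ys = np.nonzero(ec)
        shed = state.rng.random(xs.size) < rates.ec_turnover_prob
        ec[xs[shed], ys[shed]] = False

    state.ec = ec

    # injuries heal after sustained EC cover (re-endothelialisation); deep
    # strut injuries need a much longer undisturbed cover than the denuded ring
    if np.any(state.injured):
        covered = dilate8(ec)
        state.ec_cover_steps[state.injured & covered] += 1
        # a transient monolayer breach sets healing back without voiding it
        uncovered = state.injured & ~covered
        state.ec_cover_steps[uncovered] = np.maximum(
            state.ec_cover_steps[uncovered] - 4, 0)
        need = np.where(state.strut, rates.strut_heal_steps, rates.ring_heal_steps)
        healed = state.injured & (state.ec_cover_steps >= need)
        state.injured[healed] = False

    # any injury is neutralised once buried under enough neointima (for
    # struts: neo-endothelialisation walls the foreign body off); chronic
    # injuries finally resolve on their own after max_injury_days
    if np.any(state.injured):
        buried = state.injured & (state.dist_to_lumen > rates.strut_burial_depth)
        state.injured[buried] = False
        state.injury_age[state.injured] += 1
        # resolution takes longer the greater the total procedural injury
        # (sub-linear: inflammation resolves in parallel across sites)
        burden = max(1.0, (state.n_strut_sites / 20.0) ** 0.25)
        expired = state.injured & (
            state.injury_age > rates.max_injury_days * burden * STEPS_PER_DAY)
        state.injured[expired] = False
    return False
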