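"""Deterministic micro-fixtures: tiny lattices with hand-placed agents and
forced cytokine fields so every behavioural rule is unit-testable without a
full simulation.  Fixtures run through the production step operators — no
rule is mocked.
"""

from __future__ import annotations

from typing import Callable, Dict, Tuple

import numpy as np

from .config import RateTable, VesselConfig
from .state import INTIMA, LUMEN, MEDIA, SimulationState

FixtureFactory = Callable[[int], Tuple[SimulationState, dict]]
_REGISTRY: Dict[str, FixtureFactory] = {}


def register(name: str):
    def deco(fn: FixtureFactory) -> FixtureFactory:
        _REGISTRY[name] = fn
        return fn
    return deco


def fixture_names():
    return sorted(_REGISTRY)


def make_fixture(name: str, seed: int = 0) -> Tuple[SimulationState, dict]:
    """Build a registered micro-state; returns (state, expectations)."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}")
    return _REGISTRY[name](seed)


def blank_state(grid_size: int = 9, seed: int = 0, **rate_overrides) -> SimulationState:
    """An empty micro-lattice: no vessel anatomy, no circulating platelets.

    The whole grid is treated as open 'lumen' with a permissive geometry so
    hand-placed agents exercise exactly one rule at a time.
    """
    rate_overrides.setdefault("platelet_pool", 0)
    rates = RateTable(**rate_overrides)
    cfg = VesselConfig(lumen_diameter_mm=0.2, grid_size=grid_size,
                       struts_per_stent=1, rates=rates, seed=seed)
    state = SimulationState(cfg, rng=np.random.default_rng(seed))
    state.smc_region[:] = LUMEN
    state.lumen_mask[:] = True
    state.ring_mask[:] = False
    state.dist_to_lumen[:] = 0.0
    return state


def place_quanta(state: SimulationState, which: str, x: int, y: int, n: int) -> None:
    pool = state.tgfb if which == "tgfb" else state.tnfa
    pool.add(np.full(n, x), np.full(n, y), state.rates.cytokine_lifetime_steps)
    state.mass[which]["emitted"] += n


@register("empty")
def _empty(seed: int):
    state = blank_state(seed=seed)
    return state, {"note": "all step operators must be no-ops"}


@register("crowding")
def _crowding(seed: int):
    """A patch holding 16 SMCs must shed exactly one cell lumen-ward."""
    state = blank_state(seed=seed)
    state.smc_region[:] = MEDIA
    state.lumen_mask[:] = False
    state.smc[2, 2] = 16
    return state, {"patch": (2, 2), "expect_remaining": 15, "expect_displaced": 1}


@register("threshold_below")
def _threshold_below(seed: int):
    """Five local TGF-beta quanta (2.5 ng/ml) sit below the 3 ng/ml
    proliferation sensitivity: no division may ever fire."""
    state = blank_state(seed=seed)
    state.smc_region[:] = INTIMA
    state.lumen_mask[:] = False
    state.smc[4, 4] = 5
    place_quanta(state, "tgfb", 4, 4, 5)
    return state, {"patch": (4, 4), "smc_before": 5, "divisions_allowed": False}


@register("threshold_at")
def _threshold_at(seed: int):
    """Six local quanta = 3.0 ng/ml exactly reach the proliferation
    threshold: divisions are possible."""
    state = blank_state(seed=seed)
    state.smc_region[:] = INTIMA
    state.lumen_mask[:] = False
    state.smc[4, 4] = 5
    place_quanta(state, "tgfb", 4, 4, 6)
    return state, {"patch": (4, 4), "smc_before": 5, "divisions_allowed": True}


@register("apoptosis_cap")
def _apoptosis_cap(seed: int):
    """20 SMCs under saturating TNF-alpha: at most 3 (15 %) die per event."""
    state = blank_state(seed=seed)
    state.smc_region[:] = INTIMA
    state.lumen_mask[:] = False
    state.smc[4, 4] = 20
    place_quanta(state, "tnfa", 4, 4, 8)  # 8 quanta = 4 ng/ml
    return state, {"patch": (4, 4), "smc_before": 20, "max_deaths": 3}


@register("platelet_activation")
def _platelet_activation(seed: int):
    """A latent platelet beside an injured patch activates on the next step."""
    state = blank_state(seed=seed)
    state.injured[4, 4] = True
    state.latent_platelets.add([4], [5], [40])
    return state, {"expect_activated": 1}


@register("platelet_inert")
def _platelet_inert(seed: int):
    """A latent platelet far from any trigger stays latent."""
    state = blank_state(grid_size=15, seed=seed)
    state.latent_platelets.add([7], [7], [40])
    return state, {"expect_activated": 0}


@register("neutrophil_attach")
def _neutrophil_attach(seed: int):
    """A neutrophil one patch from an activated platelet attaches to the
    thrombus and stops moving."""
    state = blank_state(seed=seed)
    state.activated_platelets.add([4], [4], [40])
    state.neutrophils.add([4], [5], [20])
    return state, {"expect_attached": True}


@register("monocyte_maturation")
def _monocyte_maturation(seed: int):
    """A monocyte reaching wall tissue matures into a macrophage."""
    state = blank_state(seed=seed)
    state.smc_region[:] = INTIMA
    state.lumen_mask[:] = False
    state.smc[:, :] = 2
    state.monocytes.add([4], [4], [12])
    return state, {"expect_macrophages": 1, "expect_monocytes": 0}


@register("strut_immobility")
def _strut_immobility(seed: int):
    """Strut and plaque agents never move, appear or disappear."""
    state = blank_state(seed=seed)
    state.strut[2, 2] = True
    state.plaque[6, 6] = True
    return state, {"strut": (2, 2), "plaque": (6, 6)}


@register("ec_frontier")
def _ec_frontier(seed: int):
    """A flat SMC front with its endothelial lining: when the front advances
    one patch, the lining must advance with it."""
    state = blank_state(seed=seed, ec_reseat_prob=1.0)
    state.smc_region[:] = INTIMA
    # tissue occupies columns 6..8; open lumen on columns 0..5
    state.smc[:, 6:] = 3
    state.refresh_lumen_geometry()
    state.ec[state.ring_mask] = True
    return state, {"front_column": 6}
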