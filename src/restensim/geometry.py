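"""Vessel cross-section construction: units, strut placement, initial state.

The cross-section sits on a square lattice (0.05 mm per patch, default
150x150) with the vessel axis at the grid centre.  The post-procedural lumen
is circular; the wall is a concentric annulus partitioned into intima, media
and adventitia; struts of the deployed stent(s) are fixed square agents
evenly spaced around the lumen boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .config import PATCH_MM, VesselConfig
from .state import ADVENTITIA, INTIMA, LUMEN, MEDIA, SimulationState

DEFAULT_STRUTS_PER_STENT = 20


def mm_to_units(length_mm: float) -> float:
    """Convert a physical length to lattice units (one unit = 0.05 mm)."""
    if length_mm < 0:
        raise ValueError("length must be non-negative")
    return length_mm / PATCH_MM


def units_to_mm(length_units: float) -> float:
    if length_units < 0:
        raise ValueError("length must be non-negative")
    return length_units * PATCH_MM


def default_wall_thickness(lumen_diameter_mm: float,
                           override_mm: Optional[float] = None) -> float:
    """Wall thickness defaults to the lumen radius (typical 1:1 ratio)."""
    if lumen_diameter_mm <= 0:
        raise ValueError("lumen diameter must be positive")
    if override_mm is not None:
        return override_mm
    return lumen_diameter_mm / 2.0


def strut_count_from_spacing(lumen_diameter_mm: float, spacing_mm: float) -> int:
    """Number of struts from an inter-strut spacing.

    The post-stenting circumference is divided by the spacing and rounded to
    the nearest integer; a spacing larger than the circumference clamps to a
    single strut.
    """
    if spacing_mm <= 0:
        raise ValueError("strut spacing must be positive")
    n = int(round(math.pi * lumen_diameter_mm / spacing_mm))
    if n < 1:
        warnings.warn("strut spacing exceeds the lumen circumference; using 1 strut")
        return 1
    return n


@dataclass
class StrutLayout:
    """Polar strut positions (lattice units / radians) for one or two stents."""

    radii: List[float]            # ring radius per stent, lattice units
    angles: List[np.ndarray]      # strut centre angles per stent, radians
    side_units: float             # strut side length, lattice units

    @property
    def n_total(self) -> int:
        return sum(len(a) for a in self.angles)


def resolve_strut_count(config: VesselConfig) -> int:
    if config.struts_per_stent is not None:
        if config.struts_per_stent < 1:
            raise ValueError("struts_per_stent must be >= 1")
        return config.struts_per_stent
    if config.strut_spacing_mm is not None:
        return strut_count_from_spacing(config.lumen_diameter_mm, config.strut_spacing_mm)
    return DEFAULT_STRUTS_PER_STENT


def build_strut_layout(config: VesselConfig) -> StrutLayout:
    """Evenly spaced struts on the lumen boundary; a second stent sits on a
    radially adjacent inner ring, aligned with or staggered between the
    exterior struts."""
    if config.stent_count not in (1, 2):
        raise ValueError("stent_count must be 1 or 2")
    n = resolve_strut_count(config)
    r0 = mm_to_units(config.lumen_diameter_mm / 2.0)
    side = mm_to_units(config.strut_size_mm)
    base = 2.0 * math.pi * np.arange(n) / n
    # the exterior stent is pressed into the wall, flush with the lumen
    # boundary; an interior (second) stent sits on the radially adjacent
    # ring just inside it, protruding into the lumen
    radii = [r0 + side / 2.0]
    angles = [base]
    if config.stent_count == 2:
        inner_r = max(r0 - side / 2.0, 1.0)
        offset = math.pi / n if config.arrangement == "staggered" else 0.0
        radii.append(inner_r)
        angles.append((base + offset) % (2.0 * math.pi))
    return StrutLayout(radii=radii, angles=angles, side_units=side)


def default_plaque_box(config: VesselConfig) -> Tuple[int, int, int, int]:
    """Bounding box of a 30-degree plaque arc in the bottom-left quadrant,
    radial extent 4 patches, seated at the intima/media interface."""
    r0 = mm_to_units(config.lumen_diameter_mm / 2.0)
    wall = mm_to_units(config.wall_thickness())
    intima_th = max(1.0, config.intima_fraction * wall)
    r_in = r0 + intima_th
    r_out = r_in + 4.0
    cx = cy = (config.grid_size - 1) / 2.0
    theta = np.deg2rad(np.linspace(210.0, 240.0, 61))
    rr = np.linspace(r_in, r_out, 9)
    pts_x = (cx + np.outer(rr, np.cos(theta))).ravel()
    pts_y = (cy + np.outer(rr, np.sin(theta))).ravel()
    return (int(np.floor(pts_x.min())), int(np.ceil(pts_x.max())),
            int(np.floor(pts_y.min())), int(np.ceil(pts_y.max())))


def _paint_struts(state: SimulationState, layout: StrutLayout) -> None:
    half = layout.side_units / 2.0
    cx, cy = state.center
    n_sites = 0
    for radius, angles in zip(layout.radii, layout.angles):
        for theta in angles:
            sx = cx + radius * math.cos(theta)
            sy = cy + radius * math.sin(theta)
            x1 = int(round(sx - half)); x2 = int(round(sx + half))
            y1 = int(round(sy - half)); y2 = int(round(sy + half))
            x1, x2 = max(x1, 0), min(x2, state.grid_size - 1)
            y1, y2 = max(y1, 0), min(y2, state.grid_size - 1)
            state.strut[x1:x2 + 1, y1:y2 + 1] = True
            n_sites += 1
    state.n_strut_sites = n_sites


def build_initial_state(config: VesselConfig,
                        rng: Optional[np.random.Generator] = None) -> SimulationState:
    """Assemble the post-intervention cross-section.

    Concentric annuli around the axis: empty lumen seeded with circulating
    latent platelets; a sparse intima carrying the endothelial lining; SMC
    filled media and adventitia; a plaque pocket between intima and media;
    stent struts flagged as (deep) injuries and the denuded endothelial ring
    flagged as superficial injury.
    """
    state = SimulationState(config, rng=rng)
    r = state.radius
    r0 = state.lumen_radius_units
    wall = state.wall_units
    if r0 + wall > config.grid_size / 2.0:
        raise ValueError("vessel geometry does not fit the grid")

    intima_th = max(1.0, config.intima_fraction * wall)
    media_th = config.media_fraction * wall
    region = state.smc_region
    region[r <= r0] = LUMEN
    region[(r > r0) & (r <= r0 + intima_th)] = INTIMA
    region[(r > r0 + intima_th) & (r <= r0 + intima_th + media_th)] = MEDIA
    region[(r > r0 + intima_th + media_th) & (r <= r0 + wall)] = ADVENTITIA

    # struts first: they displace wall tissue and define deep injury sites
    layout = build_strut_layout(config)
    _paint_struts(state, layout)

    # plaque pocket clipped to the wall between intima and media
    box = config.plaque_box if config.plaque_box is not None else default_plaque_box(config)
    x1, x2, y1, y2 = box
    in_box = (state.xx >= x1) & (state.xx <= x2) & (state.yy >= y1) & (state.yy <= y2)
    plaque_zone = in_box & (r > r0 + 1.0) & (r <= r0 + wall) & ~state.strut
    if np.any(in_box & (r <= r0 - 1.0) & state.lumen_mask):
        pass  # lumen_mask not built yet; protrusion checked below on placement
    state.plaque = plaque_zone
    if np.any(state.plaque & (r <= r0)):
        raise ValueError("plaque box protrudes into the lumen")

    # SMC populations per layer
    intima_mask = (region == INTIMA) & ~state.strut & ~state.plaque
    media_mask = (region == MEDIA) & ~state.strut & ~state.plaque
    advent_mask = (region == ADVENTITIA) & ~state.strut & ~state.plaque
    state.smc[media_mask] = config.media_smc_per_patch
    state.smc[advent_mask] = config.adventitia_smc_per_patch
    seeded = state.rng.random(int(intima_mask.sum())) < config.intimal_smc_per_patch
    state.smc[intima_mask] = seeded.astype(np.int32)

    # endothelial lining: lumen patches in contact with the wall
    state.refresh_lumen_geometry()
    if state.occluded:
        raise ValueError("initial geometry occludes the vessel axis")
    state.ec[state.ring_mask] = True

    # procedural injury: the denuded ring plus strut sites
    ring_wall = (region == INTIMA) & (r <= r0 + 1.5)  # innermost wall ring
    frac = config.injured_ring_fraction
    if frac >= 1.0:
        state.injured |= ring_wall
    elif frac > 0:
        idx = np.flatnonzero(ring_wall.ravel())
        take = state.rng.choice(idx, size=int(round(frac * idx.size)), replace=False)
        flat = state.injured.ravel()
        flat[take] = True
        state.injured = flat.reshape(state.injured.shape)
    # strut injury lives on the lumen-facing strut surface: that is where
    # the wall was torn and where healing (coverage or burial) is measured
    from scipy import ndimage as _ndi
    strut_face = state.strut & _ndi.binary_dilation(
        state.lumen_mask, structure=np.ones((3, 3), bool))
    state.injured |= strut_face

    # circulating latent platelets in the open lumen
    _replenish_platelets(state, initial=True)
    return state


def _replenish_platelets(state: SimulationState, initial: bool = False) -> None:
    """Top the circulating latent pool back up toward its configured size.

    After initialisation the influx is rate-limited: fresh platelets arrive
    with the blood flow a few per step, so a consuming thrombus cannot drain
    an unbounded supply within one tick.
    """
    deficit = state.rates.platelet_pool - len(state.latent_platelets)
    if not initial:
        deficit = min(deficit, state.rates.platelet_influx_per_step)
    if deficit <= 0:
        return
    interior = state.lumen_mask & ~state.ring_mask
    idx = np.flatnonzero(interior.ravel())
    if idx.size == 0:
        return
    take = state.rng.choice(idx, size=deficit, replace=True)
    x, y = np.unravel_index(take, state.lumen_mask.shape)
    lo, hi = state.rates.platelet_lifespan_days
    spans = state.rng.integers(int(lo * 4), int(hi * 4) + 1, size=deficit)
    state.latent_platelets.add(x, y, spans)
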