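"""Measurement protocols: minimum lumen diameter from the endothelial
lining, percent lumen-area change, restenosis classification, per-step
time-series recording.

The lumen diameter is the worst case over evenly spaced rays through the
fixed vessel axis: for each ray the diameter is the distance between the
innermost endothelial boundary points on the two opposite sides.  Using the
endothelial lining as the reference boundary tracks the clinically relevant
worst-case obstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import PATCH_MM, STEPS_PER_DAY
from .cytokines import serum_concentration, window_counts
from .state import SimulationState

#: number of angular rays used for the diameter scan (convergence-checked)
DEFAULT_RAYS = 180


class MeasurementError(RuntimeError):
    """The endothelial frontier is missing without an occlusion flag."""


def min_lumen_diameter(state: SimulationState, n_rays: int = DEFAULT_RAYS) -> float:
    """Worst-case lumen diameter (mm) measured from endothelial positions.

    Casts ``n_rays`` diameters through the vessel axis at evenly spaced
    angles; each diameter is the sum of the innermost endothelial radii in
    the two opposed angular sectors.  Returns 0 for an occluded lumen.
    """
    if state.occluded:
        return 0.0
    if n_rays % 2:
        raise ValueError("n_rays must be even (rays pair into diameters)")
    xs, ys = np.nonzero(state.ec)
    if xs.size == 0:
        # transiently bare monolayer: the lining's seat (the tissue-facing
        # lumen boundary) still defines the frontier
        xs, ys = np.nonzero(state.ring_mask)
    if xs.size == 0:
        raise MeasurementError("no endothelial boundary and no occlusion flag")
    ang = np.arctan2(ys - state.center[1], xs - state.center[0])
    rad = np.hypot(xs - state.center[0], ys - state.center[1])
    bins = ((ang + np.pi) / (2.0 * np.pi) * n_rays).astype(np.int64) % n_rays
    r_min = np.full(n_rays, np.inf)
    np.minimum.at(r_min, bins, rad)
    # angular sectors with no EC inherit the nearest populated sector
    for _ in range(n_rays):
        empty = ~np.isfinite(r_min)
        if not np.any(empty):
            break
        neighbor = np.minimum(np.roll(r_min, 1), np.roll(r_min, -1))
        r_min[empty] = neighbor[empty]
    half = n_rays // 2
    # +1: an EC fills its patch, so each boundary point sits half a patch
    # beyond the patch centre, on the luminal face
    diameters = r_min[:half] + r_min[half:] + 1.0
    return float(np.min(diameters) * PATCH_MM)


def percent_area_change(initial_d_mm: float, current_d_mm: float) -> float:
    """Percent lumen-area loss from the initial and current minimum diameters."""
    if initial_d_mm <= 0:
        raise ValueError("initial diameter must be positive")
    if current_d_mm < 0:
        raise ValueError("current diameter must be non-negative")
    if current_d_mm > initial_d_mm:
        warnings.warn("current diameter exceeds initial; clamping area change to 0")
        return 0.0
    return 100.0 * (1.0 - (current_d_mm / initial_d_mm) ** 2)


def classify_restenosis(percent_change: float) -> bool:
    """Clinical restenosis: strictly more than 50 % lumen-area loss."""
    return percent_change > 50.0


@dataclass
class TimeSeries:
    """Per-step simulation record (one row appended per completed step)."""

    rows: List[dict] = field(default_factory=list)

    def append(self, row: dict) -> None:
        self.rows.append(row)

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def last(self) -> Optional[dict]:
        return self.rows[-1] if self.rows else None

    def census_tidy(self) -> pd.DataFrame:
        """Long-format per-step agent census: (step, kind, count)."""
        kinds = ["smc", "ec", "latent_platelet", "activated_platelet",
                 "monocyte", "neutrophil", "macrophage"]
        df = self.to_dataframe()
        return df.melt(id_vars=["step"], value_vars=kinds,
                       var_name="kind", value_name="count")


def record_step(state: SimulationState, series: TimeSeries,
                n_rays: int = DEFAULT_RAYS) -> TimeSeries:
    """Append one complete record of the current state; also refreshes the
    running minimum-diameter measurement the release gate consumes."""
    rates = state.rates
    if state.occluded:
        ld = 0.0
    else:
        ld = min_lumen_diameter(state, n_rays=n_rays)
    state.current_min_ld_mm = ld
    per_q = rates.ng_ml_per_local_quantum
    tgf_counts = state.local_counts("tgfb")
    tnf_counts = state.local_counts("tnfa")
    max_tgf = float(window_counts(tgf_counts).max() * per_q) if len(state.tgfb) else 0.0
    max_tnf = float(window_counts(tnf_counts).max() * per_q) if len(state.tnfa) else 0.0
    census = state.census()
    series.append({
        "step": state.step_index,
        "day": state.step_index / STEPS_PER_DAY,
        "min_lumen_diameter_mm": ld,
        "percent_area_change": percent_area_change(
            state.initial_lumen_diameter_mm, min(ld, state.initial_lumen_diameter_mm)),
        "smc": census["smc"],
        "ec": census["ec"],
        "latent_platelet": census["latent_platelet"],
        "activated_platelet": census["activated_platelet"],
        "monocyte": census["monocyte"],
        "neutrophil": census["neutrophil"],
        "macrophage": census["macrophage"],
        "max_local_tgfb_ng_ml": max_tgf,
        "max_local_tnfa_ng_ml": max_tnf,
        "serum_tgfb_ng_ml": serum_concentration(
            len(state.tgfb), rates.quantum_pg, rates.patch_thickness_mm, state.grid_size),
        "serum_tnfa_ng_ml": serum_concentration(
            len(state.tnfa), rates.quantum_pg, rates.patch_thickness_mm, state.grid_size),
        "tgfb_emitted": state.tgfb_emitted_this_step,
    })
    return series
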