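"""Simulation engine: per-step update order, stopping rule, replicates.

One tick advances 6 simulated hours and applies, in order: platelet
dynamics, TGF-beta release, leukocyte recruitment, leukocyte movement,
TNF-alpha release, cytokine diffusion/decay, SMC dynamics, endothelial
re-seating, then metrics recording.

A run ends when TGF-beta release has ceased (zero quanta emitted for four
consecutive steps); the day of the last emission is the lumen-diameter
stabilization day, after which the run continues for 60 more simulated days
to confirm the minimum diameter is static.  Full occlusion terminates a run
early; a hard cap of 400 simulated days guards against non-termination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .agents import maybe_recruit_leukocytes, step_ec, step_leukocytes, \
    step_platelets, step_smc
from .config import STEPS_PER_DAY, VesselConfig
from .cytokines import concentration_fields, diffuse_and_decay, release_tgfb, \
    release_tnfa, window_counts
from .geometry import build_initial_state
from .metrics import TimeSeries, record_step
from .state import SimulationState

#: consecutive emission-free steps that count as "release has ended"
RELEASE_DEBOUNCE_STEPS = 4
#: confirmation window after stabilization, days
CONFIRM_DAYS = 60
#: tolerated diameter drift during confirmation (one patch), mm
CONFIRM_TOLERANCE_MM = 0.05 + 1e-9
#: hard cap on simulated days
MAX_DAYS = 400


def step(state: SimulationState) -> SimulationState:
    """Advance the state by one 6-hour tick (sub-steps in fixed order)."""
    step_platelets(state)
    release_tgfb(state)
    tgf_window = window_counts(state.local_counts("tgfb"))
    maybe_recruit_leukocytes(state, tgf_window)
    step_leukocytes(state)
    release_tnfa(state)
    diffuse_and_decay(state)
    tgfb_field, tnfa_field = concentration_fields(state)
    step_smc(state, tgfb_field, tnfa_field)
    step_ec(state, tgfb_field, tnfa_field)
    state.step_index += 1
    return state


@dataclass
class RunResult:
    """Summary of one simulation run."""

    final_lumen_diameter_mm: float
    stabilization_day: int
    percent_area_change_final: float
    peak_local_tgfb_ng_ml: float
    peak_local_tnfa_ng_ml: float
    peak_serum_tgfb_ng_ml: float
    peak_serum_tnfa_ng_ml: float
    occluded: bool
    converged: bool
    seed: Optional[int]
    series: TimeSeries = field(repr=False, default_factory=TimeSeries)

    @property
    def restenosis(self) -> bool:
        return self.percent_area_change_final > 50.0


def run_simulation(config: VesselConfig, seed: Optional[int] = None,
                   max_days: int = MAX_DAYS) -> RunResult:
    """Run one replicate to stabilization plus the 60-day confirmation."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    state = build_initial_state(config, rng=rng)
    series = TimeSeries()

    quiet_steps = 0          # consecutive steps without TGF-beta emission
    stabilization_day: Optional[int] = None
    ld_at_stabilization: Optional[float] = None
    confirm_deadline: Optional[int] = None
    max_steps = max_days * STEPS_PER_DAY

    while state.step_index < max_steps:
        step(state)
        record_step(state, series)

        if state.occluded:
            stabilization_day = int(round(state.day))
            break

        if state.tgfb_emitted_this_step == 0:
            quiet_steps += 1
        else:
            quiet_steps = 0
            if stabilization_day is not None:
                # release resumed: discard the candidate stabilization point
                stabilization_day = None
                confirm_deadline = None

        if stabilization_day is None and quiet_steps >= RELEASE_DEBOUNCE_STEPS:
            stabilization_day = max(0, (state.last_tgfb_emission_step
                                        + STEPS_PER_DAY) // STEPS_PER_DAY)
            ld_at_stabilization = state.current_min_ld_mm
            confirm_deadline = state.step_index + CONFIRM_DAYS * STEPS_PER_DAY

        if confirm_deadline is not None:
            if abs(state.current_min_ld_mm - ld_at_stabilization) > CONFIRM_TOLERANCE_MM:
                # late drift: restart the confirmation window
                ld_at_stabilization = state.current_min_ld_mm
                confirm_deadline = state.step_index + CONFIRM_DAYS * STEPS_PER_DAY
            elif state.step_index >= confirm_deadline:
                break

    converged = stabilization_day is not None
    if not converged:
        warnings.warn("run hit the simulated-day cap before lumen-diameter "
                      "stabilization was confirmed")
        stabilization_day = max_days

    df = series.to_dataframe()
    if state.occluded:
        final_ld = 0.0
    elif converged:
        # the confirmed diameter: median over the 60-day confirmation
        # window, robust to the one-patch flicker of the boundary scan
        window = df["min_lumen_diameter_mm"].tail(CONFIRM_DAYS * STEPS_PER_DAY)
        final_ld = float(window.median())
    else:
        final_ld = float(df["min_lumen_diameter_mm"].iloc[-1])
    from .metrics import percent_area_change
    final_pct = percent_area_change(
        config.lumen_diameter_mm, min(final_ld, config.lumen_diameter_mm))
    return RunResult(
        final_lumen_diameter_mm=final_ld,
        stabilization_day=int(stabilization_day),
        percent_area_change_final=final_pct,
        peak_local_tgfb_ng_ml=float(df["max_local_tgfb_ng_ml"].max()),
        peak_local_tnfa_ng_ml=float(df["max_local_tnfa_ng_ml"].max()),
        peak_serum_tgfb_ng_ml=float(df["serum_tgfb_ng_ml"].max()),
        peak_serum_tnfa_ng_ml=float(df["serum_tnfa_ng_ml"].max()),
        occluded=bool(state.occluded),
        converged=converged,
        seed=seed,
        series=series,
    )


@dataclass
class ReplicateSummary:
    """Mean +/- SD outcome statistics across independent replicates."""

    n: int
    final_ld_mean: float
    final_ld_sd: float
    stabilization_day_mean: float
    stabilization_day_sd: float
    percent_area_change_mean: float
    percent_area_change_sd: float
    peak_local_tgfb_ng_ml: float
    peak_local_tnfa_ng_ml: float
    peak_serum_tgfb_ng_ml: float
    peak_serum_tnfa_ng_ml: float
    restenosis_fraction: float
    n_excluded: int
    results: List[RunResult] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "results"}
        return d


def summarize(results: List[RunResult], n_excluded: int = 0) -> ReplicateSummary:
    lds = np.array([r.final_lumen_diameter_mm for r in results])
    days = np.array([r.stabilization_day for r in results])
    pct = np.array([r.percent_area_change_final for r in results])
    return ReplicateSummary(
        n=len(results),
        final_ld_mean=float(lds.mean()),
        final_ld_sd=float(lds.std(ddof=1)) if len(results) > 1 else 0.0,
        stabilization_day_mean=float(days.mean()),
        stabilization_day_sd=float(days.std(ddof=1)) if len(results) > 1 else 0.0,
        percent_area_change_mean=float(pct.mean()),
        percent_area_change_sd=float(pct.std(ddof=1)) if len(results) > 1 else 0.0,
        peak_local_tgfb_ng_ml=max(r.peak_local_tgfb_ng_ml for r in results),
        peak_local_tnfa_ng_ml=max(r.peak_local_tnfa_ng_ml for r in results),
        peak_serum_tgfb_ng_ml=max(r.peak_serum_tgfb_ng_ml for r in results),
        peak_serum_tnfa_ng_ml=max(r.peak_serum_tnfa_ng_ml for r in results),
        restenosis_fraction=float(np.mean([r.restenosis for r in results])),
        n_excluded=n_excluded,
        results=results,
    )


def run_replicates(config: VesselConfig, n: int = 10,
                   base_seed: int = 0) -> ReplicateSummary:
    """Run ``n`` independent replicates seeded base_seed + replicate index."""
    if n < 1:
        raise ValueError("need at least one replicate")
    results, excluded = [], 0
    for i in range(n):
        result = run_simulation(config, seed=base_seed + i)
        if result.converged:
            results.append(result)
        else:
            excluded += 1
            warnings.warn(f"replicate {i} (seed {base_seed + i}) did not "
                          "converge and is excluded from the summary")
    if not results:
        raise RuntimeError("no replicate converged")
    return summarize(results, n_excluded=excluded)
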