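"""Packaged experiments: imaging-study validation scenarios, the
overlapping-stent comparison, and the one-at-a-time sensitivity scan.

The three validation scenarios use the post-procedural lumen diameters
reported by the serial imaging studies of Kimura, Hoffmann and Chamie
(2.9, 3.19 and 2.39 mm), a single 20-strut stent and the default 1:1
radius-to-wall geometry.  Each scenario carries both the imaging study's
follow-up outcome (mean +/- SD) and the reference simulation outcome the
default calibration was frozen against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .config import RateTable, VesselConfig
from .engine import ReplicateSummary, run_replicates


@dataclass(frozen=True)
class Scenario:
    """One named validation scenario with its expected outcome ranges."""

    name: str
    lumen_diameter_mm: float
    study_final_ld_mm: float
    study_final_ld_sd: float
    reference_final_ld_mm: float
    reference_final_ld_sd: float
    reference_stabilization_days: float
    reference_stabilization_sd: float
    replicates: int = 10

    def config(self, **overrides) -> VesselConfig:
        base = dict(lumen_diameter_mm=self.lumen_diameter_mm,
                    stent_count=1, struts_per_stent=20)
        base.update(overrides)
        return VesselConfig(**base)


VALIDATION_SCENARIOS: Dict[str, Scenario] = {
    "kimura": Scenario("kimura", 2.9, 2.2, 0.6, 2.13, 0.02, 89, 7),
    "hoffmann": Scenario("hoffmann", 3.19, 2.12, 0.82, 2.34, 0.02, 82, 16),
    "chamie": Scenario("chamie", 2.39, 1.28, 0.74, 1.75, 0.05, 93, 15),
}


def validation_suite(base_seed: int = 0, replicates: int = 10,
                     scenarios: Optional[Iterable[str]] = None) -> dict:
    """Run the validation scenarios and check each replicate-mean final
    lumen diameter against the corresponding imaging-study window
    (study mean +/- one study SD)."""
    names = list(scenarios) if scenarios is not None else list(VALIDATION_SCENARIOS)
    report: dict = {"scenarios": {}, "all_within_one_sd": True}
    for offset, name in enumerate(names):
        sc = VALIDATION_SCENARIOS[name]
        summary = run_replicates(sc.config(), n=replicates,
                                 base_seed=base_seed + 1000 * offset)
        lo = sc.study_final_ld_mm - sc.study_final_ld_sd
        hi = sc.study_final_ld_mm + sc.study_final_ld_sd
        ok = lo <= summary.final_ld_mean <= hi
        report["scenarios"][name] = {
            "initial_ld_mm": sc.lumen_diameter_mm,
            "study_window_mm": (lo, hi),
            "model_final_ld_mean": summary.final_ld_mean,
            "model_final_ld_sd": summary.final_ld_sd,
            "model_stabilization_day_mean": summary.stabilization_day_mean,
            "model_stabilization_day_sd": summary.stabilization_day_sd,
            "within_one_study_sd": ok,
            "summary": summary,
        }
        report["all_within_one_sd"] &= ok
    return report


def overlap_experiment(base_seed: int = 0, replicates: int = 10,
                       arrangements: Sequence[str] = ("staggered", "aligned")) -> dict:
    """Kimura-parameter runs with two overlapping stents vs one stent.

    Expected directions: smaller final diameter, longer stabilization and
    higher peak local cytokine levels with the second stent.
    """
    sc = VALIDATION_SCENARIOS["kimura"]
    single = run_replicates(sc.config(), n=replicates, base_seed=base_seed)
    report: dict = {"single": _summary_dict(single), "overlap": {}}
    for i, arrangement in enumerate(arrangements):
        cfg = sc.config(stent_count=2, arrangement=arrangement)
        overlap = run_replicates(cfg, n=replicates,
                                 base_seed=base_seed + 5000 * (i + 1))
        entry = _summary_dict(overlap)
        entry["delta_final_ld_mm"] = overlap.final_ld_mean - single.final_ld_mean
        entry["delta_final_ld_pct"] = 100.0 * (
            overlap.final_ld_mean / single.final_ld_mean - 1.0)
        entry["delta_stabilization_days"] = (
            overlap.stabilization_day_mean - single.stabilization_day_mean)
        entry["delta_stabilization_pct"] = 100.0 * (
            overlap.stabilization_day_mean / single.stabilization_day_mean - 1.0)
        entry["delta_peak_tgfb_ng_ml"] = (
            overlap.peak_local_tgfb_ng_ml - single.peak_local_tgfb_ng_ml)
        entry["delta_peak_tnfa_ng_ml"] = (
            overlap.peak_local_tnfa_ng_ml - single.peak_local_tnfa_ng_ml)
        report["overlap"][arrangement] = entry
    return report


def _summary_dict(summary: ReplicateSummary) -> dict:
    d = summary.to_dict()
    d["summary"] = summary
    return d


def _registered_fields() -> Dict[str, str]:
    """Numeric parameters the sensitivity scan may perturb, with their home
    ('config' or 'rates')."""
    out: Dict[str, str] = {}
    for f in dataclasses.fields(VesselConfig):
        if f.name in ("rates", "plaque_box", "arrangement", "seed", "grid_size"):
            continue
        out[f.name] = "config"
    for f in dataclasses.fields(RateTable):
        if f.name == "platelet_lifespan_days":
            continue
        out[f.name] = "rates"
    return out


def sensitivity_scan(parameter: str, deltas: Sequence[float] = (-0.5, -0.1, 0.1, 0.5),
                     base_seed: int = 0, replicates: int = 10,
                     scenario: str = "kimura", alpha: float = 0.01) -> dict:
    """Perturb one registered parameter by the given relative deltas and
    report the effect on final diameter and stabilization day (Welch t-test
    against the unperturbed baseline).  After the perturbation batch a
    default-configuration run confirms the baseline is restored."""
    registry = _registered_fields()
    if parameter not in registry:
        raise ValueError(f"unknown parameter {parameter!r}; "
                         f"registered: {sorted(registry)}")
    sc = VALIDATION_SCENARIOS[scenario]
    baseline_cfg = sc.config()
    baseline = run_replicates(baseline_cfg, n=replicates, base_seed=base_seed)
    base_lds = [r.final_lumen_diameter_mm for r in baseline.results]

    rows = []
    for delta in deltas:
        cfg = _perturbed_config(sc, parameter, registry[parameter], delta)
        summary = run_replicates(cfg, n=replicates, base_seed=base_seed)
        lds = [r.final_lumen_diameter_mm for r in summary.results]
        if np.allclose(lds, base_lds):
            pvalue = 1.0
        else:
            pvalue = float(stats.ttest_ind(lds, base_lds, equal_var=False).pvalue)
        rows.append({
            "parameter": parameter,
            "delta": delta,
            "final_ld_mean": summary.final_ld_mean,
            "final_ld_sd": summary.final_ld_sd,
            "stabilization_day_mean": summary.stabilization_day_mean,
            "pvalue_vs_baseline": pvalue,
            "significant": pvalue < alpha,
        })

    # restoration check: a default-config replicate must reproduce baseline
    restored = run_replicates(baseline_cfg, n=1, base_seed=base_seed)
    restoration_ok = np.isclose(
        restored.results[0].final_lumen_diameter_mm,
        baseline.results[0].final_lumen_diameter_mm)
    return {
        "baseline": _summary_dict(baseline),
        "perturbations": rows,
        "restoration_confirmed": bool(restoration_ok),
    }


def _perturbed_config(scenario: Scenario, parameter: str, home: str,
                      delta: float) -> VesselConfig:
    cfg = scenario.config()
    if home == "config":
        value = getattr(cfg, parameter)
        if value is None:
            raise ValueError(f"{parameter} has no default value to perturb")
        new = value * (1.0 + delta)
        if isinstance(value, int):
            new = max(1, int(round(new)))
        return cfg.replace(**{parameter: new})
    value = getattr(cfg.rates, parameter)
    new = value * (1.0 + delta)
    if isinstance(value, int):
        new = max(0, int(round(new)))
    return cfg.replace(rates=dataclasses.replace(cfg.rates, **{parameter: new}))


def restenosis_fraction(n_runs: int = 50, base_seed: int = 0,
                        scenario: str = "kimura") -> dict:
    """Fraction of runs in which thickening never reaches the >50 %
    area-loss restenosis point, over ``n_runs`` independent seeds."""
    sc = VALIDATION_SCENARIOS[scenario]
    cfg = sc.config()
    from .engine import run_simulation
    below = 0
    results = []
    for i in range(n_runs):
        res = run_simulation(cfg, seed=base_seed + i)
        results.append(res)
        if not res.restenosis:
            below += 1
    return {
        "n_runs": n_runs,
        "fraction_no_restenosis": below / n_runs,
        "results": results,
    }
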