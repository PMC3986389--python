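"""Run configuration for the restenosis simulator.

Two groups of settings live here:

* scenario parameters a user sets per run (post-procedural lumen diameter,
  stent geometry, plaque box, seed), and
* biological rate constants (cytokine release rates, thresholds, migration
  speeds, lifespans) together with the calibration knobs the model exposes
  because the underlying physiology does not pin them down (injury release
  factor, hoop-stress cutoff, leukocyte recruitment rate, ...).

All lengths are millimetres unless a name says otherwise; the lattice side
is 0.05 mm per patch and one time step is 6 hours.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

#: side length of one lattice patch, mm
PATCH_MM = 0.05
#: hours represented by one simulation step
STEP_HOURS = 6.0
#: simulation steps per simulated day
STEPS_PER_DAY = int(24 / STEP_HOURS)
#: default lattice side, patches
GRID_SIZE = 150


@dataclass
class RateTable:
    """Biological constants and calibration knobs.

    The first block holds literature-derived values (release rates,
    sensitivities, speeds, lifespans).  The second block holds model
    calibration parameters: quantities the biology leaves open and that were
    tuned once against the reference imaging outcomes, then frozen.
    """

    # --- literature-derived constants -----------------------------------
    cytokine_release_pg_per_10h: float = 0.02
    quantum_pg: float = 0.012             # mass of one cytokine agent (= one 6 h emission)
    patch_thickness_mm: float = 16.0 / 15.0   # C (~1.067 mm) in V = C x AP, chosen so
    # one local quantum is exactly 0.5 ng/ml: thresholds = 6 (TGF-b) / 8 (TNF-a) quanta
    smc_doubling_h: float = 30.0
    smc_migration_um_per_h: float = 20.0
    leukocyte_migration_um_per_min: float = 1.0
    apoptosis_cap_frac: float = 0.15      # max fraction of a local population lost per exposure event
    tgfb_prolif_threshold_ng_ml: float = 3.0
    tnfa_apoptosis_threshold_ng_ml: float = 4.0
    recruitment_threshold_quanta: int = 1  # femtomolar-scale trigger = 1 detectable local quantum
    serum_limit_ng_ml: float = 10.0
    platelet_lifespan_days: Tuple[float, float] = (5.0, 10.0)
    monocyte_lifespan_days: float = 3.0
    macrophage_lifespan_days: float = 45.0
    neutrophil_lifespan_days: float = 5.0
    smc_patch_capacity: int = 15
    cytokine_lifetime_steps: int = 10     # 60 h residence of a quantum before passive decay

    # --- calibration knobs ----------------------------------------------
    release_fraction: float = 0.1225       # per-cell per-step emission probability at unit stress/injury
    tnfa_release_fraction: float = 0.2    # per-leukocyte per-step TNF-a emission probability
    max_emitters_per_patch: int = 2       # surface-exposure cap: secreting cells per patch per class
    tgfb_inhibition_ng_ml: float = 3.0    # autoregulation: release stops where local TGF-b is this high
    tnfa_inhibition_ng_ml: float = 6.0    # same negative feedback for TNF-a release
    tgfb_clearance_ng_ml: float = 4.3     # receptor-mediated uptake consumes TGF-b above this level
    tnfa_clearance_ng_ml: float = 7.5     # and TNF-a above this level
    injury_release_factor: float = 1.3    # extra release for cells sitting on an injured patch
    hoop_gate: float = 0.70             # stress ratio r/t below which stretch-driven TGF-b release stops
    injury_severity_coeff: float = 0.15   # global release scaling per extra strut beyond the reference 20
    strut_burial_depth: int = 3           # patches of neointimal cover that neutralise a strut injury
    ring_heal_steps: int = 8              # steps of continuous EC cover that clear a denuded-ring injury
    strut_heal_steps: int = 400            # steps of continuous EC cover that silence a strut injury
    max_injury_days: float = 96.0        # chronic-resolution backstop: injuries older than this resolve
    ec_reseat_prob: float = 0.5           # per-step chance an EC monolayer gap is re-covered
    ec_turnover_prob: float = 0.08        # spontaneous per-step EC detachment (monolayer turnover)
    recruit_rate: float = 1.2             # monocytes (and neutrophils) recruited per triggering step
    macrophage_strut_fraction: float = 1.0
    platelet_pool: int = 150              # circulating latent platelets kept in the lumen
    platelet_influx_per_step: int = 4     # cap on fresh latent platelets entering per step
    medial_migration_prob: float = 0.05    # per-step chance a proliferating medial SMC migrates inward
    chemotaxis_bias: float = 0.8          # fraction of leukocyte sub-steps aimed at the nearest wound

    @property
    def division_prob_per_step(self) -> float:
        """Per-step SMC division probability from the population doubling time."""
        return 2.0 ** (STEP_HOURS / self.smc_doubling_h) - 1.0

    @property
    def smc_migration_units_per_step(self) -> float:
        return self.smc_migration_um_per_h * STEP_HOURS / (PATCH_MM * 1000.0)

    @property
    def leukocyte_migration_units_per_step(self) -> float:
        return self.leukocyte_migration_um_per_min * STEP_HOURS * 60.0 / (PATCH_MM * 1000.0)

    @property
    def ng_ml_per_local_quantum(self) -> float:
        """Concentration of one quantum measured over a full 9-patch window."""
        # pg / mm^3 is numerically equal to ng/ml
        return self.quantum_pg / (self.patch_thickness_mm * 9.0 * PATCH_MM**2)

    def lifespan_steps(self, days: float) -> int:
        return int(round(days * STEPS_PER_DAY))


@dataclass
class VesselConfig:
    """All user-settable parameters of one simulated vessel cross-section."""

    lumen_diameter_mm: float = 2.9
    wall_thickness_mm: Optional[float] = None   # default: equal to the lumen radius
    stent_count: int = 1
    struts_per_stent: Optional[int] = None      # default 20 when spacing also unset
    strut_spacing_mm: Optional[float] = None
    strut_size_mm: float = 0.1
    arrangement: str = "aligned"                # 'aligned' | 'staggered' (two-stent runs)
    stent_length_mm: float = 15.0               # recorded metadata only
    plaque_box: Optional[Tuple[int, int, int, int]] = None  # (x1, x2, y1, y2) lattice bounds
    seed: int = 0
    grid_size: int = GRID_SIZE

    # wall layer partition (fractions of the wall thickness)
    intima_fraction: float = 0.10
    media_fraction: float = 0.60
    intimal_smc_per_patch: float = 1.0 / 3.0    # sparse initial intimal SMC seeding
    media_smc_per_patch: int = 5
    adventitia_smc_per_patch: int = 5
    injured_ring_fraction: float = 1.0          # fraction of the denuded EC ring flagged injured

    rates: RateTable = field(default_factory=RateTable)

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.lumen_diameter_mm <= 0:
            raise ValueError("lumen_diameter_mm must be positive")
        if self.stent_count not in (1, 2):
            raise ValueError("stent_count must be 1 or 2")
        if self.arrangement not in ("aligned", "staggered"):
            raise ValueError("arrangement must be 'aligned' or 'staggered'")
        if self.struts_per_stent is not None and self.strut_spacing_mm is not None:
            raise ValueError("set at most one of struts_per_stent / strut_spacing_mm")
        if self.strut_size_mm <= 0:
            raise ValueError("strut_size_mm must be positive")
        radius_units = (self.lumen_diameter_mm / 2.0) / PATCH_MM
        wall_units = self.wall_thickness() / PATCH_MM
        if radius_units + wall_units > self.grid_size / 2.0:
            raise ValueError(
                "vessel does not fit the grid: lumen radius + wall thickness "
                f"= {(radius_units + wall_units) * PATCH_MM:.2f} mm exceeds "
                f"{self.grid_size / 2.0 * PATCH_MM:.2f} mm"
            )

    def wall_thickness(self) -> float:
        """Wall thickness in mm; defaults to the lumen radius (1:1 ratio)."""
        if self.wall_thickness_mm is not None:
            return self.wall_thickness_mm
        return self.lumen_diameter_mm / 2.0

    def replace(self, **kwargs) -> "VesselConfig":
        return dataclasses.replace(self, **kwargs)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "VesselConfig":
        data = dict(data)
        rates = data.pop("rates", None)
        if isinstance(rates, dict):
            known = {f.name for f in dataclasses.fields(RateTable)}
            unknown = set(rates) - known
            if unknown:
                raise ValueError(f"unknown rate parameters: {sorted(unknown)}")
            rt = RateTable(**{k: tuple(v) if isinstance(v, list) else v for k, v in rates.items()})
        elif isinstance(rates, RateTable):
            rt = rates
        else:
            rt = RateTable()
        known = {f.name for f in dataclasses.fields(cls)} - {"rates"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config parameters: {sorted(unknown)}")
        if "plaque_box" in data and isinstance(data["plaque_box"], list):
            data["plaque_box"] = tuple(data["plaque_box"])
        return cls(rates=rt, **data)

    @classmethod
    def from_yaml(cls, path) -> "VesselConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def circumference_mm(lumen_diameter_mm: float) -> float:
    return math.pi * lumen_diameter_mm
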