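"""In-memory simulation state: lattice occupancy, mobile agents, cytokines.

Dense cell populations (smooth muscle cells, endothelial lining) are stored
as per-patch count grids; sparse mobile agents (platelets, leukocytes) and
cytokine quanta are stored as coordinate arrays.  Everything mutable during a
run lives on this object so that a fixed seed reproduces a run bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import ndimage

from ._grid import closing8, dilate4
from .config import PATCH_MM, STEPS_PER_DAY, VesselConfig

# region codes for the initial vessel anatomy
LUMEN, INTIMA, MEDIA, ADVENTITIA, OUTSIDE = 0, 1, 2, 3, 4

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connected structuring element


@dataclass
class Particles:
    """Point agents on the lattice (one row per agent)."""

    x: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    y: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    age: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    lifespan: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    flag: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __len__(self) -> int:
        return self.x.size

    def keep(self, mask: np.ndarray) -> None:
        self.x, self.y = self.x[mask], self.y[mask]
        self.age, self.lifespan = self.age[mask], self.lifespan[mask]
        self.flag = self.flag[mask]

    def add(self, x, y, lifespan, flag=False) -> None:
        x = np.atleast_1d(np.asarray(x, dtype=np.int64))
        y = np.atleast_1d(np.asarray(y, dtype=np.int64))
        n = x.size
        self.x = np.concatenate([self.x, x])
        self.y = np.concatenate([self.y, y])
        self.age = np.concatenate([self.age, np.zeros(n, dtype=np.int64)])
        life = np.broadcast_to(np.asarray(lifespan, dtype=np.int64), (n,))
        self.lifespan = np.concatenate([self.lifespan, life])
        fl = np.broadcast_to(np.asarray(flag, dtype=bool), (n,))
        self.flag = np.concatenate([self.flag, fl])

    def counts(self, grid_size: int) -> np.ndarray:
        out = np.zeros((grid_size, grid_size), dtype=np.int64)
        np.add.at(out, (self.x, self.y), 1)
        return out


class SimulationState:
    """Full mutable state of one simulated vessel cross-section."""

    def __init__(self, config: VesselConfig, rng: Optional[np.random.Generator] = None):
        self.config = config
        self.rates = config.rates
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        n = config.grid_size
        self.grid_size = n
        self.center = ((n - 1) / 2.0, (n - 1) / 2.0)

        xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        self.xx, self.yy = xx, yy
        self.radius = np.hypot(xx - self.center[0], yy - self.center[1])
        self.angle = np.arctan2(yy - self.center[1], xx - self.center[0])

        # lattice occupancy -------------------------------------------------
        self.smc = np.zeros((n, n), dtype=np.int32)
        self.smc_region = np.full((n, n), OUTSIDE, dtype=np.int8)  # anatomical region of each patch
        self.ec = np.zeros((n, n), dtype=bool)        # endothelial lining (lumen side of the frontier)
        self.strut = np.zeros((n, n), dtype=bool)
        self.plaque = np.zeros((n, n), dtype=bool)
        self.injured = np.zeros((n, n), dtype=bool)   # unhealed procedural injury
        self.ec_cover_steps = np.zeros((n, n), dtype=np.int32)
        self.injury_age = np.zeros((n, n), dtype=np.int32)

        # mobile agents -----------------------------------------------------
        self.latent_platelets = Particles()
        self.activated_platelets = Particles()
        self.monocytes = Particles()
        self.neutrophils = Particles()   # flag = attached to thrombus
        self.macrophages = Particles()   # flag = resident at a strut

        # cytokine quanta ---------------------------------------------------
        self.tgfb = Particles()
        self.tnfa = Particles()
        # exact mass bookkeeping (in quanta)
        self.mass: Dict[str, Dict[str, int]] = {
            "tgfb": {"emitted": 0, "decayed": 0, "consumed": 0},
            "tnfa": {"emitted": 0, "decayed": 0, "consumed": 0},
        }

        # clocks and bookkeeping -------------------------------------------
        self.step_index = 0
        self.occluded = False
        self.last_tgfb_emission_step = -1
        self.tgfb_emitted_this_step = 0
        self.initial_lumen_diameter_mm = config.lumen_diameter_mm
        self.current_min_ld_mm = config.lumen_diameter_mm

        # derived masks maintained by the EC step
        self.lumen_mask = np.zeros((n, n), dtype=bool)
        self.ring_mask = np.zeros((n, n), dtype=bool)
        self.dist_to_lumen = np.zeros((n, n), dtype=np.float64)

    # ------------------------------------------------------------------
    @property
    def day(self) -> float:
        return self.step_index / STEPS_PER_DAY

    @property
    def lumen_radius_units(self) -> float:
        return (self.config.lumen_diameter_mm / 2.0) / PATCH_MM

    @property
    def wall_units(self) -> float:
        return self.config.wall_thickness() / PATCH_MM

    def tissue_mask(self) -> np.ndarray:
        """Patches occupied by wall tissue, plaque or struts."""
        return (self.smc > 0) | self.strut | self.plaque

    def refresh_lumen_geometry(self) -> None:
        """Recompute the lumen flood-fill, the EC ring support and distances.

        The lumen is the connected free region containing the vessel axis;
        the ring support is the set of lumen patches in contact with tissue
        (where the endothelial lining lives).  Sets the occlusion flag when
        the axis itself is overgrown or no free region remains.
        """
        tissue = self.tissue_mask()
        # seal 1-2 patch crevices: the endothelial monolayer bridges narrow
        # inlets, so they are not part of the hemodynamically open lumen
        tissue = closing8(tissue)
        cx = int(round(self.center[0]))
        cy = int(round(self.center[1]))
        free = ~tissue
        if not free[cx, cy]:
            self.occluded = True
            self.lumen_mask[:] = False
            self.ring_mask[:] = False
            self.dist_to_lumen[:] = np.inf
            return
        labels, _ = ndimage.label(free, structure=_STRUCT8)
        self.lumen_mask = labels == labels[cx, cy]
        # edge (4-connected) contact keeps the lining one cell thick
        touching = dilate4(tissue)
        self.ring_mask = self.lumen_mask & touching
        self.dist_to_lumen = ndimage.distance_transform_edt(~self.lumen_mask)

    def local_counts(self, which: str) -> np.ndarray:
        """Per-patch counts of cytokine quanta ('tgfb' or 'tnfa')."""
        particles = self.tgfb if which == "tgfb" else self.tnfa
        return particles.counts(self.grid_size)

    def injury_severity(self) -> float:
        """Global release multiplier: greater procedural injury, greater release.

        Normalised to 1.0 for the reference single 20-strut stent; each
        additional strut site adds injury_severity_coeff / 20.
        """
        n_struts = self.n_strut_sites
        ref = 20
        return 1.0 + self.rates.injury_severity_coeff * max(0, n_struts - ref) / ref

    n_strut_sites: int = 0  # set by geometry when struts are placed

    def census(self) -> Dict[str, int]:
        return {
            "smc": int(self.smc.sum()),
            "ec": int(self.ec.sum()),
            "latent_platelet": len(self.latent_platelets),
            "activated_platelet": len(self.activated_platelets),
            "monocyte": len(self.monocytes),
            "neutrophil": len(self.neutrophils),
            "macrophage": len(self.macrophages),
            "tgfb_quanta": len(self.tgfb),
            "tnfa_quanta": len(self.tnfa),
        }
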