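"""Rendering helpers: cross-section snapshots and outcome curves.

Agent colours follow the model's visual convention: SMC green, EC pink,
latent platelet dark red, activated platelet red, monocyte blue,
neutrophil light blue, macrophage cyan, strut gray, plaque violet.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .state import SimulationState

_COLORS = {
    "background": (1.0, 1.0, 1.0),
    "smc": (0.20, 0.65, 0.25),
    "ec": (0.98, 0.75, 0.83),
    "strut": (0.45, 0.45, 0.45),
    "plaque": (0.56, 0.27, 0.68),
    "latent_platelet": (0.65, 0.10, 0.10),
    "activated_platelet": (0.90, 0.10, 0.10),
    "monocyte": (0.15, 0.25, 0.85),
    "neutrophil": (0.55, 0.75, 0.95),
    "macrophage": (0.10, 0.80, 0.80),
}


def render_state(state: SimulationState, ax=None, title: str | None = None):
    """Colour-coded snapshot of the cross-section (one pixel per patch)."""
    n = state.grid_size
    img = np.ones((n, n, 3))
    img[state.smc > 0] = _COLORS["smc"]
    img[state.ec] = _COLORS["ec"]
    for pool, key in ((state.latent_platelets, "latent_platelet"),
                      (state.activated_platelets, "activated_platelet"),
                      (state.monocytes, "monocyte"),
                      (state.neutrophils, "neutrophil"),
                      (state.macrophages, "macrophage")):
        if len(pool):
            img[pool.x, pool.y] = _COLORS[key]
    img[state.plaque] = _COLORS["plaque"]
    img[state.strut] = _COLORS["strut"]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.transpose(img, (1, 0, 2)), origin="lower")
    ax.set_xticks([]); ax.set_yticks([])
    if title:
        ax.set_title(title)
    return ax


def plot_time_series(df, ax=None, column: str = "percent_area_change",
                     label: str | None = None, **kwargs):
    """Plot one recorded quantity against simulated days."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.plot(df["day"], df[column], label=label, **kwargs)
    ax.set_xlabel("days post-intervention")
    ax.set_ylabel(column.replace("_", " "))
    if label:
        ax.legend()
    return ax
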