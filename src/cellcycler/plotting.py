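"""Matplotlib helpers for trajectories and tumour growth curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .engine import Trajectory
from .tumour import OverlayData, TumourConfig, growth_rate, radius_trajectory

__all__ = ["plot_phase_volumes", "plot_tumour_radius"]


def plot_phase_volumes(traj: Trajectory, normalised: bool = True, ax=None):
    """Plot per-phase proliferating volume (or phase shares) over time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    frame = traj.phase_volumes(normalised=normalised)
    for phase in frame.columns:
        ax.plot(frame.index, frame[phase], label=phase)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("phase share" if normalised else "phase volume")
    ax.legend(title="phase")
    return ax


def plot_tumour_radius(
    traj: Trajectory,
    tumour: TumourConfig,
    overlay: OverlayData | None = None,
    ax=None,
):
    """Plot simulated tumour radius, the drug-free line, and any overlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    r = radius_trajectory(traj, tumour)
    ax.plot(traj.times, r, label="treated")
    a = growth_rate(traj.cell_config.doubling_time)
    ax.plot(
        traj.times,
        tumour.initial_radius + a * tumour.layer_thickness * traj.times,
        "--",
        label="no drug",
    )
    if overlay is not None:
        ax.plot(overlay.time_h, overlay.diameter_mm / 2.0, "ko", label="observed")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("radius (mm)")
    ax.legend()
    return ax
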