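"""Plots for protocol convergence and free-energy surfaces.

Thin matplotlib helpers over the results objects: a convergence profile
with replicate spread bands and epoch markers, the per-pair spread decay
against the retirement threshold, and a heatmap of a 2D free-energy
surface with optional macrostate contours.
"""

from __future__ import annotations

import numpy as np

from .adaptive import ProtocolResult
from .fes import FESGrid, MacrostateMask

__all__ = ["plot_convergence", "plot_pair_spreads", "plot_fes"]


def plot_convergence(result: ProtocolResult, ax=None, label: str | None = None):
    """Mean physical binding free energy per epoch with a +/-1 sd band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    epochs = np.asarray(result.profile.epochs)
    mean = np.asarray(result.profile.dg_mean)
    sd = np.asarray(result.profile.dg_sd)
    ax.plot(epochs, mean, marker="o", label=label)
    ax.fill_between(epochs, mean - sd, mean + sd, alpha=0.25)
    for e in epochs:
        ax.axvline(e, color="tab:blue", linestyle=":", linewidth=0.5, alpha=0.4)
    ax.set_xlabel("epoch")
    ax.set_ylabel("dG (kcal/mol)")
    if label:
        ax.legend()
    return ax


def plot_pair_spreads(result: ProtocolResult, tau: float | None = None, ax=None):
    """Across-replicate spread of every window pair over the epochs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    history = np.asarray(result.profile.pair_sigma_history)  # (epochs, pairs)
    epochs = np.asarray(result.profile.epochs)
    for p in range(history.shape[1]):
        ax.plot(epochs, history[:, p], linewidth=0.8, alpha=0.7)
    if tau is not None:
        ax.axhline(tau, color="k", linestyle="--", label=f"tau = {tau}")
        ax.legend()
    ax.set_xlabel("epoch")
    ax.set_ylabel("pair spread (kcal/mol)")
    ax.set_yscale("log")
    return ax


def plot_fes(grid: FESGrid, masks: dict[str, MacrostateMask] | None = None, ax=None,
             vmax: float | None = 8.0):
    """Heatmap of the surface (kcal/mol) with optional macrostate outlines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(
        grid.edges1, grid.edges2, grid.free_energy.T, shading="flat", vmax=vmax
    )
    plt.colorbar(mesh, ax=ax, label="free energy (kcal/mol)")
    for name, mask in (masks or {}).items():
        x, y = mask.polygon.exterior.xy
        ax.plot(x, y, label=name)
    if masks:
        ax.legend(loc="upper left", fontsize="small")
    ax.set_xlabel("lid end-to-end distance (A)")
    ax.set_ylabel("lid-core distance (A)")
    return ax
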