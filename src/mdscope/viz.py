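"""Presentation-layer rendering of the analysis maps (PNG/SVG)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap

#: discrete orange-to-blue diverging scale used for correlation maps
DCC_BOUNDS = [-1.0, -0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75, 1.0]
DCC_COLORS = [
    "#b35806", "#e08214", "#fdb863", "#fee0b6",
    "#d8daeb", "#b2abd2", "#8073ac", "#542788",
]

#: wavelet period bins (ns)
PERIOD_BOUNDS = [0.0, 5.0, 10.0, 15.0, 20.0, 25.0]

#: residual-RMSD bins (A)
RMSD_BOUNDS = [0.0, 2.0, 4.0, 6.0, 10.0]


def _discrete(ax, matrix, bounds, colors, extent=None):
    cmap = ListedColormap(colors)
    norm = BoundaryNorm(bounds, cmap.N)
    im = ax.imshow(
        matrix, cmap=cmap, norm=norm, origin="lower", aspect="auto", extent=extent
    )
    return im


def render_dccm(dmap, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = _discrete(ax, dmap.matrix, DCC_BOUNDS, DCC_COLORS)
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    fig.colorbar(im, ax=ax, label="cross-correlation")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_residual_rmsd(rmap, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    cmap = ListedColormap(["#ffffff", "#9ecae1", "#3182bd", "#000000"])
    norm = BoundaryNorm(RMSD_BOUNDS, cmap.N)
    extent = [
        rmap.window_times_ns[0], rmap.window_times_ns[-1],
        rmap.residue_ids[0], rmap.residue_ids[-1],
    ]
    im = ax.imshow(
        np.clip(rmap.values, 0, RMSD_BOUNDS[-1]),
        cmap=cmap, norm=norm, origin="lower", aspect="auto", extent=extent,
    )
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("residue")
    fig.colorbar(im, ax=ax, label="residual RMSD (A)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_wavelet(wmap, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    cmap = ListedColormap(["#ffffff", "#9ecae1", "#3182bd", "#08519c", "#000000"])
    norm = BoundaryNorm(PERIOD_BOUNDS, cmap.N)
    extent = [
        wmap.times_ns[0], wmap.times_ns[-1],
        wmap.residue_ids[0], wmap.residue_ids[-1],
    ]
    shown = np.where(
        wmap.significant if wmap.significant is not None else np.ones_like(wmap.power, bool),
        wmap.dominant_period_ns, 0.0,
    )
    im = ax.imshow(shown, cmap=cmap, norm=norm, origin="lower", aspect="auto", extent=extent)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("residue")
    fig.colorbar(im, ax=ax, label="dominant period (ns)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_fel(fel, path, max_energy: float = 12000.0) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    xc = 0.5 * (fel.x_edges[:-1] + fel.x_edges[1:])
    yc = 0.5 * (fel.y_edges[:-1] + fel.y_edges[1:])
    z = np.where(np.isfinite(fel.energy), fel.energy, max_energy)
    cs = ax.contourf(xc, yc, np.clip(z.T, 0, max_energy), levels=20, cmap="viridis")
    ax.set_xlabel(f"PC{fel.pc_pair[0] + 1} (A)")
    ax.set_ylabel(f"PC{fel.pc_pair[1] + 1} (A)")
    fig.colorbar(cs, ax=ax, label="free energy (J/mol)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_profile(profile, path, column: str = "bfactor") -> None:
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(profile["residue_id"], profile[column])
    ax.set_xlabel("residue")
    ax.set_ylabel({"bfactor": "B-factor (A$^2$)", "rmsf": "RMSF (A)"}.get(column, column))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
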