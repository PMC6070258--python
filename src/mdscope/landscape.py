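"""Free-energy landscapes over principal-component pairs, basins and bending.

G_a = -kT ln( P(q_a) / P_max(q) ) with T the simulation temperature (default
303 K) and P the joint kernel density estimate of two projection coordinates;
the most populated state sits at G = 0 and energies are reported in J/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .constants import BOLTZMANN_J_PER_MOL_K, DEFAULT_TEMPERATURE_K
from .io import AtomSelection, Structure, Trajectory
from .modes import ProjectionSeries

#: default basin threshold (J/mol) and grid resolution
BASIN_THRESHOLD_J_MOL = 100.0
GRID_CELLS = 100

#: grid padding beyond the data range, in kernel bandwidths
GRID_PAD_BANDWIDTHS = 3.0


def scott_bandwidth(x: np.ndarray) -> float:
    """Scott's rule per axis for a 2-D KDE: n^(-1/6) * std."""
    return float(len(x) ** (-1.0 / 6.0) * np.std(x))


@dataclass
class FELGrid:
    """2-D free-energy grid over two reaction coordinates."""

    energy: np.ndarray  # (nx, ny) J/mol, min = 0
    x_edges: np.ndarray
    y_edges: np.ndarray
    pc_pair: tuple[int, int]
    temperature: float
    frame_assignment: np.ndarray  # (n_frames, 2) cell indices, -1 if outside
    occupied: np.ndarray  # (nx, ny) bool: at least one frame in the cell
    samples: np.ndarray  # (n_frames, 2) the projection coordinates

    @property
    def cell_widths(self) -> tuple[float, float]:
        return (
            float(self.x_edges[1] - self.x_edges[0]),
            float(self.y_edges[1] - self.y_edges[0]),
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        df = pd.DataFrame(self.energy, index=xc, columns=yc)
        df.index.name = f"pc{self.pc_pair[0] + 1}"
        df.to_csv(path, sep="\t", float_format="%.3f")


def _binned_kde(
    x: np.ndarray,
    y: np.ndarray,
    grid: int,
    bw_x: float,
    bw_y: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast 2-D Gaussian KDE: histogram on the grid + Gaussian smoothing."""
    pad_x, pad_y = GRID_PAD_BANDWIDTHS * bw_x, GRID_PAD_BANDWIDTHS * bw_y
    x_edges = np.linspace(x.min() - pad_x, x.max() + pad_x, grid + 1)
    y_edges = np.linspace(y.min() - pad_y, y.max() + pad_y, grid + 1)
    hist, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    sigma = (bw_x / (x_edges[1] - x_edges[0]), bw_y / (y_edges[1] - y_edges[0]))
    density = ndimage.gaussian_filter(hist, sigma=sigma, mode="constant")
    return density, x_edges, y_edges


def fel_from_projections(
    proj: ProjectionSeries,
    pc_pair: tuple[int, int] = (0, 1),
    grid: int = GRID_CELLS,
    temperature: float = DEFAULT_TEMPERATURE_K,
    bandwidth: tuple[float, float] | None = None,
) -> FELGrid:
    """Free-energy landscape over two projection coordinates.

    The joint density is a Gaussian kernel estimate (Scott's rule per axis
    unless ``bandwidth`` overrides it) on a ``grid`` x ``grid`` mesh spanning
    the data range plus three bandwidths, and G = -kT ln(P / P_max).
    """
    if proj.n_frames < 100:
        raise ValueError(f"need >= 100 frames for a landscape, got {proj.n_frames}")
    i, j = pc_pair
    if max(i, j) >= proj.values.shape[1] or i == j:
        raise ValueError(f"invalid pc_pair {pc_pair} for {proj.values.shape[1]} modes")
    x, y = proj.values[:, i], proj.values[:, j]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (zero-variance) reaction coordinate")
    bw_x, bw_y = bandwidth if bandwidth is not None else (
        scott_bandwidth(x), scott_bandwidth(y),
    )
    density, x_edges, y_edges = _binned_kde(x, y, grid, bw_x, bw_y)
    p_max = density.max()
    with np.errstate(divide="ignore"):
        energy = -BOLTZMANN_J_PER_MOL_K * temperature * np.log(density / p_max)

    ix = np.clip(np.digitize(x, x_edges) - 1, 0, grid - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, grid - 1)
    assignment = np.stack([ix, iy], axis=1)
    occupied = np.zeros((grid, grid), dtype=bool)
    occupied[ix, iy] = True
    energy = np.where(density > 0, energy, np.inf)
    return FELGrid(
        energy=energy,
        x_edges=x_edges,
        y_edges=y_edges,
        pc_pair=pc_pair,
        temperature=temperature,
        frame_assignment=assignment,
        occupied=occupied,
        samples=np.stack([x, y], axis=1),
    )


@dataclass
class Basin:
    """A connected low-free-energy region and its member frames."""

    frames: np.ndarray
    centroid: np.ndarray  # mean PC coordinates of member frames
    min_cell: tuple[int, int]
    min_energy: float
    n_cells: int

    @property
    def occupancy(self) -> int:
        return len(self.frames)


def extract_basins(
    fel: FELGrid, threshold: float = BASIN_THRESHOLD_J_MOL
) -> list[Basin]:
    """Connected components (4-neighbor) of cells with G < threshold.

    Basins are ordered by depth (minimum G first); each carries its member
    frames, their centroid in PC space, and the minimum-energy cell.  An empty
    list (no cell below threshold) is returned, not an error.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    low = (fel.energy < threshold) & fel.occupied
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n_labels = ndimage.label(low, structure=structure)
    if n_labels == 0:
        return []
    cell_label = labels[fel.frame_assignment[:, 0], fel.frame_assignment[:, 1]]
    basins = []
    for lab in range(1, n_labels + 1):
        frames = np.flatnonzero(cell_label == lab)
        cells = np.argwhere(labels == lab)
        energies = fel.energy[labels == lab]
        k = int(np.argmin(energies))
        centroid = (
            fel.samples[frames].mean(axis=0)
            if len(frames)
            else np.array(
                [
                    0.5 * (fel.x_edges[cells[k, 0]] + fel.x_edges[cells[k, 0] + 1]),
                    0.5 * (fel.y_edges[cells[k, 1]] + fel.y_edges[cells[k, 1] + 1]),
                ]
            )
        )
        basins.append(
            Basin(
                frames=frames,
                centroid=centroid,
                min_cell=tuple(cells[k]),
                min_energy=float(energies[k]),
                n_cells=len(cells),
            )
        )
    basins.sort(key=lambda b: b.min_energy)
    return basins


def basin_shift(
    fel_a: FELGrid,
    fel_b: FELGrid,
    threshold: float = BASIN_THRESHOLD_J_MOL,
) -> np.ndarray:
    """Per-axis displacement of the deepest-basin centroid between two landscapes.

    Both grids must cover the same projection pair in a common coordinate frame
    (e.g. both runs projected onto one shared mode basis).
    """
    if fel_a.pc_pair != fel_b.pc_pair:
        raise ValueError("landscapes cover different PC pairs")
    basins_a = extract_basins(fel_a, threshold)
    basins_b = extract_basins(fel_b, threshold)
    if not basins_a or not basins_b:
        raise ValueError("no basin below threshold in at least one landscape")
    return basins_b[0].centroid - basins_a[0].centroid


def representative_frame(fel: FELGrid, basin: Basin) -> int:
    """Frame index closest (in PC space) to the basin's minimum-energy cell."""
    cx = 0.5 * (fel.x_edges[basin.min_cell[0]] + fel.x_edges[basin.min_cell[0] + 1])
    cy = 0.5 * (fel.y_edges[basin.min_cell[1]] + fel.y_edges[basin.min_cell[1] + 1])
    d = ((fel.samples - np.array([cx, cy])) ** 2).sum(axis=1)
    if len(basin.frames):
        member_d = d[basin.frames]
        return int(basin.frames[np.argmin(member_d)])
    return int(np.argmin(d))


def bend_angle_series(
    traj: Trajectory,
    triple: tuple[AtomSelection, AtomSelection, AtomSelection],
) -> np.ndarray:
    """Vertex angle (deg) at the middle of three single-residue Calpha selectors.

    Each selector must resolve to exactly one atom; coincident points in a
    frame yield NaN for that frame rather than an exception.
    """
    points = []
    for sel in triple:
        if len(sel) != 1:
            raise ValueError(f"selector {sel.label!r} must resolve to exactly 1 atom")
        points.append(traj.coords[:, sel.indices[0]])
    a, b, c = points
    v1 = a - b
    v2 = c - b
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    bad = (n1 == 0) | (n2 == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (v1 * v2).sum(axis=1) / (n1 * n2)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angles[bad] = np.nan
    return angles
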