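"""Collective-motion analysis: essential dynamics (PCA), elastic-network normal
modes, mode projections, Kullback-Leibler convergence and hinge detection.

Essential dynamics diagonalizes the mass-unweighted coordinate covariance of an
aligned trajectory; the elastic-network model (anisotropic network model on
Calpha atoms, uniform springs inside a distance cutoff) stands in for all-atom
normal modes and reproduces the same low-frequency collective picture.  Both
routes produce a ModeSet, so every downstream map (fluctuations, correlations,
conformers, dihedral deviations) works identically on either source.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .constants import BOLTZMANN_J_PER_MOL_K, DEFAULT_TEMPERATURE_K
from .io import AtomSelection, Structure, Trajectory

#: eigenvalues below RIGID_MODE_TOL * max are treated as rigid-body null space
RIGID_MODE_TOL = 1e-8

#: ENM defaults: interaction cutoff (A), spring constant (kJ/(mol A^2)),
#: and number of retained internal modes
ENM_CUTOFF = 12.0
ENM_GAMMA = 1.0
ENM_N_MODES = 26


@dataclass
class ModeSet:
    """Ordered orthonormal modes over 3N Cartesian coordinates.

    PCA eigenvalues are variances (A^2), sorted descending; ENM eigenvalues are
    harmonic force constants, sorted ascending after removal of the six
    rigid-body modes.
    """

    eigenvectors: np.ndarray  # (M, 3N)
    eigenvalues: np.ndarray  # (M,)
    mean_coords: np.ndarray  # (3N,)
    source: str  # "PCA" | "ENM"
    removed_rigid_modes: int = 0
    residue_ids: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_atoms(self) -> int:
        return self.eigenvectors.shape[1] // 3

    def eigenvalue_fractions(self) -> np.ndarray:
        """Per-mode eigenvalue normalized over the total (sums to 1)."""
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else np.zeros_like(self.eigenvalues)

    def cumulative_fractions(self) -> np.ndarray:
        return np.cumsum(self.eigenvalue_fractions())

    def amplitudes_sq(self, temperature: float = DEFAULT_TEMPERATURE_K) -> np.ndarray:
        """Squared thermal amplitude per mode: the eigenvalue for PCA, kT/eigenvalue for ENM."""
        if self.source == "PCA":
            return self.eigenvalues.copy()
        kt = BOLTZMANN_J_PER_MOL_K * temperature / 1000.0  # kJ/mol, matches gamma units
        return kt / self.eigenvalues


@dataclass
class ProjectionSeries:
    """Trajectory frames projected onto the leading modes (A per mode)."""

    times_ns: np.ndarray
    values: np.ndarray  # (n_frames, k)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            columns=[f"pc{i + 1}" for i in range(self.values.shape[1])],
        )
        df.insert(0, "time_ns", self.times_ns)
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each mode so its largest-magnitude component is positive."""
    out = vectors.copy()
    for m in range(len(out)):
        i = np.argmax(np.abs(out[m]))
        if out[m, i] < 0:
            out[m] = -out[m]
    return out


def covariance_matrix(
    traj: Trajectory, selection: AtomSelection, offset: int = 10
) -> np.ndarray:
    """3N x 3N coordinate covariance over frames sampled every ``offset`` frames.

    c_ij = <r_i r_j> - <r_i><r_j>; the trajectory must already be aligned.
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    sub = traj.coords[::offset, selection.indices]
    if len(sub) < 2:
        raise ValueError(
            f"need >= 2 sampled frames, got {len(sub)} (offset={offset})"
        )
    flat = sub.reshape(len(sub), -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    return centered.T @ centered / len(flat)


def eigendecompose(
    cov: np.ndarray,
    n_modes: int | None = None,
    mean_coords: np.ndarray | None = None,
    residue_ids: np.ndarray | None = None,
) -> ModeSet:
    """Top eigenpairs of a symmetric covariance matrix, descending by variance."""
    cov = np.asarray(cov, dtype=np.float64)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance matrix must be square")
    asym = np.abs(cov - cov.T).max()
    if asym > 1e-8 * max(1.0, np.abs(cov).max()):
        raise ValueError(f"matrix is not symmetric (max asymmetry {asym:.3g})")
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    order = np.argsort(w)[::-1]
    if n_modes is not None:
        order = order[:n_modes]
    eigenvalues = np.clip(w[order], 0.0, None)
    eigenvectors = _fix_sign(v[:, order].T)
    if mean_coords is None:
        mean_coords = np.zeros(cov.shape[0])
    return ModeSet(
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        mean_coords=np.asarray(mean_coords, dtype=np.float64).ravel(),
        source="PCA",
        residue_ids=residue_ids,
    )


def pca_modes(
    traj: Trajectory,
    selection: AtomSelection,
    n_modes: int = 20,
    offset: int = 10,
) -> ModeSet:
    """Essential dynamics of an aligned trajectory (covariance + diagonalization)."""
    cov = covariance_matrix(traj, selection, offset=offset)
    sub = traj.coords[::offset, selection.indices]
    mean = sub.reshape(len(sub), -1).mean(axis=0)
    return eigendecompose(
        cov,
        n_modes=n_modes,
        mean_coords=mean,
        residue_ids=traj.atoms.residue_id[selection.indices],
    )


# ---------------------------------------------------------------------------
# Elastic network model
# ---------------------------------------------------------------------------

def enm_hessian(coords: np.ndarray, cutoff: float, gamma: float) -> np.ndarray:
    """Anisotropic-network Hessian for pairwise springs inside ``cutoff``."""
    n = len(coords)
    dist = squareform(pdist(coords))
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if d == 0 or d > cutoff:
                continue
            dr = coords[j] - coords[i]
            block = -gamma * np.outer(dr, dr) / d**2
            hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hess


def enm_modes(
    structure: Structure,
    selection: AtomSelection,
    cutoff: float = ENM_CUTOFF,
    gamma: float = ENM_GAMMA,
    n_modes: int = ENM_N_MODES,
) -> ModeSet:
    """Elastic-network normal modes on the selected atoms.

    The contact graph at ``cutoff`` must be connected; exactly six near-zero
    eigenvalues (global translation/rotation) are identified and removed, and
    the lowest ``n_modes`` internal modes retained, ascending in stiffness.
    """
    idx = selection.indices
    coords = structure.coords[idx]
    if len(coords) < 3:
        raise ValueError("ENM needs at least 3 atoms")
    dist = squareform(pdist(coords))
    adjacency = (dist > 0) & (dist <= cutoff)
    n_comp, labels = connected_components(adjacency, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"contact graph is disconnected at cutoff {cutoff} A: "
            f"{n_comp} components with sizes {sizes.tolist()}"
        )
    hess = enm_hessian(coords, cutoff, gamma)
    w, v = np.linalg.eigh(hess)
    w = np.where(np.abs(w) < RIGID_MODE_TOL * np.abs(w).max(), 0.0, w)
    rigid = int((w <= RIGID_MODE_TOL * w.max()).sum())
    if rigid != 6:
        raise ValueError(
            f"expected exactly 6 rigid-body modes, found {rigid}: degenerate geometry"
        )
    keep = slice(rigid, rigid + n_modes) if n_modes is not None else slice(rigid, None)
    eigenvalues = w[keep]
    eigenvectors = _fix_sign(v[:, keep].T)
    return ModeSet(
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        mean_coords=coords.ravel().copy(),
        source="ENM",
        removed_rigid_modes=6,
        residue_ids=structure.residue_id[idx],
    )


# ---------------------------------------------------------------------------
# Projections and convergence
# ---------------------------------------------------------------------------

def project_trajectory(
    traj: Trajectory,
    modes: ModeSet,
    k: int | None = None,
    selection: AtomSelection | None = None,
) -> ProjectionSeries:
    """Project frames onto the first ``k`` modes: value_m(t) = (x(t) - mean) . v_m."""
    k = modes.n_modes if k is None else min(k, modes.n_modes)
    coords = traj.coords if selection is None else traj.coords[:, selection.indices]
    flat = coords.reshape(traj.n_frames, -1)
    if flat.shape[1] != modes.eigenvectors.shape[1]:
        raise ValueError(
            f"coordinate dimension {flat.shape[1]} does not match eigenvector "
            f"length {modes.eigenvectors.shape[1]}"
        )
    values = (flat - modes.mean_coords) @ modes.eigenvectors[:k].T
    return ProjectionSeries(times_ns=traj.times_ns, values=values)


def kld_histogram(
    p_samples: np.ndarray,
    q_samples: np.ndarray,
    n_bins: int = 100,
    pseudocount: float = 0.5,
    symmetrized: bool = False,
) -> float:
    """Histogram KLD(p || q) on the union support, with pseudo-count smoothing."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p_samples = np.asarray(p_samples, dtype=np.float64).ravel()
    q_samples = np.asarray(q_samples, dtype=np.float64).ravel()
    if len(p_samples) == 0 or len(q_samples) == 0:
        raise ValueError("both sample series must be non-empty")
    lo = min(p_samples.min(), q_samples.min())
    hi = max(p_samples.max(), q_samples.max())
    if hi == lo:
        hi = lo + 1e-12
    hp, _ = np.histogram(p_samples, bins=n_bins, range=(lo, hi))
    hq, _ = np.histogram(q_samples, bins=n_bins, range=(lo, hi))
    p = (hp + pseudocount) / (hp.sum() + pseudocount * n_bins)
    q = (hq + pseudocount) / (hq.sum() + pseudocount * n_bins)
    kld_pq = float(np.sum(p * np.log(p / q)))
    if not symmetrized:
        return kld_pq
    kld_qp = float(np.sum(q * np.log(q / p)))
    return 0.5 * (kld_pq + kld_qp)


def kld_convergence(
    proj_a: ProjectionSeries,
    proj_b: ProjectionSeries,
    n_bins: int = 100,
    pseudocount: float = 0.5,
    symmetrized: bool = False,
) -> np.ndarray:
    """Per-mode KLD between two projection series (p = the first series)."""
    if proj_a.values.shape[1] != proj_b.values.shape[1]:
        raise ValueError("projection series have different mode counts")
    return np.array(
        [
            kld_histogram(
                proj_a.values[:, m],
                proj_b.values[:, m],
                n_bins=n_bins,
                pseudocount=pseudocount,
                symmetrized=symmetrized,
            )
            for m in range(proj_a.values.shape[1])
        ]
    )


def split_halves(proj: ProjectionSeries) -> tuple[ProjectionSeries, ProjectionSeries]:
    """First-half / second-half split of a projection series."""
    half = proj.n_frames // 2
    return (
        ProjectionSeries(proj.times_ns[:half], proj.values[:half]),
        ProjectionSeries(proj.times_ns[half:], proj.values[half:]),
    )


def kld_time_course(
    proj: ProjectionSeries, n_points: int = 20, n_bins: int = 100
) -> pd.DataFrame:
    """Halves-KLD of the truncated series as a function of elapsed time.

    For each truncation point t the series [0, t] is split into halves and the
    per-mode KLD computed, giving the convergence-vs-time curve.
    """
    rows = []
    grid = np.unique(np.linspace(proj.n_frames // n_points, proj.n_frames, n_points).astype(int))
    for stop in grid:
        if stop < 4:
            continue
        trunc = ProjectionSeries(proj.times_ns[:stop], proj.values[:stop])
        a, b = split_halves(trunc)
        klds = kld_convergence(a, b, n_bins=n_bins)
        rows.append({"time_ns": proj.times_ns[stop - 1], **{f"pc{m + 1}": k for m, k in enumerate(klds)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mode-derived observables
# ---------------------------------------------------------------------------

def mode_fluctuations(
    modes: ModeSet,
    first_k: int | None = None,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> pd.DataFrame:
    """Per-atom mean-square fluctuation from the first ``first_k`` modes.

    MSF_i = sum_m amp_m^2 * |v_m,i|^2 with amp_m^2 the eigenvalue for PCA modes
    and kT/eigenvalue for ENM modes; returned with the B-factor conversion
    applied (B = (8/3) pi^2 * MSF).
    """
    from .fluctuations import B_FACTOR_PREFACTOR

    k = modes.n_modes if first_k is None else min(first_k, modes.n_modes)
    amps = modes.amplitudes_sq(temperature)[:k]
    comps = modes.eigenvectors[:k].reshape(k, modes.n_atoms, 3)
    msf = np.einsum("m,mia->i", amps, comps**2)
    resids = (
        modes.residue_ids
        if modes.residue_ids is not None
        else np.arange(modes.n_atoms)
    )
    return pd.DataFrame(
        {
            "residue_id": resids.astype(int),
            "msf": msf,
            "rmsf": np.sqrt(msf),
            "bfactor": msf * B_FACTOR_PREFACTOR,
        }
    )


def mode_conformers(
    modes: ModeSet,
    mode_index: int,
    amplitude: float,
    n_frames: int = 20,
    atoms: Structure | None = None,
    dt_ps: float = 1.0,
) -> Trajectory:
    """Sinusoidal sweep along one mode: x(t) = mean + A sin(2 pi t / n) * v."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    v = modes.eigenvectors[mode_index]
    t = np.arange(n_frames)
    frames = (
        modes.mean_coords[None, :]
        + amplitude * np.sin(2 * np.pi * t / n_frames)[:, None] * v[None, :]
    ).reshape(n_frames, modes.n_atoms, 3)
    if atoms is None:
        n = modes.n_atoms
        atoms = Structure(
            atom_serial=np.arange(1, n + 1),
            atom_name=np.array(["CA"] * n),
            residue_name=np.array(["ALA"] * n),
            residue_id=(
                modes.residue_ids if modes.residue_ids is not None else np.arange(1, n + 1)
            ),
            chain_id=np.array(["A"] * n),
            coords=modes.mean_coords.reshape(n, 3),
        )
    return Trajectory(coords=frames, dt_ps=dt_ps, atoms=atoms)


def pooled_mode_conformers(
    modes: ModeSet,
    first_k: int = 3,
    amplitude: float | None = None,
    n_frames: int = 20,
    atoms: Structure | None = None,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> Trajectory:
    """Concatenated sinusoidal sweeps of the first k modes (thermal amplitudes)."""
    amps = np.sqrt(modes.amplitudes_sq(temperature)[:first_k])
    if amplitude is not None:
        amps = np.full(first_k, amplitude)
    parts = [
        mode_conformers(modes, m, float(amps[m]), n_frames=n_frames, atoms=atoms)
        for m in range(first_k)
    ]
    coords = np.concatenate([p.coords for p in parts], axis=0)
    return Trajectory(coords=coords, dt_ps=parts[0].dt_ps, atoms=parts[0].atoms)


# ---------------------------------------------------------------------------
# Dihedral hinge detection
# ---------------------------------------------------------------------------

def wrap_angle_deg(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences (deg) into (-180, 180]."""
    return -((-np.asarray(delta) + 180.0) % 360.0 - 180.0)


def _backbone_indices(structure: Structure):
    """Per-residue (N, CA, C) atom indices in chain order; None where missing."""
    table: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    for i, (ch, rid, name) in enumerate(
        zip(structure.chain_id, structure.residue_id, structure.atom_name)
    ):
        key = (str(ch), int(rid))
        if key not in table:
            table[key] = {}
            order.append(key)
        if name in ("N", "CA", "C"):
            table[key].setdefault(str(name), i)
    return order, table


def dihedral_aud(
    conformers: Trajectory,
    average: Structure,
    hinge_percentile: float = 90.0,
) -> pd.DataFrame:
    """Average unsigned deviation of phi/psi backbone dihedrals vs a reference.

    Per residue, the mean over conformers of |wrapped(angle - angle_ref)| in
    degrees.  Chain breaks and missing backbone atoms yield flagged (NaN) rows,
    never silent zeros.  Hinge candidates are local maxima of
    max(AUD_phi, AUD_psi) above ``hinge_percentile``.
    """
    from MDAnalysis.lib.distances import calc_dihedrals

    order, table = _backbone_indices(average)

    quads_phi, quads_psi = [], []
    flags = []
    for r, key in enumerate(order):
        prev_key = order[r - 1] if r > 0 else None
        next_key = order[r + 1] if r + 1 < len(order) else None
        res = table[key]
        has_bb = all(a in res for a in ("N", "CA", "C"))
        phi_ok = (
            has_bb
            and prev_key is not None
            and prev_key[0] == key[0]
            and "C" in table[prev_key]
        )
        psi_ok = (
            has_bb
            and next_key is not None
            and next_key[0] == key[0]
            and "N" in table[next_key]
        )
        quads_phi.append(
            (table[prev_key]["C"], res["N"], res["CA"], res["C"]) if phi_ok else None
        )
        quads_psi.append(
            (res["N"], res["CA"], res["C"], table[next_key]["N"]) if psi_ok else None
        )
        flags.append(not has_bb)

    def _angles(coords: np.ndarray, quads) -> np.ndarray:
        valid = [q for q in quads if q is not None]
        if not valid:
            return np.full(len(quads), np.nan)
        arr = np.array(valid)
        vals = np.degrees(
            calc_dihedrals(coords[arr[:, 0]], coords[arr[:, 1]], coords[arr[:, 2]], coords[arr[:, 3]])
        )
        out = np.full(len(quads), np.nan)
        out[[i for i, q in enumerate(quads) if q is not None]] = vals
        return out

    ref_phi = _angles(average.coords, quads_phi)
    ref_psi = _angles(average.coords, quads_psi)
    acc_phi = np.zeros(len(order))
    acc_psi = np.zeros(len(order))
    for f in range(conformers.n_frames):
        acc_phi += np.abs(wrap_angle_deg(_angles(conformers.coords[f], quads_phi) - ref_phi))
        acc_psi += np.abs(wrap_angle_deg(_angles(conformers.coords[f], quads_psi) - ref_psi))
    aud_phi = acc_phi / conformers.n_frames
    aud_psi = acc_psi / conformers.n_frames

    df = pd.DataFrame(
        {
            "chain": [k[0] for k in order],
            "residue_id": [k[1] for k in order],
            "aud_phi": aud_phi,
            "aud_psi": aud_psi,
            "flagged": np.array(flags) | np.isnan(aud_phi) & np.isnan(aud_psi),
        }
    )
    combined = np.nanmax(df[["aud_phi", "aud_psi"]].to_numpy(), axis=1)
    finite = combined[np.isfinite(combined)]
    thr = np.percentile(finite, hinge_percentile) if len(finite) else np.inf
    is_peak = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        if not np.isfinite(combined[i]) or combined[i] < thr:
            continue
        left = combined[i - 1] if i > 0 and np.isfinite(combined[i - 1]) else -np.inf
        right = combined[i + 1] if i + 1 < len(df) and np.isfinite(combined[i + 1]) else -np.inf
        is_peak[i] = combined[i] >= left and combined[i] >= right
    df["hinge_candidate"] = is_peak
    return df


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_modes(modes: ModeSet, directory: str | Path) -> None:
    """Eigenvalue table (TSV), eigenvector matrix (npy) and mean coordinates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "mode": np.arange(1, modes.n_modes + 1),
            "eigenvalue": modes.eigenvalues,
            "fraction": modes.eigenvalue_fractions(),
            "cumulative_fraction": modes.cumulative_fractions(),
        }
    )
    df.to_csv(directory / "eigenvalues.tsv", sep="\t", index=False)
    np.save(directory / "eigenvectors.npy", modes.eigenvectors)
    np.save(directory / "mean_coords.npy", modes.mean_coords)
    meta = {
        "source": modes.source,
        "removed_rigid_modes": modes.removed_rigid_modes,
    }
    pd.Series(meta).to_json(directory / "modes_meta.json")
    if modes.residue_ids is not None:
        np.save(directory / "residue_ids.npy", modes.residue_ids)


def load_modes(directory: str | Path) -> ModeSet:
    directory = Path(directory)
    df = pd.read_csv(directory / "eigenvalues.tsv", sep="\t")
    meta = pd.read_json(directory / "modes_meta.json", typ="series")
    resid_path = directory / "residue_ids.npy"
    return ModeSet(
        eigenvectors=np.load(directory / "eigenvectors.npy"),
        eigenvalues=df["eigenvalue"].to_numpy(),
        mean_coords=np.load(directory / "mean_coords.npy"),
        source=str(meta["source"]),
        removed_rigid_modes=int(meta["removed_rigid_modes"]),
        residue_ids=np.load(resid_path) if resid_path.exists() else None,
    )
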