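"""Synthetic trajectories with planted, recoverable structure.

Every generator is a pure function of its parameters (seed included) and
returns ground-truth metadata sufficient to compute the expected value of any
downstream analysis without re-deriving the construction.  The fixtures
emulate, at desk scale, the phenomena a microsecond protein simulation shows:
Gaussian fluctuations with a few dominant collective modes, anti-correlated
two-domain hinge motion, per-region periodic oscillations, a two-basin
conformational equilibrium whose populations shift on ligand binding, and a
ligand in a hydrogen-bonding pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .io import Structure, Trajectory
from .modes import ModeSet, _fix_sign

#: default trajectory scale: snapshots every 10 ps
DT_PS_DEFAULT = 10.0

#: default isotropic per-atom noise floor (A)
NOISE_DEFAULT = 0.2


def ca_chain_structure(n_residues: int, jitter: float = 0.0, seed: int = 0) -> Structure:
    """A Calpha-only helical chain: compact, three-dimensional, connected."""
    # alpha-helix-like trace: 3.8 A between neighbours, 5.4 A pitch per turn,
    # dense enough that an elastic network at the default cutoff has no
    # internal mechanisms
    i = np.arange(n_residues)
    coords = np.stack(
        [2.3 * np.cos(1.745 * i), 2.3 * np.sin(1.745 * i), 1.5 * i], axis=1
    )
    if jitter > 0:
        coords = coords + np.random.default_rng(seed).normal(0, jitter, coords.shape)
    return Structure(
        atom_serial=i + 1,
        atom_name=np.array(["CA"] * n_residues),
        residue_name=np.array(["ALA"] * n_residues),
        residue_id=i + 1,
        chain_id=np.array(["A"] * n_residues),
        coords=coords,
        bfactor=np.zeros(n_residues),
        element=np.array(["C"] * n_residues),
    )


@dataclass
class SyntheticResult:
    """Trajectory plus the ground truth that generated it."""

    trajectory: Trajectory
    structure: Structure
    meta: dict[str, Any] = field(default_factory=dict)
    modes: ModeSet | None = None


# ---------------------------------------------------------------------------
# Gaussian trajectories with planted covariance / mode structure
# ---------------------------------------------------------------------------

def gen_gaussian_traj(
    n_residues: int = 200,
    n_frames: int = 20000,
    dt_ps: float = DT_PS_DEFAULT,
    amplitudes: tuple[float, ...] = (3.0, 2.0, 1.0),
    noise: float = NOISE_DEFAULT,
    seed: int = 0,
    covariance: np.ndarray | None = None,
) -> SyntheticResult:
    """Frames = mean + sum_m amp_m z_m(t) v_m + isotropic noise.

    The planted directions are random orthonormal 3N-vectors; the ground-truth
    ModeSet carries them with eigenvalues amp^2 + noise^2 (the true directional
    variance of the sampled distribution, noise floor included).  Passing an
    explicit ``covariance`` samples from it instead (must be PSD).
    """
    rng = np.random.default_rng(seed)
    structure = ca_chain_structure(n_residues)
    mean = structure.coords.ravel()
    dim = 3 * n_residues

    if covariance is not None:
        covariance = np.asarray(covariance, dtype=np.float64)
        w, v = np.linalg.eigh((covariance + covariance.T) / 2.0)
        if w.min() < -1e-8 * max(abs(w).max(), 1.0):
            raise ValueError("planted covariance is not positive semidefinite")
        w = np.clip(w, 0.0, None)
        z = rng.standard_normal((n_frames, dim))
        flat = mean + z @ (v * np.sqrt(w)).T
        order = np.argsort(w)[::-1]
        truth = ModeSet(
            eigenvectors=_fix_sign(v[:, order].T),
            eigenvalues=w[order],
            mean_coords=mean,
            source="PCA",
            residue_ids=structure.residue_id,
        )
        meta = {"seed": seed, "covariance": "explicit", "noise": 0.0}
    else:
        k = len(amplitudes)
        q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
        vectors = _fix_sign(q.T)  # (k, 3N) orthonormal
        amps = np.asarray(amplitudes, dtype=np.float64)
        z = rng.standard_normal((n_frames, k))
        flat = mean + (z * amps) @ vectors
        if noise > 0:
            flat = flat + rng.normal(0.0, noise, (n_frames, dim))
        truth = ModeSet(
            eigenvectors=vectors,
            eigenvalues=amps**2 + noise**2,
            mean_coords=mean,
            source="PCA",
            residue_ids=structure.residue_id,
        )
        meta = {"seed": seed, "amplitudes": list(amplitudes), "noise": noise}
    traj = Trajectory(coords=flat.reshape(n_frames, n_residues, 3), dt_ps=dt_ps, atoms=structure)
    return SyntheticResult(trajectory=traj, structure=structure, meta=meta, modes=truth)


# ---------------------------------------------------------------------------
# Two-domain hinge
# ---------------------------------------------------------------------------

def _backbone_chain(
    n_residues: int, pivot: int, arm_angle_deg: float = 120.0
) -> Structure:
    """Backbone (N, CA, C) chain with two straight arms meeting at the pivot.

    Calpha atoms lie in the z = 0 plane; the pivot's N-CA bond points along +z
    so a rotation of the downstream arm about that bond is simultaneously a
    pure phi-dihedral change at the pivot and an in-plane change of the
    vertex (bend) angle.
    """
    spacing = 3.8
    up_dir = np.array([-1.0, 0.0, 0.0])
    theta = np.radians(180.0 - arm_angle_deg)
    down_dir = np.array([np.cos(-theta), np.sin(-theta), 0.0])
    down_perp = np.array([-np.sin(-theta), np.cos(-theta), 0.0])

    ca = np.zeros((n_residues, 3))
    for i in range(n_residues):
        zig = 0.4 * (-1) ** i
        if i < pivot:
            ca[i] = (pivot - i) * spacing * up_dir + np.array([0.0, zig, 0.0])
        elif i == pivot:
            ca[i] = 0.0
        else:
            ca[i] = (i - pivot) * spacing * down_dir + zig * down_perp

    n_off = np.array([-0.45, 0.95, 0.35])
    c_off = np.array([0.55, 0.95, -0.35])
    names, resids, coords, elements = [], [], [], []
    for i in range(n_residues):
        n_pos = ca[i] + (np.array([0.0, 0.0, 1.46]) if i == pivot else n_off)
        for name, pos, el in (("N", n_pos, "N"), ("CA", ca[i], "C"), ("C", ca[i] + c_off, "C")):
            names.append(name)
            resids.append(i + 1)
            coords.append(pos)
            elements.append(el)
    n_atoms = len(names)
    return Structure(
        atom_serial=np.arange(1, n_atoms + 1),
        atom_name=np.array(names),
        residue_name=np.array(["ALA"] * n_atoms),
        residue_id=np.array(resids),
        chain_id=np.array(["A"] * n_atoms),
        coords=np.array(coords),
        bfactor=np.zeros(n_atoms),
        element=np.array(elements),
    )


def gen_two_domain_hinge(
    n_residues_block1: int = 25,
    n_residues_block2: int = 25,
    theta0_deg: float = 20.0,
    period_frames: int = 200,
    n_frames: int = 2000,
    dt_ps: float = DT_PS_DEFAULT,
    noise: float = 0.05,
    seed: int = 0,
) -> SyntheticResult:
    """Two rigid arms articulated at a single pivot residue.

    Block 1 stays fixed; block 2 (everything downstream of the pivot's
    N-CA bond) is rigidly rotated about that bond by
    theta(t) = theta0 sin(2 pi t / period), plus a small isotropic noise
    floor.  By construction the rotation is a pure phi change at the pivot
    (expected AUD_phi = 2 theta0 / pi) and an equal change of the bend angle
    at the pivot Calpha.
    """
    n_res = n_residues_block1 + 1 + n_residues_block2
    pivot = n_residues_block1  # 0-based residue index of the hinge
    structure = _backbone_chain(n_res, pivot)
    rng = np.random.default_rng(seed)

    downstream = np.zeros(structure.n_atoms, dtype=bool)
    for a in range(structure.n_atoms):
        rid = structure.residue_id[a] - 1
        if rid > pivot or (rid == pivot and structure.atom_name[a] == "C"):
            downstream[a] = True

    t = np.arange(n_frames)
    theta = np.radians(theta0_deg) * np.sin(2 * np.pi * t / period_frames)
    coords = np.empty((n_frames, structure.n_atoms, 3))
    base = structure.coords
    for f in range(n_frames):
        c, s = np.cos(theta[f]), np.sin(theta[f])
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        frame = base.copy()
        frame[downstream] = base[downstream] @ rot.T
        coords[f] = frame
    if noise > 0:
        coords = coords + rng.normal(0.0, noise, coords.shape)

    pivot_resid = pivot + 1
    meta = {
        "seed": seed,
        "theta0_deg": theta0_deg,
        "period_frames": period_frames,
        "noise": noise,
        "pivot_residue": pivot_resid,
        "block1_residues": (1, n_residues_block1),
        "block2_residues": (pivot_resid + 1, n_res),
        "bend_triple_residues": (
            max(1, pivot_resid - n_residues_block1 // 2),
            pivot_resid,
            min(n_res, pivot_resid + n_residues_block2 // 2),
        ),
        "expected_aud_phi_deg": 2.0 * theta0_deg / np.pi,
    }
    traj = Trajectory(coords=coords, dt_ps=dt_ps, atoms=structure)
    return SyntheticResult(trajectory=traj, structure=structure, meta=meta)


# ---------------------------------------------------------------------------
# Periodic oscillations per residue group
# ---------------------------------------------------------------------------

def gen_oscillatory(
    groups: dict[str, dict],
    n_residues: int = 60,
    n_frames: int = 5000,
    dt_ps: float = 100.0,
    noise: float = NOISE_DEFAULT,
    seed: int = 0,
) -> SyntheticResult:
    """Residue groups oscillating along fixed random directions at set periods.

    ``groups`` maps a name to {"residues": (lo, hi), "period_ns": float,
    "amplitude": float, optionally "burst_frames": (f0, f1)}.  Atoms outside
    every group only carry the white-noise floor.  Periods must be resolvable:
    within [2 dt, n_frames dt / 2].
    """
    dt_ns = dt_ps / 1000.0
    rng = np.random.default_rng(seed)
    structure = ca_chain_structure(n_residues)
    coords = np.broadcast_to(
        structure.coords, (n_frames, n_residues, 3)
    ).copy()
    t_ns = np.arange(n_frames) * dt_ns
    for name, g in groups.items():
        period = float(g["period_ns"])
        if not (2 * dt_ns <= period <= n_frames * dt_ns / 2):
            raise ValueError(
                f"group {name!r}: period {period} ns outside "
                f"[{2 * dt_ns}, {n_frames * dt_ns / 2}] ns"
            )
        lo, hi = g["residues"]
        rows = np.flatnonzero((structure.residue_id >= lo) & (structure.residue_id <= hi))
        amp = float(g.get("amplitude", 2.0))
        phase = rng.uniform(0, 2 * np.pi)
        envelope = np.ones(n_frames)
        if "burst_frames" in g:
            f0, f1 = g["burst_frames"]
            envelope = np.zeros(n_frames)
            envelope[f0:f1] = 1.0
        signal = amp * envelope * np.sin(2 * np.pi * t_ns / period + phase)
        for r in rows:
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            coords[:, r] += signal[:, None] * u
    if noise > 0:
        coords = coords + rng.normal(0.0, noise, coords.shape)
    meta = {"seed": seed, "groups": groups, "noise": noise, "dt_ps": dt_ps}
    return SyntheticResult(
        trajectory=Trajectory(coords=coords, dt_ps=dt_ps, atoms=structure),
        structure=structure,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Double-well (two-basin) trajectories
# ---------------------------------------------------------------------------

def gen_double_well(
    n_residues: int = 50,
    n_frames: int = 20000,
    dt_ps: float = DT_PS_DEFAULT,
    occupancy: float = 0.8,
    separation: float = 6.0,
    sigma_well: float = 1.0,
    noise: float = NOISE_DEFAULT,
    seed: int = 0,
    mode_seed: int | None = None,
) -> SyntheticResult:
    """Two-component Gaussian mixture along a planted pair of collective modes.

    The first mode coordinate is drawn from N(-separation/2, sigma_well) with
    probability ``occupancy`` and N(+separation/2, sigma_well) otherwise; the
    second mode coordinate is N(0, sigma_well).  The ground-truth ModeSet
    provides the shared projection basis for landscape comparisons: pass the
    same ``mode_seed`` (default: ``seed``) to paired runs — e.g. a free and a
    ligand-bound condition differing only in well populations — so both live
    in one mode basis.
    """
    if not (0.0 < occupancy < 1.0):
        raise ValueError("occupancy must be inside (0, 1)")
    rng = np.random.default_rng(seed)
    structure = ca_chain_structure(n_residues)
    mean = structure.coords.ravel()
    dim = 3 * n_residues
    rng_modes = np.random.default_rng(seed if mode_seed is None else mode_seed)
    q, _ = np.linalg.qr(rng_modes.standard_normal((dim, 2)))
    vectors = _fix_sign(q.T)

    in_a = rng.random(n_frames) < occupancy
    centers = np.where(in_a, -separation / 2.0, separation / 2.0)
    c1 = rng.normal(centers, sigma_well)
    c2 = rng.normal(0.0, sigma_well, n_frames)
    flat = mean + np.outer(c1, vectors[0]) + np.outer(c2, vectors[1])
    if noise > 0:
        flat = flat + rng.normal(0.0, noise, (n_frames, dim))
    var1 = sigma_well**2 + occupancy * (1 - occupancy) * separation**2
    truth = ModeSet(
        eigenvectors=vectors,
        eigenvalues=np.array([var1 + noise**2, sigma_well**2 + noise**2]),
        mean_coords=mean,
        source="PCA",
        residue_ids=structure.residue_id,
    )
    meta = {
        "seed": seed,
        "occupancy": occupancy,
        "center_a_pc1": -separation / 2.0,
        "center_b_pc1": separation / 2.0,
        "sigma_well": sigma_well,
        "noise": noise,
        "state": np.where(in_a, "A", "B"),
    }
    return SyntheticResult(
        trajectory=Trajectory(
            coords=flat.reshape(n_frames, n_residues, 3), dt_ps=dt_ps, atoms=structure
        ),
        structure=structure,
        meta=meta,
        modes=truth,
    )


# ---------------------------------------------------------------------------
# Hydrogen-bond pocket fixture
# ---------------------------------------------------------------------------

def gen_hbond_fixture(seed: int = 0, n_frames: int = 200) -> SyntheticResult:
    """A rigid 10-residue pocket and a 23-atom disaccharide-like ligand.

    Three donor-acceptor pairs are planted with per-frame presence fractions
    (1.0, 0.5, 0.0) on a deterministic schedule: the first pair is bonded in
    every frame (with an explicit donor hydrogen), the second in even frames
    only (distance criterion), the third held at 6.5 A throughout.
    """
    rng = np.random.default_rng(seed)
    ring_r = 9.0

    names, resnames, resids, chains, coords, elements = [], [], [], [], [], []

    def add(name, resname, resid, chain, pos, element):
        names.append(name)
        resnames.append(resname)
        resids.append(resid)
        chains.append(chain)
        coords.append(np.asarray(pos, dtype=float))
        elements.append(element)

    # Pocket: 10 residues on a ring, each with N, CA, C, O
    for i in range(1, 11):
        phi = 2 * np.pi * i / 10.0
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        ca = ring_r * radial
        add("N", "GLY", i, "A", ca - 1.4 * radial, "N")
        add("CA", "GLY", i, "A", ca, "C")
        add("C", "GLY", i, "A", ca + np.array([0.0, 0.0, 1.5]), "C")
        add("O", "GLY", i, "A", ca + np.array([0.0, 0.0, 2.9]), "O")

    def pocket_pos(resid, name):
        for k in range(len(names)):
            if resids[k] == resid and names[k] == name and chains[k] == "A":
                return coords[k]
        raise KeyError((resid, name))

    center = np.zeros(3)

    def inward(pos, dist):
        u = center - pos
        return pos + dist * u / np.linalg.norm(u)

    # Ligand: 23 atoms near the center (12 C, 7 bystander O, 3 planted O, 1 H)
    lig_positions = 0.9 * rng.standard_normal((19, 3))
    norms = np.linalg.norm(lig_positions, axis=1, keepdims=True)
    lig_positions *= np.minimum(1.0, 2.5 / np.maximum(norms, 1e-9))  # keep the blob compact
    for k in range(12):
        add(f"C{k + 1}", "LIG", 100, "L", lig_positions[k], "C")
    for k in range(7):
        add(f"O{k + 4}", "LIG", 100, "L", lig_positions[12 + k], "O")

    o1 = inward(pocket_pos(3, "N"), 2.9)
    add("O1", "LIG", 100, "L", o1, "O")
    add("HO1", "LIG", 100, "L", o1 + 1.0 * (pocket_pos(3, "N") - o1) / 2.9, "H")
    o2_near = inward(pocket_pos(5, "N"), 2.9)
    o2_far = inward(pocket_pos(5, "N"), 6.0)
    add("O2", "LIG", 100, "L", o2_near, "O")
    add("O3", "LIG", 100, "L", inward(pocket_pos(7, "O"), 6.5), "O")

    structure = Structure(
        atom_serial=np.arange(1, len(names) + 1),
        atom_name=np.array(names),
        residue_name=np.array(resnames),
        residue_id=np.array(resids),
        chain_id=np.array(chains),
        coords=np.array(coords),
        bfactor=np.zeros(len(names)),
        element=np.array(elements),
    )
    o2_index = int(np.flatnonzero(structure.atom_name == "O2")[0])
    frames = np.broadcast_to(
        structure.coords, (n_frames, structure.n_atoms, 3)
    ).copy()
    frames[1::2, o2_index] = o2_far  # odd frames: pair 2 broken
    meta = {
        "seed": seed,
        "pairs": [
            {"ligand_atom": "O1", "residue": 3, "residue_atom": "N", "expected_pct": 100.0},
            {"ligand_atom": "O2", "residue": 5, "residue_atom": "N", "expected_pct": 50.0},
            {"ligand_atom": "O3", "residue": 7, "residue_atom": "O", "expected_pct": 0.0},
        ],
    }
    return SyntheticResult(
        trajectory=Trajectory(coords=frames, dt_ps=DT_PS_DEFAULT, atoms=structure),
        structure=structure,
        meta=meta,
    )
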