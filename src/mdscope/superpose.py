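"""Least-squares (Kabsch) superposition and RMSD quantities.

Global rotation/translation is removed by fitting each frame onto a reference
(or onto the iteratively refined trajectory average) before any fluctuation,
covariance or wavelet analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AtomSelection, Structure, Trajectory

#: convergence threshold (A) and iteration cap for alignment to the average
AVERAGE_FIT_TOL = 1e-6
AVERAGE_FIT_MAX_ITER = 10

#: default color-scale bin edges (A) for residual-RMSD maps
RESIDUAL_RMSD_BINS = (2.0, 4.0, 6.0)


class DegenerateGeometryError(ValueError):
    """Fewer than 3 atoms, or a (near-)collinear configuration."""


@dataclass
class FitResult:
    """Rigid transform x -> rotation @ (x - mobile centroid) + reference centroid."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    mobile_centroid: np.ndarray

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mobile_centroid) @ self.rotation.T + self.translation


def kabsch_fit(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> FitResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Minimizes the weighted sum of squared deviations over all proper rotations
    and translations; the returned rotation has determinant +1.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n_atoms, 3)")
    n = len(mobile)
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 atoms to fit, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    a = (mobile - cm) * w[:, None]
    b = reference - cr
    h = a.T @ b
    # Rank of the weighted configuration; collinear point sets leave the
    # rotation about the line undetermined.
    if np.linalg.matrix_rank(mobile - cm, tol=1e-9) < 2:
        raise DegenerateGeometryError("collinear (rank-deficient) configuration")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fit = FitResult(rotation=rotation, translation=cr, rmsd=0.0, mobile_centroid=cm)
    diff = fit.transform(mobile) - reference
    fit.rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum()))
    return fit


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) RMSD between two coordinate sets."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def align_trajectory(
    traj: Trajectory,
    reference: Structure | str = "average",
    fit_selection: AtomSelection | None = None,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Fit every frame on ``fit_selection`` and apply the transform to all atoms.

    ``reference`` may be a Structure or the string ``"average"``, in which case
    frames are fitted to the trajectory mean, the mean recomputed, and the two
    steps iterated to a fixed point (max-atom shift < 1e-6 A, <= 10 iterations).
    """
    idx = (
        fit_selection.indices
        if fit_selection is not None
        else np.arange(traj.n_atoms)
    )
    coords = traj.coords.copy()

    def _fit_all(ref_sel: np.ndarray) -> None:
        for f in range(len(coords)):
            fit = kabsch_fit(coords[f, idx], ref_sel, weights=weights)
            coords[f] = fit.transform(coords[f])

    if isinstance(reference, Structure):
        _fit_all(reference.coords[idx])
    elif reference == "average":
        mean = coords.mean(axis=0)
        for _ in range(AVERAGE_FIT_MAX_ITER):
            _fit_all(mean[idx])
            new_mean = coords.mean(axis=0)
            shift = np.abs(new_mean - mean).max()
            mean = new_mean
            if shift < AVERAGE_FIT_TOL:
                break
    else:
        raise ValueError("reference must be a Structure or 'average'")
    return traj.with_coords(coords)


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection: AtomSelection,
    fit: bool = True,
    fit_selection: AtomSelection | None = None,
) -> np.ndarray:
    """Per-frame RMSD (A) of ``selection`` against a reference structure.

    With ``fit=True`` each frame is first least-squares fitted onto the
    reference on ``fit_selection`` (default: the same selection), so exclusion
    selections ("everything except a mobile domain") behave as expected.
    """
    idx = selection.indices
    if idx.max() >= traj.n_atoms or idx.max() >= reference.n_atoms:
        raise ValueError("selection exceeds the atom tables being compared")
    fidx = fit_selection.indices if fit_selection is not None else idx
    ref = reference.coords
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        if fit:
            k = kabsch_fit(frame[fidx], ref[fidx])
            frame = k.transform(frame)
        out[f] = rmsd(frame[idx], ref[idx])
    return out


@dataclass
class ResidualRMSDMap:
    """residue x time matrix of per-residue deviations (A)."""

    values: np.ndarray
    residue_ids: np.ndarray
    window_times_ns: np.ndarray
    bin_edges: tuple = RESIDUAL_RMSD_BINS

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.values,
            index=self.residue_ids,
            columns=[f"{t:.4f}" for t in self.window_times_ns],
        )
        df.index.name = "residue_id"
        df.to_csv(path, sep="\t")


def residual_rmsd_map(
    traj: Trajectory,
    selection: AtomSelection,
    window: int = 1,
    reference: Structure | str = "average",
) -> ResidualRMSDMap:
    """Per-residue deviation from its reference position, through time.

    The reference position is each atom's time average (default) or its
    position in a supplied structure (e.g. the crystallographic reference).
    Deviations are RMS-combined over a residue's selected atoms and averaged
    over non-overlapping windows of ``window`` frames.
    """
    if window < 1 or window > traj.n_frames:
        raise ValueError(
            f"window must be in [1, n_frames={traj.n_frames}], got {window}"
        )
    idx = selection.indices
    sub = traj.coords[:, idx]  # (F, n, 3)
    if isinstance(reference, Structure):
        ref = reference.coords[idx]
    else:
        ref = sub.mean(axis=0)
    sq = ((sub - ref) ** 2).sum(axis=2)  # (F, n) squared deviation per atom

    resids = traj.atoms.residue_id[idx]
    chains = traj.atoms.chain_id[idx]
    keys = []
    seen: dict[tuple[str, int], int] = {}
    groups: list[list[int]] = []
    for col, (ch, rid) in enumerate(zip(chains, resids)):
        key = (str(ch), int(rid))
        if key not in seen:
            seen[key] = len(groups)
            groups.append([])
            keys.append(key)
        groups[seen[key]].append(col)

    n_windows = traj.n_frames // window
    per_res = np.empty((len(groups), n_windows))
    for g, cols in enumerate(groups):
        dev = np.sqrt(sq[:, cols].mean(axis=1))  # (F,) rms over the residue's atoms
        trimmed = dev[: n_windows * window].reshape(n_windows, window)
        per_res[g] = trimmed.mean(axis=1)
    t_mid = (np.arange(n_windows) + 0.5) * window * traj.dt_ps / 1000.0
    return ResidualRMSDMap(
        values=per_res,
        residue_ids=np.array([rid for _, rid in keys]),
        window_times_ns=t_mid,
    )
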