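"""Dynamical cross-correlation maps (DCCM) and quantitative map comparison.

C_ij = c_ij / sqrt(c_ii c_jj) with c_ij = <dr_i . dr_j> the scalar covariance
of displacement vectors after least-squares fitting; +1 is fully correlated,
-1 fully anti-correlated motion.  Maps can be computed from a trajectory, an
X-ray structure ensemble, or analytically from a ModeSet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_TEMPERATURE_K
from .io import AtomSelection, Structure, Trajectory
from .modes import ModeSet
from .superpose import kabsch_fit

#: variance below this (relative to the max) marks an atom as undefined
ZERO_VARIANCE_TOL = 1e-12


@dataclass
class DCCMap:
    """Symmetric N x N normalized cross-correlation map in [-1, 1]."""

    matrix: np.ndarray
    labels: np.ndarray  # residue ids (or atom indices at atom granularity)
    undefined: np.ndarray  # boolean per label: zero-variance rows/columns
    granularity: str  # "atom" | "residue"
    source: str  # "trajectory" | "modes" | "ensemble"

    def __post_init__(self) -> None:
        m = self.matrix
        assert np.abs(m[~self.undefined][:, ~self.undefined]).max(initial=0.0) <= 1 + 1e-9, (
            "cross-correlations must lie in [-1, 1]"
        )

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)
        df.index.name = "residue_id"
        df.to_csv(path, sep="\t", float_format="%.6f")


def _normalize_covariance(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    var = np.diag(cov).copy()
    undefined = var <= ZERO_VARIANCE_TOL * max(var.max(), 1e-300)
    safe = np.where(undefined, 1.0, var)
    denom = np.sqrt(np.outer(safe, safe))
    c = cov / denom
    c = np.clip(c, -1.0, 1.0)
    c[undefined, :] = 0.0
    c[:, undefined] = 0.0
    np.fill_diagonal(c, np.where(undefined, 0.0, 1.0))
    return c, undefined


def _ensemble_coords(frames: Trajectory | list[Structure]) -> tuple[np.ndarray, Structure, str]:
    if isinstance(frames, Trajectory):
        return frames.coords, frames.atoms, "trajectory"
    if len(frames) < 2:
        raise ValueError("need at least 2 structures in an ensemble")
    coords = np.stack([s.coords for s in frames])
    return coords, frames[0], "ensemble"


def dccm(
    frames: Trajectory | list[Structure],
    selection: AtomSelection,
    granularity: str = "residue",
    representative: str = "CA",
    fit: bool = True,
    fit_selection: AtomSelection | None = None,
    atom_average: bool = False,
) -> DCCMap:
    """Cross-correlation map of an aligned trajectory or structure ensemble.

    At residue granularity either one representative atom per residue is used
    (default Calpha) or, with ``atom_average=True``, the atom-level map is
    averaged over residue pairs.  With ``fit=True`` frames are least-squares
    fitted onto their mean on ``fit_selection`` (default: the analysis
    selection) before displacement covariances are accumulated.
    """
    coords, atoms, source = _ensemble_coords(frames)
    if len(coords) < 2:
        raise ValueError("need at least 2 frames")
    if fit:
        fidx = fit_selection.indices if fit_selection is not None else selection.indices
        coords = coords.copy()
        mean = coords.mean(axis=0)
        for _ in range(5):
            for f in range(len(coords)):
                k = kabsch_fit(coords[f, fidx], mean[fidx])
                coords[f] = k.transform(coords[f])
            new_mean = coords.mean(axis=0)
            if np.abs(new_mean - mean).max() < 1e-6:
                break
            mean = new_mean

    idx = selection.indices
    resids = atoms.residue_id[idx]
    if granularity == "residue" and not atom_average:
        keep = atoms.atom_name[idx] == representative
        if not keep.any():
            raise ValueError(f"no {representative!r} atoms in selection")
        idx = idx[keep]
        resids = atoms.residue_id[idx]

    sub = coords[:, idx]
    disp = sub - sub.mean(axis=0)
    nf = len(disp)
    cov = sum(disp[:, :, d].T @ disp[:, :, d] for d in range(3)) / nf
    c, undefined = _normalize_covariance(cov)

    if granularity == "atom":
        return DCCMap(c, labels=np.arange(len(idx)), undefined=undefined,
                      granularity="atom", source=source)
    if atom_average:
        unique = pd.unique(resids)
        n = len(unique)
        pos = {r: i for i, r in enumerate(unique)}
        groups = [np.flatnonzero(resids == r) for r in unique]
        avg = np.zeros((n, n))
        und = np.zeros(n, dtype=bool)
        for a in range(n):
            und[a] = undefined[groups[a]].all()
            for b in range(n):
                block = c[np.ix_(groups[a], groups[b])]
                m = ~np.outer(undefined[groups[a]], np.ones(len(groups[b]), bool)) & \
                    ~np.outer(np.ones(len(groups[a]), bool), undefined[groups[b]])
                avg[a, b] = block[m].mean() if m.any() else 0.0
        np.fill_diagonal(avg, np.where(und, 0.0, 1.0))
        avg = np.clip(avg, -1.0, 1.0)
        return DCCMap(avg, labels=unique.astype(int), undefined=und,
                      granularity="residue", source=source)
    return DCCMap(c, labels=resids.astype(int), undefined=undefined,
                  granularity="residue", source=source)


def dccm_from_modes(
    modes: ModeSet,
    first_k: int | None = None,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> DCCMap:
    """Analytic cross-correlation map from the first ``first_k`` modes.

    c_ij = sum_m amp_m^2 (v_m,i . v_m,j), normalized as C_ij; amplitudes are
    eigenvalues for PCA modes and kT/eigenvalue for ENM modes.
    """
    k = modes.n_modes if first_k is None else min(first_k, modes.n_modes)
    amps = modes.amplitudes_sq(temperature)[:k]
    comps = modes.eigenvectors[:k].reshape(k, modes.n_atoms, 3)
    cov = np.einsum("m,mia,mja->ij", amps, comps, comps)
    c, undefined = _normalize_covariance(cov)
    labels = (
        modes.residue_ids.astype(int)
        if modes.residue_ids is not None
        else np.arange(modes.n_atoms)
    )
    return DCCMap(c, labels=labels, undefined=undefined,
                  granularity="residue", source="modes")


def compare_dccm(a: DCCMap, b: DCCMap) -> tuple[float, int]:
    """Pearson r between two maps over the unique off-diagonal (i < j) pairs.

    Maps with different label sets are compared over the intersection (with a
    warning); undefined rows/columns are excluded.  Returns (r, n_pairs).
    """
    la, lb = list(a.labels), list(b.labels)
    if la != lb:
        import warnings

        shared = [x for x in la if x in set(lb)]
        warnings.warn(
            f"label sets differ; comparing over the {len(shared)}-label intersection"
        )
        ia = [la.index(x) for x in shared]
        ib = [lb.index(x) for x in shared]
        ma, ua = a.matrix[np.ix_(ia, ia)], a.undefined[ia]
        mb, ub = b.matrix[np.ix_(ib, ib)], b.undefined[ib]
    else:
        ma, ua, mb, ub = a.matrix, a.undefined, b.matrix, b.undefined
    n = len(ma)
    iu, ju = np.triu_indices(n, k=1)
    ok = ~(ua[iu] | ua[ju] | ub[iu] | ub[ju])
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 usable pairs, got {int(ok.sum())}")
    r, _ = stats.pearsonr(ma[iu[ok], ju[ok]], mb[iu[ok], ju[ok]])
    return float(r), int(ok.sum())


def block_statistics(
    dmap: DCCMap, blocks: dict[str, list[tuple[int, int]]]
) -> pd.DataFrame:
    """Mean/min/max cross-correlation within and between named residue blocks.

    ``blocks`` maps a name to a list of inclusive (lo, hi) residue-id ranges
    (possibly discontiguous, e.g. the paper-style "block D" partition).
    Within-block statistics run over unique i < j pairs.
    """
    labels = np.asarray(dmap.labels)
    members: dict[str, np.ndarray] = {}
    for name, ranges in blocks.items():
        mask = np.zeros(len(labels), dtype=bool)
        for lo, hi in ranges:
            mask |= (labels >= lo) & (labels <= hi)
        mask &= ~dmap.undefined
        if not mask.any():
            raise ValueError(f"block {name!r} selects no residues")
        members[name] = np.flatnonzero(mask)

    rows = []
    names = list(members)
    for i, na in enumerate(names):
        for nb in names[i:]:
            ia, ib = members[na], members[nb]
            if na == nb:
                iu, ju = np.triu_indices(len(ia), k=1)
                vals = dmap.matrix[ia[iu], ia[ju]]
            else:
                vals = dmap.matrix[np.ix_(ia, ib)].ravel()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "block_a": na,
                    "block_b": nb,
                    "mean": float(vals.mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n_pairs": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)
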