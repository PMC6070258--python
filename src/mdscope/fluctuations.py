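"""Atomic fluctuations: RMSF, B-factors, and comparison with experiment.

RMSF_i = sqrt( (1/nsteps) * sum_t || r_i(t) - <r_i> ||^2 )   [A]
B_i    = RMSF_i^2 * (8/3) * pi^2                             [A^2]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AtomSelection, Structure, Trajectory

#: B-factor conversion constant (8/3) * pi^2
B_FACTOR_PREFACTOR = (8.0 / 3.0) * np.pi**2

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "X": 12.011,
}


def _masses(elements: np.ndarray) -> np.ndarray:
    return np.array([ATOMIC_MASSES.get(str(e).upper(), 12.011) for e in elements])


def rmsf(
    traj: Trajectory,
    selection: AtomSelection,
    mass_weighted: bool = False,
    aligned: bool = True,
) -> pd.DataFrame:
    """Per-residue RMSF (A) over an aligned trajectory.

    With a single selected atom per residue (the usual Calpha selection) the
    residue value is that atom's RMSF; with several, a (mass-)weighted mean of
    the atomic RMSF values.  ``aligned=False`` raises: fluctuations about the
    mean are meaningful only after global rotation/translation removal.
    """
    if not aligned:
        raise ValueError("trajectory must be aligned before computing RMSF")
    if traj.n_frames < 2:
        raise ValueError("RMSF is undefined for a single-frame trajectory")
    idx = selection.indices
    sub = traj.coords[:, idx]
    dev = sub - sub.mean(axis=0)
    atomic = np.sqrt((dev**2).sum(axis=2).mean(axis=0))  # (n_sel,)

    resid = traj.atoms.residue_id[idx]
    chain = traj.atoms.chain_id[idx]
    weights = _masses(traj.atoms.element[idx]) if mass_weighted else np.ones(len(idx))

    rows = []
    order: dict[tuple[str, int], list[int]] = {}
    for col, (ch, rid) in enumerate(zip(chain, resid)):
        order.setdefault((str(ch), int(rid)), []).append(col)
    for (ch, rid), cols in order.items():
        w = weights[cols]
        rows.append(
            {"chain": ch, "residue_id": rid, "rmsf": float(np.average(atomic[cols], weights=w))}
        )
    return pd.DataFrame(rows)


def bfactor_from_rmsf(profile: pd.DataFrame) -> pd.DataFrame:
    """Populate the ``bfactor`` column: B = RMSF^2 * (8/3) * pi^2."""
    out = profile.copy()
    out["bfactor"] = out["rmsf"] ** 2 * B_FACTOR_PREFACTOR
    return out


@dataclass
class BFactorComparison:
    pearson_r: float
    n: int
    dropped_calculated: np.ndarray
    dropped_experimental: np.ndarray


def bfactor_correlation(
    calculated: pd.DataFrame,
    experimental: Structure,
    atom_name: str = "CA",
) -> BFactorComparison:
    """Pearson correlation between computed and experimental per-residue B-factors.

    Experimental values come from the structure's B-factor column at ``atom_name``;
    the correlation runs over the intersection of residue ids, and the residues
    dropped from either side are reported.
    """
    if experimental.bfactor is None:
        raise ValueError("experimental structure carries no B-factor column")
    mask = experimental.atom_name == atom_name
    exp = pd.Series(
        experimental.bfactor[mask], index=experimental.residue_id[mask].astype(int)
    )
    exp = exp[~exp.index.duplicated(keep="first")]
    calc = calculated.set_index("residue_id")["bfactor"]
    shared = calc.index.intersection(exp.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared residues for a correlation, got {len(shared)}"
        )
    r, _ = stats.pearsonr(calc.loc[shared], exp.loc[shared])
    return BFactorComparison(
        pearson_r=float(r),
        n=len(shared),
        dropped_calculated=np.array(sorted(set(calc.index) - set(shared))),
        dropped_experimental=np.array(sorted(set(exp.index) - set(shared))),
    )


def stamp_bfactors(structure: Structure, profile: pd.DataFrame) -> Structure:
    """Return a copy of the structure with computed B written into the B column."""
    lookup = profile.set_index("residue_id")["bfactor"].to_dict()
    b = np.array([lookup.get(int(r), 0.0) for r in structure.residue_id])
    from dataclasses import replace

    return replace(structure, bfactor=b)


def profile_to_tsv(profile: pd.DataFrame, path) -> None:
    cols = [c for c in ("chain", "residue_id", "rmsf", "bfactor") if c in profile]
    profile[cols].rename(
        columns={"rmsf": "rmsf_A", "bfactor": "bfactor_A2"}
    ).to_csv(path, sep="\t", index=False)
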