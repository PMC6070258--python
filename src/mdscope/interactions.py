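"""Hydrogen-bond occurrence maps between a ligand and protein residues.

A donor-acceptor pair counts as bonded in a frame when the heavy-atom distance
is at most ``d_cut`` (default 3.5 A) and, when hydrogens are present on the
donor, the donor-H...acceptor angle is at least ``angle_cut`` (default 135
degrees).  Occurrence is the percentage of frames (typically a basin cluster)
in which the bond is present.  Nonpolar ring contacts are reported separately
through a minimum-distance criterion, labeled "contact", never "hbond".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AtomSelection, Trajectory

D_CUT_DEFAULT = 3.5
ANGLE_CUT_DEFAULT = 135.0
CONTACT_CUT_DEFAULT = 4.5

#: heavy atoms eligible as hydrogen-bond donors or acceptors
POLAR_ELEMENTS = ("N", "O")

#: maximum covalent D-H bond length (A) used to attach hydrogens to donors
H_COVALENT_CUT = 1.25


def _polar_atoms(traj: Trajectory, sel: AtomSelection) -> np.ndarray:
    el = traj.atoms.element[sel.indices]
    return sel.indices[np.isin(el, POLAR_ELEMENTS)]


def _attached_hydrogens(traj: Trajectory, donor: int) -> np.ndarray:
    """Hydrogens covalently bound to a donor, from first-frame geometry."""
    h_idx = np.flatnonzero(traj.atoms.element == "H")
    if len(h_idx) == 0:
        return h_idx
    d = np.linalg.norm(traj.coords[0, h_idx] - traj.coords[0, donor], axis=1)
    return h_idx[d <= H_COVALENT_CUT]


def _angles_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    v1 = a - b
    v2 = c - b
    cosang = (v1 * v2).sum(axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hbond_occurrence(
    frames: Trajectory,
    ligand_sel: AtomSelection,
    protein_sel: AtomSelection,
    d_cut: float = D_CUT_DEFAULT,
    angle_cut: float = ANGLE_CUT_DEFAULT,
) -> pd.DataFrame:
    """Hydrogen-bond occurrence (%) per ligand-atom / protein-residue@atom pair.

    Candidate pairs are all polar (N/O) ligand-protein atom pairs; the angle
    criterion applies per frame to whichever side carries a covalent hydrogen
    (hydrogen-free structures fall back to the distance-only criterion).
    Only pairs with nonzero occurrence are returned.
    """
    if len(ligand_sel) == 0 or len(protein_sel) == 0:
        raise ValueError("ligand and protein selections must be non-empty")
    lig = _polar_atoms(frames, ligand_sel)
    pro = _polar_atoms(frames, protein_sel)
    if len(lig) == 0 or len(pro) == 0:
        raise ValueError("no polar (N/O) atoms in ligand or protein selection")

    atoms = frames.atoms
    nf = frames.n_frames
    rows = []
    for la in lig:
        lig_h = _attached_hydrogens(frames, la)
        for pa in pro:
            dist = np.linalg.norm(frames.coords[:, la] - frames.coords[:, pa], axis=1)
            present = dist <= d_cut
            pro_h = _attached_hydrogens(frames, pa)
            role = "unassigned"
            if len(lig_h):
                role = "donor"  # ligand donates
                ok = np.zeros(nf, dtype=bool)
                for h in lig_h:
                    ok |= (
                        _angles_deg(
                            frames.coords[:, la], frames.coords[:, h], frames.coords[:, pa]
                        )
                        >= angle_cut
                    )
                present = present & ok
            elif len(pro_h):
                role = "acceptor"  # ligand accepts
                ok = np.zeros(nf, dtype=bool)
                for h in pro_h:
                    ok |= (
                        _angles_deg(
                            frames.coords[:, pa], frames.coords[:, h], frames.coords[:, la]
                        )
                        >= angle_cut
                    )
                present = present & ok
            occurrence = 100.0 * present.sum() / nf
            if occurrence > 0:
                rows.append(
                    {
                        "ligand_atom": str(atoms.atom_name[la]),
                        "residue": int(atoms.residue_id[pa]),
                        "residue_name": str(atoms.residue_name[pa]),
                        "residue_atom": str(atoms.atom_name[pa]),
                        "ligand_role": role,
                        "occurrence_pct": occurrence,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand_atom", "residue", "residue_name", "residue_atom",
            "ligand_role", "occurrence_pct",
        ],
    )


def contact_occurrence(
    frames: Trajectory,
    ligand_sel: AtomSelection,
    protein_sel: AtomSelection,
    d_cut: float = CONTACT_CUT_DEFAULT,
) -> pd.DataFrame:
    """Minimum-distance heavy-atom contact listing (stacking/hydrophobic).

    A ligand-atom / protein-residue pair is in contact in a frame when any
    heavy-atom distance is <= ``d_cut`` (default 4.5 A).
    """
    if len(ligand_sel) == 0 or len(protein_sel) == 0:
        raise ValueError("ligand and protein selections must be non-empty")
    atoms = frames.atoms
    lig = ligand_sel.indices[atoms.element[ligand_sel.indices] != "H"]
    pro = protein_sel.indices[atoms.element[protein_sel.indices] != "H"]
    resids = atoms.residue_id[pro]
    rows = []
    for la in lig:
        d = np.linalg.norm(
            frames.coords[:, pro] - frames.coords[:, la][:, None, :], axis=2
        )  # (F, n_pro)
        for rid in np.unique(resids):
            cols = resids == rid
            present = (d[:, cols] <= d_cut).any(axis=1)
            occurrence = 100.0 * present.sum() / frames.n_frames
            if occurrence > 0:
                rows.append(
                    {
                        "ligand_atom": str(atoms.atom_name[la]),
                        "residue": int(rid),
                        "kind": "contact",
                        "occurrence_pct": occurrence,
                    }
                )
    return pd.DataFrame(rows, columns=["ligand_atom", "residue", "kind", "occurrence_pct"])
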