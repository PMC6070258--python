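# mdscope

Multi-scale dynamics analysis of molecular-dynamics trajectories for
multi-domain proteins — the kind of analysis used to dissect how a large
enzyme such as a GH70 branching sucrase, with its five-domain U-shaped fold,
twists, bends and wobbles: which loops are mobile, which domains move in
tandem or in opposition, where the inter-domain hinges sit, and how ligand
binding shifts the conformational equilibrium.

It is a library (plus a thin `mdscope` command-line pipeline) for structural
bioinformaticians who have a trajectory (DCD/XTC + PDB topology) and want the
standard battery of post-processing analyses in one tested, reproducible
place:

- **Superposition / RMSD** — Kabsch least-squares fitting, per-frame RMSD
  series with exclusion selections, and per-residue ("residual") RMSD maps
  through time.
- **Fluctuations** — RMSF about the mean position and crystallographic-style
  temperature factors, `B = RMSF² · (8/3)π²`, with Pearson comparison against
  the experimental B-factor column of a PDB file.
- **Essential dynamics (PCA)** — coordinate-covariance eigenmodes, frame
  projections, eigenvalue fractions, and simulation-convergence checks via
  the Kullback–Leibler divergence between first-half and second-half
  projection histograms.
- **Elastic-network normal modes** — an anisotropic network model on Cα atoms
  (uniform springs within a 12 Å cutoff), with the six rigid-body modes
  identified and removed, thermal amplitudes `kT/λ`, mode-derived B-factors
  and sinusoidal mode conformers.
- **Dynamical cross-correlation maps (DCCM)** —
  `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩)` from trajectories, X-ray
  ensembles or mode sets; Pearson comparison between maps and named-block
  (domain) statistics.
- **Hinge detection** — average unsigned deviation (AUD) of backbone φ/ψ
  dihedrals across conformers, with periodic wrapping and local-maximum hinge
  candidates.
- **Morlet wavelet maps** — per-residue continuous wavelet transforms of
  displacement series over a geometric scale grid (0.2 → 25 ns, step ×1.01),
  dominant-period maps, and χ²-based significance testing against white or
  lag-1 autoregressive noise at 99 % confidence.
- **Free-energy landscapes** — `G = −kT ln(P/P_max)` over pairs of principal
  components via fast binned kernel density estimation at 303 K, basin
  extraction (`ΔG` threshold, 4-connected components), basin population
  shifts between conditions, and an inter-domain bending-angle series.
- **Hydrogen bonds** — donor–acceptor occurrence maps (distance ≤ 3.5 Å,
  D–H···A angle ≥ 135° when hydrogens exist) over a frame cluster, plus a
  separate hydrophobic/stacking contact listing.
- **Synthetic data** — generators that plant recoverable structure
  (collective modes, hinged anti-correlated domains, periodic oscillations,
  two-state equilibria, hydrogen-bond geometries) so that every stage of the
  pipeline can be validated end-to-end without any external data.

## Worked example: finding a hinge between two anti-correlated domains

```python
import numpy as np
import mdscope as m
from mdscope import synthetic as syn
from mdscope.correlation import block_statistics

# two-domain enzyme mimic: arms of 25 residues hinged at residue 26,
# swinging by +/-20 degrees
fixture = syn.gen_two_domain_hinge(theta0_deg=20.0, n_frames=2000, seed=42)
traj = fixture.trajectory
ca = m.select_atoms(traj.atoms, "name CA")

dmap = m.dccm(traj, ca)
blocks = {"armA": [fixture.meta["block1_residues"]],
          "armB": [fixture.meta["block2_residues"]]}
print(block_statistics(dmap, blocks).to_string(index=False, float_format="%.3f"))

mean_structure = fixture.structure.with_coords(traj.coords.mean(axis=0))
aud = m.dihedral_aud(traj, mean_structure)
peak = aud.loc[aud[["aud_phi", "aud_psi"]].max(axis=1).idxmax()]
print(f"hinge residue: {peak.residue_id}  AUD_phi = {peak.aud_phi:.1f} deg")

triple = tuple(m.select_atoms(fixture.structure, f"resid {r} and name CA")
               for r in fixture.meta["bend_triple_residues"])
angles = m.bend_angle_series(traj, triple)
print(f"bend angle: mean = {np.nanmean(angles):.1f} deg, "
      f"amplitude = {np.sqrt(2) * np.nanstd(angles):.1f} deg")
```

Output:

```
block_a block_b   mean    min   max  n_pairs
   armA    armA  0.497 -0.619 1.000      300
   armA    armB -0.488 -0.999 0.996      625
   armB    armB  0.497 -0.619 1.000      300
hinge residue: 26  AUD_phi = 13.0 deg
bend angle: mean = 119.0 deg, amplitude = 20.0 deg
```

Reading the numbers: the two arms are internally correlated (mean within-block
cross-correlation +0.50) and move against each other (mean inter-block
correlation −0.49), the dihedral-deviation profile peaks exactly at the
planted pivot residue 26 (a ±20° torsional swing has mean unsigned deviation
2·20/π ≈ 12.7°), and the inter-domain bending angle oscillates about 119°
with the planted 20° amplitude.

The same analyses run from the shell:

```bash
mdscope simulate-fixture --kind hinge --out fix --seed 42
mdscope dccm --traj fix/trajectory.dcd --top fix/topology.pdb \
        --blocks domains.yml --out dccm_out
mdscope report --traj fix/trajectory.dcd --top fix/topology.pdb --out report
```

Every stage writes a `manifest.json` with parameter snapshots and
input/output checksums, so a rerun with the same seed is checkably
bit-identical.

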