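# Methods

This note documents the models behind each analysis stage, the defaults and
their units, the numerical choices that matter, what the synthetic generators
do and do not emulate, and the known limitations.

## Coordinate conventions

Coordinates are Ångström everywhere in memory; XTC files (nanometres on disk)
are converted on read/write by the MDAnalysis backend. Time is carried in
picoseconds and reported in nanoseconds. Residue numbers are author numbering
from the PDB file and are never renumbered; selections accept a
`resid_offset` so inputs expressed in a different numbering scheme (common
when crystallographic and construct numbering disagree) can be mapped without
touching the data.

## Superposition and RMSD

Rigid-body fitting is the Kabsch SVD solution for the proper rotation and
translation minimizing the (optionally weighted) squared deviation. Inputs
with fewer than three atoms or a collinear configuration are rejected —
the rotation is not identifiable there. Alignment to the trajectory average
is the usual fixed-point iteration (fit all frames to the mean, recompute the
mean), with a convergence threshold of 1e-6 Å on the maximum atom shift and a
cap of 10 iterations; in practice two to three iterations suffice.

The residual (per-residue) RMSD map measures each residue's deviation from a
reference position through time: the deviation is RMS-combined over the
residue's selected atoms and averaged over non-overlapping frame windows
(default window = 1, no smoothing). The reference is the residue's
time-average position by default — the map then shows *fluctuation* about
the trajectory mean — with a crystallographic structure as an alternative
reference when drift from the experimental conformation is the question. The
conventional color bins {2, 4, 6} Å ship as the default rendering scale.

## Fluctuations and B-factors

RMSF_i = sqrt( (1/n) Σ_t ‖r_i(t) − ⟨r_i⟩‖² ) on an aligned trajectory, and
B_i = RMSF_i² · (8/3)π² (so RMSF = 1 Å ↦ B ≈ 26.32 Å²). When several atoms
of a residue are selected the residue value is a mass-weighted mean of atomic
RMSF values; for the usual Cα-only selection the weighting is a no-op, which
is why the equation itself carries no mass term. Comparison with experiment
is a Pearson correlation over the intersection of residue ids against the
PDB B-factor column at Cα, reporting the n used and the residues dropped on
either side.

## Essential dynamics (PCA)

The coordinate covariance c_ij = ⟨r_i r_j⟩ − ⟨r_i⟩⟨r_j⟩ is accumulated over
frames sampled at a stride (default offset = 10 frames) from an aligned
trajectory, and diagonalized; eigenvalues are variances (Å²) sorted
descending, with normalized fractions and cumulative coverage exposed so
statements like "the first three components cover X% of the motion" are one
call. Eigenvector sign is fixed by making each mode's largest-magnitude
component positive — eigenvectors are only defined up to sign, and the
convention makes mode comparisons and regression tests deterministic.

Convergence is probed with the Kullback–Leibler divergence between the
projection histograms of the two halves of the trajectory. The estimator is
a histogram KLD on the union support with 100 bins, a pseudo-count of ½ per
bin, natural log, and the first half as p; a symmetrized variant and a
cumulative KLD-versus-time curve are available. The pseudo-count bounds the
divergence of identical inputs at exactly zero and keeps empty bins finite;
the estimator reproduces the closed-form KLD = μ²/2 = 0.5 of N(0,1) vs
N(1,1) within a few percent at 10⁵ samples.

## Elastic-network normal modes

All-atom normal modes at a force-field minimum are replaced by a Cα
anisotropic network model: identical springs (γ, default 1 kJ·mol⁻¹·Å⁻²)
between atoms within a 12 Å cutoff, Hessian assembled from the standard
−γ·(d⊗d)/|d|² off-diagonal blocks. This reproduces the low-frequency
collective modes that domain-motion analysis consumes without a molecular
mechanics force field. The contact graph must be connected (the error lists
component sizes otherwise); exactly six near-zero eigenvalues (below 1e-8 of
the maximum) must be found — these are global translation/rotation and are
removed — and any other count means the geometry is degenerate for this
model. The number of retained internal modes is the exposed knob (default
26); a spectroscopic frequency cutoff is not meaningful for a dimensionless
network model. Thermal mode amplitudes are amp² = kT/λ at 303 K; PCA modes
use amp² = λ. Both sources share one `ModeSet` container, so fluctuation
profiles, correlation maps, conformer sweeps and projections are
source-agnostic.

A note on degenerate constructions: two rigid bodies connected by a *single*
central-force spring keep five internal mechanisms (free relative rotations),
so such a dumbbell necessarily fails the exactly-six-rigid-modes contract —
that is physics, not a bug. The hinge behavior of the model is therefore
validated on a two-arm elbow structure, whose lowest internal modes are
counter-motions of the arms with negative inter-arm cross-correlation.

## Dynamical cross-correlation maps

c_ij is the scalar product covariance ⟨Δr_i·Δr_j⟩ of displacement vectors
after least-squares fitting, normalized to C_ij = c_ij/√(c_ii·c_jj) ∈ [−1,1].
The scalar-product convention is what makes the map's range statement (−1
fully anti-correlated, +1 fully correlated) exact. One consequence worth
stating: for a rank-1 (single-mode) covariance, C_ij equals the cosine of
the angle between the per-atom mode vectors — not ±1, which only holds for
per-component correlations. Zero-variance atoms are flagged in an explicit
mask, never encoded as NaN or sentinel values, and masked entries are
excluded from map comparisons (Pearson over unique i<j pairs) and block
statistics. Residue granularity uses the Cα atom as representative by
default, or averages atom-level correlations over residue pairs behind a
flag. Named residue blocks may be discontiguous, matching the way structural
domains are built from sequence-discontinuous segments.

## Morlet wavelet maps

Each selected atom's displacement about its mean position is transformed
with the complex Morlet wavelet (ω₀ = 6) by FFT convolution (zero-padded to
the next power of two) on a geometric scale grid s_k = 0.2·1.01^k ns,
truncated at 25 ns (486 scales). Scales convert to Fourier periods by the
standard Morlet factor 4π/(ω₀+√(2+ω₀²)) ≈ 1.033, and all outputs report
period. Per-residue power is the mean over the residue's atoms; the dominant
period per (residue, frame) is the scale of maximum power; frames within the
e-folding time √2·s of either end are edge-flagged (cone of influence).

The transform runs per Cartesian axis with powers summed (default). The
scalar displacement *magnitude* ‖r(t)−⟨r⟩‖ is available behind a flag, but
it is not the default because the magnitude of a symmetric oscillation about
the mean oscillates at twice the true frequency — a planted 10 ns sinusoid
would be reported at 5 ns. The per-axis transform recovers planted periods
exactly (within the grid resolution) and its power is invariant to
oscillation phase.

Significance follows a chi-squared test against a model background spectrum:
the expected power per scale is computed exactly for the discrete transform
from the AR(1) (red-noise, lag-1 coefficient estimated from the series) or
white spectrum, and a cell is significant when
power / (background × χ²_crit) exceeds the 99 % quantile of χ² with the
complex wavelet's two degrees of freedom, divided by the degrees of freedom.
χ²_crit = 1.6094 is an opaque, configurable threshold constant; with the
defaults the null false-positive rate on white noise is far below the 1 %
nominal level (the test is conservative). The AR(1) background assumes
stationarity: for strongly non-stationary series (isolated bursts) the
fitted red-noise background under-represents high frequencies and the white
background is the appropriate choice.

## Free-energy landscapes and basins

G = −kT·ln(P/P_max) with k the molar gas constant (energies in J/mol) and
T = 303 K by default, so kT ≈ 2519 J/mol and a cell at P = P_max/e sits at
exactly kT. P is a fast binned kernel estimate: a 2-D histogram on the
analysis grid (default 100×100 spanning the data range ± 3 bandwidths)
smoothed with a Gaussian of per-axis Scott bandwidth n^(−1/6)·σ
(user-overridable). Cells that received no frames are flagged and excluded
from basin connectivity. Basins are 4-connected components of cells with
G below a threshold, ordered by depth, each carrying its member frames,
their centroid in PC space and its minimum cell; the basin-shift between two
conditions is the difference of deepest-basin centroids and requires both
landscapes to live in a common mode basis — project both trajectories onto
one shared set of eigenvectors (the recommended route) rather than running
separate PCAs.

The default basin threshold is 100 J/mol (≈ 0.04 kT), which isolates the
very core of the dominant state — appropriate for extracting a tight
representative cluster. For *population* questions on a two-state system the
threshold must exceed the wells' depth difference, kT·ln(p/(1−p)) ≈ 3.5
kJ/mol at 80/20, or the minor well is invisible by construction; the
two-state analyses here use 2 kT, chosen from that planted depth difference,
and the occupancy-ratio check uses wells 10σ apart with a 6 kT threshold so
both wells are captured almost completely and the basin populations reflect
the mixture weights.

## Hydrogen bonds and contacts

A donor–acceptor pair (N/O heavy atoms across the ligand–protein interface)
is bonded in a frame when the heavy-atom distance is ≤ 3.5 Å and, when a
covalent hydrogen (≤ 1.25 Å in the first frame) exists on either side, the
D–H···A angle is ≥ 135°; structures without hydrogens fall back to the
distance-only criterion. Occurrence is the percentage of input frames —
typically a basin cluster — in which the bond is present. Stacking and
hydrophobic contacts are reported by a separate minimum-distance listing
(any heavy-atom pair ≤ 4.5 Å), labeled "contact" and never mixed into the
hydrogen-bond map.

## Synthetic study conditions

The generators are pure functions of their parameters (seed included) and
record ground truth sufficient to predict every downstream readout:

- `gen_gaussian_traj` — 200 residues × 20 000 frames at 10 ps spacing by
  default; planted orthonormal modes with amplitudes (3, 2, 1) Å over an
  isotropic 0.2 Å noise floor. Recorded eigenvalues are amp² + σ², the true
  directional variance including noise.
- `gen_two_domain_hinge` — two 25-residue backbone arms meeting at 120° at a
  pivot whose N–Cα bond is the rotation axis, so a θ₀·sin(2πt/T) swing of
  the downstream arm is simultaneously a pure φ change at the pivot
  (expected AUD = 2θ₀/π) and an equal change of the bend angle; noise floor
  0.05 Å, chosen so its closed-form propagation into the bend angle
  (≈ 0.4° per frame over ~10 Å arms) stays well inside the analysis
  tolerances.
- `gen_oscillatory` — residue groups oscillating along fixed random
  directions at set periods (optionally time-windowed bursts) over a white
  0.2 Å floor; 0.1 ns frame spacing so the default wavelet grid resolves
  the planted bands.
- `gen_double_well` — a two-component Gaussian mixture along two planted
  modes (centers ±separation/2 on mode 1, unit within-well σ); a
  `mode_seed` separate from the sampling seed lets paired free/bound runs
  share one basis.
- `gen_hbond_fixture` — a rigid 10-residue pocket and a 23-atom
  disaccharide-like ligand with three planted pairs at presence fractions
  (1.0, 0.5, 0.0) on a deterministic even/odd frame schedule.

What the generators do **not** emulate: force-field energetics, solvent and
friction, anharmonic couplings between modes, sequence-dependent geometry,
or experimental noise models. Passing the planted-recovery suite therefore
demonstrates that the estimators are correct and calibrated — not that any
particular biological system is well described by a harmonic or two-state
model. Problem sizes in the validation script (200 residues × 50 000 frames
for mode recovery, 20 null seeds × 10 000 frames for wavelet calibration,
50 000 frames for landscapes) were chosen to make statistical fluctuations
small relative to the assertion tolerances while the whole script stays
around a minute on one CPU.

## Known limitations

- PDB output truncates serials and residue ids to the fixed-column widths
  (modulo 100 000 / 10 000); mmCIF is out of scope.
- The elastic network is Cα-only with uniform springs; stiffness is in
  arbitrary units and only relative mode structure is meaningful.
- KDE landscapes inherit kernel bias: wells narrower than the bandwidth are
  broadened and very shallow basins can merge; the per-axis Scott rule
  assumes roughly unimodal marginals and over-smooths strongly multimodal
  coordinates (override the bandwidth there).
- The wavelet significance test treats residue-aggregated power as if it had
  the single-series degrees of freedom; with several atoms per residue it is
  conservative.
- Hydrogen-bond typing is element-based (N/O); no distinction between, e.g.,
  amide and carboxylate oxygens, and no water-mediated bridges.
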