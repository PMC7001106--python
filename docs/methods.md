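# Methods

## The synthetic membrane model

The generator replaces cluster-scale coarse-grained membrane MD with a
quasi-two-dimensional surrogate chosen so that every downstream
analysis has an exactly known answer.

**Dynamics.** Lipid head particles move in the membrane plane (x, y)
by overdamped (Brownian) Langevin dynamics,

    x ← x + (D/k_B T) F(x) dt + sqrt(2 D dt) η,

with η standard normal. Protein and site-anchor particles are
immobile; z coordinates mark the leaflet and never change (no
flip-flop). Lipids do not interact with each other — the model is an
ideal lateral gas in external potentials — because the analyses under
test depend only on the sampled configurations of individual lipids
relative to the protein, not on lipid–lipid structure. D = 0.1 nm²/ns
and dt = 0.01 ns are surrogate choices (fast desk-scale mixing), not
physical claims; no lateral diffusion coefficient is asserted for any
real lipid. Temperature is 310 K everywhere (k_B T = 2.5775 kJ/mol);
coordinates are integrated and stored unwrapped, with the
minimum-image convention applied inside all distance computations, so
diffusive observables (MSD) remain exact.

**Planted sites.** A binding site is a radial Gaussian well
U(r) = −D₀ exp(−r²/2σ²) in the plane, anchored either at the box
center (the dilute single-site setup used for free-energy protocols)
or at four positions related by 90° rotations at the rim of a soft
harmonic protein wall (the tetramer mimic). The Gaussian form is
analytically tractable — partition functions reduce to 1D quadrature —
and its amplitude D₀ equals the depth of the 1D PMF in the dilute
limit, a property the recovery tests verify rather than assume.
Default σ = 0.3 nm, a head-group bead scale. Well magnitudes default
to 37, 20, 28 and 9 kJ/mol for PIP2, PIP, PIP3 and PS, the reported
well depths those species show at the phosphoinositide site of the
motivating channel; the model cannot (and does not try to)
distinguish PI(4,5)P₂ from PI(3,5)P₂, so PIP2 is one species.

**Bilayer composition.** The mixed in-vivo mimetic membrane uses
outer leaflet PC:PE:SM:GM3:CHOL = 40:10:15:10:25 and inner leaflet
PC:PE:PS:PIP2:CHOL = 10:40:15:10:25, giving 5% overall PIP2 with
equal leaflet counts. Species counts are largest-remainder roundings
of fraction × lipids_per_leaflet with ties broken by species name, so
builds are deterministic; initial positions are uniform per leaflet
with a 0.3 nm minimum spacing and excluded from the protein footprint.

**What the surrogate does not emulate.** MARTINI energetics,
self-assembly, thermostats/barostats, membrane undulations, lipid
tails and entanglement, 3D head-group geometry, and protein
flexibility. Passing tests therefore demonstrate that the
*estimators* are correct and internally consistent on trajectories
with the statistical structure of lateral lipid motion; they say
nothing about force-field accuracy on real membranes.

## Free-energy protocols

**Reaction coordinate.** The signed projection of the lipid-to-anchor
displacement onto an in-plane axis (default +x). Signed, because the
canonical window ladder starts at −0.7 nm, which an unsigned distance
cannot reach; an unsigned radial mode is available for comparison.

**Umbrella sampling.** 38 windows evenly spaced on [−0.7, 3.0] nm
(spacing 0.1 nm), k = 500 kJ/mol/nm², lateral restraint
100 kJ/mol/nm² off-axis, 310 K. The anchor-group xy restraint of
400 kJ/mol/nm² used by the motivating protocol is carried in the spec
for completeness but exerts no force here: anchors are immobile by
construction. Windows start at their centers and all evolve
simultaneously as one vectorized Brownian ensemble. Burn-in is
fraction-based (25% of each window) because absolute times do not
transfer from microsecond MD to the surrogate; the reference protocol
retains 450k steps per window, sized so the seed-to-seed spread of a
recovered depth is ≈ 0.16 kJ/mol (measured over repeat runs), an
order of magnitude inside the ±2 kJ/mol recovery band. Biased
protocols integrate with dt = 0.0025 ns rather than the free-diffusion
0.01 ns: the Euler–Maruyama stationary variance is inflated by
≈ (1 − κ D dt/2k_B T)⁻¹ and the stiffest windows reach
κ ≈ 900 kJ/mol/nm², so the smaller step keeps the discretization bias
around 1% of k_B T. A guard refuses κ D dt/k_B T ≥ 1 (divergent).

**WHAM.** Standard binned self-consistent iteration in non-log space
with underflow treated as exact zero; bin width 0.05 nm (half the
window spacing), convergence when the largest window free-energy
shift drops below 1e-8 kJ/mol, 1e5 iteration cap, deterministic given
samples. Non-overlapping adjacent windows are detected up front and
reported with the gap location.

**Lateral-width correction.** The planted well is radial but the PMF
is 1D, so the raw −k_B T ln P(s) contains the free energy of the
lateral coordinate: integrating out y near a deep well narrows the
lateral distribution and biases the apparent depth by
+k_B T ln(w_bulk/w_well) (≈ +1.8 kJ/mol at D₀ = 37, σ = 0.3,
k_lat = 100 — confirmed by quadrature). The protocol therefore adds
k_B T ln(w(s)/w_bulk) to the profile, with w(s) the per-window
standard deviation of the sampled lateral coordinate interpolated
along the mean sampled s and w_bulk averaged over bulk-interval
windows. The correction is measured, not taken from the planted
parameters, and vanishes identically when the lateral spread is
constant. It assumes the conditional lateral distribution is
approximately Gaussian; quadrature puts the residual error below
~0.3 kJ/mol for the depths used here.

**Referencing and depth.** Profiles are zeroed so the mean over the
bulk interval s ∈ [2.5, 3.0] nm (the outermost 0.5 nm of the ladder)
is exactly 0; the well depth is min G minus that bulk mean. The
zeroing convention and interval are package choices — the motivating
analyses do not state theirs.

**Errors and convergence.** Well-depth error bars come from a block
bootstrap over each window's sample series (block length twice the
largest integrated autocorrelation time across windows, Sokal
windowing), repeating the entire analysis per resample — the
bootstrap tracks the spread of independent repeat simulations within
a factor ~2 in tests. Convergence is monitored by recomputing the PMF
on sample prefixes and reporting the largest |ΔG| between successive
checkpoints over bins both populate with ≥10 counts.

**Alchemical route.** U_λ = (1−λ)U_A + λU_B at 21 evenly spaced λ
(spacing 0.05), each window under an identical harmonic site hold of
500 kJ/mol/nm² that defines the bound state; 10% burn-in per window
(mirroring protocols that analyze the final 225 of 250 stored frames).
Every retained configuration is scored at every λ and the
dimensionless free energies solve the self-consistent MBAR equations
(tolerance 1e-12); errors use the standard MBAR asymptotic covariance
(SVD form), which matches Bennett's two-state variance within ~10% on
harmonic benchmarks. The reported ΔΔG adds the measured
configurational-volume correction k_B T ln(v_B/v_A), v being the mean
per-axis positional variance at the endpoint windows: a shallower
well is wider, and that width entropy is not binding strength, so the
correction converts the bound-ensemble ΔG into a well-depth
difference comparable with the PMF route (Laplace analysis puts the
residual anharmonic mismatch near 0.2 kJ/mol for the depths used).
Known limitation: the asymptotic error assumes independent samples
and therefore understates the uncertainty of correlated Brownian
sampling; seed-to-seed spread of the full protocol is ≈ 0.1 kJ/mol.

## Site mapping

Density maps deposit unit mass per selected particle per frame into
the containing 0.1 nm voxel (nearest-voxel, not kernel-smeared, so
per-frame-mean normalization conserves mass exactly). Sites are
6-connected components of voxels ≥ 0.5 × the global peak; the
pipeline additionally requires the peak itself to reach 0.1
per-frame-mean occupancy (a lipid present ≥10% of frames in one
voxel) so a flat well-free map reports zero sites rather than
background specks. Ordering is by peak value, ties by flat voxel
index — deterministic.

Distance-to-site traces use the center of mass of the lipid head
particles against the site-anchor COM, projected into the membrane
plane with minimum image. Contact durations instead use the
particle-to-particle minimum between a residue's particles and the
lipid head particles, the per-residue fingerprint convention. Events
follow a dual cutoff — open below 0.55 nm, close above 1.0 nm — which
suppresses single-threshold rattling; the cutoffs are package
defaults (conventional for coarse bead scales; no cutoff is stated in
the motivating analyses) and are exposed in the config. Durations are
event frame counts × frame spacing; tables report per-(chain,
residue) statistics and optionally chain-averaged values, plus a
linear white-to-red color scale with the maximum mean duration mapped
to 1 (all-equal tables map to 1 by documented convention).

## Geometry metrics

Hydrogen bonds use the geometric criterion d(D,A) ≤ 0.35 nm and
D–H…A deviation from linearity ≤ 30° (0° = collinear; stated
explicitly to avoid the equivalent ≥150° convention), with
minimum-image distances; both parameters are configurable, and
results are criterion-sensitive as usual for geometric H-bond counts.
Ligand RMSD traces superpose each frame's protein particles onto a
reference frame by least-squares (Kabsch, proper rotation enforced;
degenerate/collinear fit sets rejected), apply the transform to the
whole frame, and report each ligand copy's RMSD against its reference
pose with no fitting on the ligand — loose copies show large
fluctuations, stable ones stay near zero.

## Pipeline, seeds, formats

The pipeline runs membrane → density/sites → contacts → umbrella/WHAM
→ FEP → consistency → geometry in dependency order, halting
downstream stages on failure while recording partial state. One root
seed; per-stage streams derive from it by fixed documented offsets so
stages can be re-run in isolation; identical config + seed give
identical manifests. Two presets are version-controlled: `ci`
(reduced sampling, proportionally looser tolerances) and `reference`
(the ±2 kJ/mol recovery bands). Interchange formats are deliberately
plain text: PDB/GRO in, a documented line-oriented trajectory store,
OpenDX grids (data body in the standard z-fastest order, so files
load in VMD), TSV tables, YAML configs, JSON manifests. The
umbrella-window TSV is long-format (window, center, k, s, y) so
externally generated window samples can be fed to the WHAM stage
unchanged.

## Problem sizes

Reference protocols run at desk scale by design: 38 × 600k Brownian
steps per PMF (~25 s on one CPU), 21 × 25k steps for the alchemical
ladder (~10 s), 20k steps for the mixed-bilayer demonstration. These
sizes were chosen so each estimator's stochastic error sits well
inside its acceptance band; they are surrogate sampling lengths, not
claims about MD convergence times.
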