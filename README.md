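# memsite

Protein–lipid interaction analysis on synthetic membrane trajectories
with planted ground truth.

## The problem

Coarse-grained membrane simulations of ion channels (TRP channels such
as polycystin-2 being the motivating case) are analyzed through a
standard chain of methods: 3D lipid occupancy densities reveal
interaction sites on the protein surface; per-residue contact
durations fingerprint the residues that hold a lipid in place;
umbrella sampling along an in-plane reaction coordinate, unbiased with
WHAM, yields the potential of mean force (PMF) and its well depth for
each lipid species; and alchemical free-energy perturbation analyzed
with MBAR cross-checks the relative binding free energies. For a
channel binding phosphoinositides at four symmetry-related sites these
analyses produce numbers like a −37 kJ/mol PIP₂ well depth and
ΔΔG ≈ +17 kJ/mol for converting bound PIP₂ to PIP.

Every step of that chain is easy to get subtly wrong, and none of it
is verifiable against the original cluster-scale trajectories at desk
scale. `memsite` therefore re-implements the chain against a synthetic
membrane model in which the answer is known exactly: lipid head
particles diffuse in the bilayer plane by overdamped Langevin
dynamics, and binding sites are *planted* radial Gaussian wells
U(r) = −D₀ exp(−r²/2σ²) whose amplitude D₀ is the free energy the
estimators must recover. The package is for anyone who wants tested,
reusable implementations of WHAM, MBAR, residence-time and density
analyses — or a controlled test bed for their own.

## The estimators

**WHAM.** Umbrella windows i apply a bias b_i(s) = k/2 (s − s_i)² on
the signed in-plane coordinate s (default ladder: 38 windows on
[−0.7, 3.0] nm, k = 500 kJ/mol/nm², 310 K, with a 100 kJ/mol/nm²
lateral restraint off-axis). Binned samples are combined by iterating

    p_j ∝ M_j / Σ_i N_i exp(β f_i) exp(−β b_i(x_j)),
    exp(−β f_i) = Σ_j exp(−β b_i(x_j)) p_j,

to self-consistency; G(s) = −k_B T ln p(s), referenced so the mean
over a bulk interval (default s ∈ [2.5, 3.0] nm) is zero. Because the
planted well is radial while the PMF is one-dimensional, the profile
is corrected by +k_B T ln(w(s)/w_bulk) with w the measured per-window
lateral spread, after which min G equals −D₀ in the dilute limit.

**MBAR.** For the alchemical route U_λ = (1−λ) U_A + λ U_B is sampled
at 21 evenly spaced λ under a harmonic site hold; the dimensionless
free energies solve

    f_k = −ln Σ_n exp(−u_k(x_n)) / Σ_l N_l exp(f_l − u_l(x_n)),

with the standard asymptotic covariance for the error bar and a
pairwise Bennett acceptance ratio as the two-state fallback. A
measured configurational-volume correction k_B T ln(v_B/v_A) converts
the bound-state ΔG into a well-depth difference comparable with the
PMF route.

Both estimators follow the statsmodels convention: build the model
from data, `fit()`, and inspect the returned results object
(`PMFResult`, `FreeEnergyResult`) for estimates, uncertainties,
diagnostics, `summary()` and `plot()`.

## Worked example

Plant the −37 kJ/mol well, recover it by umbrella sampling + WHAM, and
cross-check the PIP₂→PIP conversion alchemically:

```python
from memsite.protocols import recover_well_depth, alchemical_ddg

est = recover_well_depth(depth=37.0, seed=1)
print(est.profile.summary())
print(f"recovered well depth: {est.recovered_depth:+.2f} kJ/mol")

fep = alchemical_ddg(37.0, 20.0, seed=1)
print(f"ddG (alchemical): {fep['ddg']:+.2f} kJ/mol "
      f"(volume correction {fep['volume_correction']:+.2f})")
```

prints (about half a minute on one CPU):

```
PMF reconstruction (WHAM)
=========================================
bins:                 86 [-0.970, 3.280] nm
temperature:          310.0 K
iterations:           4405 (converged)
lateral correction:   applied
bulk interval:        (2.5, 3.0)
minimum:              G(-0.020 nm) = -36.45 kJ/mol
recovered well depth: -36.45 kJ/mol
ddG (alchemical): +16.88 kJ/mol (volume correction +0.49)
```

The WHAM route recovers the planted −37 kJ/mol within its ~±0.5
kJ/mol seed-to-seed spread, and the alchemical route puts the
37→20 kJ/mol conversion at +16.9, against +17 exact — the two
independent estimators agreeing on the same planted truth.

The same machinery is scriptable from the shell: `memsite run` drives
the whole pipeline (mixed in-vivo-mimetic bilayer → density map → site
detection → contacts → PMFs → FEP → geometry metrics) from a YAML
config, and `memsite pmf`, `memsite fep`, `memsite density`,
`memsite sites`, `memsite contacts`, `memsite hbonds`, `memsite rmsd`
expose the stages individually. Every run logs its resolved
configuration and seed and writes a JSON manifest with the planted
ground truth next to the derived results.

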