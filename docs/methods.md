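# Methods

## Model

A coarse-grained (CG) system is a set of beads grouped into monomers.  The
potential energy is

U(R^N) = U_bond + U_elec + U_rep + U_att,

where U_bond sums intra-monomer harmonic springs ½ k_IJ (R − r0)² and the
three nonbonded terms sum over inter-monomer bead pairs only — beads of the
same monomer interact exclusively through springs.  Per pair (I, J) at
distance R:

* U_elec = Q_I Q_J /(4π ε0 ε_r R) · exp(−κ_D R).  Screened electrostatics
  stands in for implicit solvent and salt.  Defaults ε_r = 17.5 and
  κ_D = 1.274 nm⁻¹ correspond to a high-dielectric, ~250 mM salt
  environment; Q are the summed charges of the particles mapped to a bead.
* U_rep = A_IJ H(R_rep − R)[1 + cos(π R / R_rep)] + B/R⁴.  The cosine
  shoulder is a soft steric wall switched off beyond R_rep (the Heaviside
  convention H(0) = 1 is immaterial because the bracket vanishes there);
  the B/R⁴ barrier (default B = 6 kcal/mol·Å⁴ = 2.5104·10⁻³ kJ mol⁻¹ nm⁴)
  prevents collapse of opposite-charge pairs onto the Coulomb singularity.
  It is applied to all pairs by default (it is negligible at typical
  distances and does not affect training); a per-pair flag can disable it.
* U_att = C_IJ /(σ√(2π)) · exp(−(R − R_att)²/2σ²), a Gaussian well of
  width σ = 0.2 nm centered at the typical contact distance.  C_IJ is
  signed — attraction means C < 0 — and the C_IJ are the trainable
  parameters θ.  They are initialized at 0 so early training is driven
  purely by the distributional (KL) term.

All nonbonded terms are truncated sharply at a global cutoff (default
2.5 nm) without energy shifting: the training averages depend on absolute
energies, and every well in this model family has decayed to numerical
noise long before 2.5 nm, so truncation noise is negligible.  Units are
kJ/mol, nm, ps, K and elementary charges throughout (k_B = 0.0083145
kJ mol⁻¹ K⁻¹); kcal/mol inputs are converted at 4.184 on read.

The binding energy V_bind of a configuration is the inter-monomer nonbonded
energy, optionally restricted to one designated monomer pair; it contains
no bonded or intra-monomer contribution.

## Bead definitions (EDCG)

Bead boundaries are placed on a fine chain by minimizing

χ² = 1/(3 N_beads) ⟨ Σ_I Σ_{i<j∈I} |Δr_i^PC − Δr_j^PC|² ⟩,

the intra-bead mismatch of fluctuations projected on the retained principal
components.  Frames are least-squares superposed onto their mean before the
covariance is formed; by default the smallest number of components carrying
≥ 90 % of the total variance is retained.  The ensemble average is
evaluated algebraically from the retained covariance (equivalent to
averaging projected frames): with P_ij the 3×3-block trace of the
reconstructed covariance, a segment of length L costs L·Σ P_ii − Σ P_ij,
which prefix sums make O(n²) for all segments.  A dynamic program over
boundary placements then returns the exact optimum (ties broken toward the
lexicographically smallest boundary vector); a seeded annealing fallback
exists for chains too long for the table.  Beads are contiguous chain
segments; non-contiguous grouping is unsupported.  The bead position
operator is the mass-weighted mean of member particles (uniform weighting
optional); bead charge and mass are sums, so both are conserved exactly.

## Springs (hENM)

Intra-monomer pairs closer than r_enm (default 2.0 nm in the library
surface; the synthetic systems use their native geometry) are connected by
springs with rest lengths at the reference mean distance.  Spring constants
are fitted iteratively: each iteration samples the current model and
updates the compliance,

1/k(n+1) = 1/k(n) − γ_hENM (⟨R²⟩_CG − ⟨R²⟩_ref),

clamped to k ∈ [1, 10⁵] kJ mol⁻¹ nm⁻² (an update driving 1/k ≤ 0 clamps to
the stiff end).  The sampled map k → ⟨R²⟩ is monotone decreasing, so the
update sign always points at the fixed point.  The default per-spring
γ_hENM = 2/(k·⟨R²⟩_ref) moves 1/k by at most ~20 % for a 10 % fluctuation
mismatch, which keeps the iteration stable.  Because the fixed point is
approached through sampling noise, the returned constants are the harmonic
mean of k over a final window of iterations (the compliance is the
quantity the update walks in); initial k is 500 kJ mol⁻¹ nm⁻², a typical
elastic-network scale.  These hENM settings are this package's own
defaults, exposed in the API.

## Sampling

CG ensembles are generated by Langevin dynamics with a BAOAB splitting,
which is accurate for configurational averages at large time steps; the
default step is 15 fs with friction 1 ps⁻¹ (the friction value is a
package default — only the thermostat family is standard here).  Bead
masses are the summed fine masses.  Runs are bitwise reproducible given a
seed.  Complexes live in open boundaries; an optional reflecting spherical
wall about the origin bounds the accessible volume, playing the role of
the reference simulation's finite box: it sets an effective concentration
so that dissociated partners can re-encounter each other, and it prevents
the ensemble averages from being dominated by free diffusion.  Energies,
V_bind, dU/dθ and kinetic energy are recorded every `stride` steps.

## Training

Standard REM descends ∇L = β⟨∇θU⟩_ref − β⟨∇θU⟩_CG with a fresh CG
trajectory per iteration, started from the native (bound) reference
structure so that the per-iteration RMSD is a meaningful training
observable.  For the Gaussian amplitudes, ∇θU is θ-independent given the
coordinates, so the reference-side average is computed once and cached —
an exact optimization, not an approximation.

reg-REM adds κ(V0 − V̄_bind)² to the loss.  Differentiating the ensemble
average under the Boltzmann measure gives the covariance-form estimator

∇θ⟨V_bind⟩ = ⟨∇θV_bind⟩ − β⟨V_bind ∇θU⟩ + β⟨∇θU⟩⟨V_bind⟩,

evaluated from the per-frame records of the same trajectory used for the
KL term.  Because the trainable parameters are purely inter-molecular,
⟨∇θV_bind⟩ coincides with ⟨∇θU⟩ (restricted to the designated pairs in
multimer mode).  With κ = 0 the code path returns the KL gradient
unchanged, bitwise.

Updates are plain gradient descent θ ← θ − γ∇L (no momentum).  Defaults:
γ = 1.0 (kJ mol⁻¹ nm)² per unit gradient, with the update vector rescaled
whenever its largest component exceeds 1 kJ mol⁻¹ nm.  These conservative
values prevent the overshoot limit-cycles that larger steps produce when
the regularizer and the KL term pull against each other; they are this
package's own defaults (no standard values exist for this family of
problems).  If a simulation diverges, γ is halved and the iteration
retried once before the run aborts with its history.  In multimer mode the
gradients and the regularized observable are computed from one designated
monomer pair while the updated type-pair parameters apply to all monomers.
Frames from partially dissociated configurations enter all averages; the
fraction of unbound frames is logged per iteration.

Reported "trained" quantities are means over a final window (default 20
iterations for observables, longer for parameter-recovery studies): at the
stochastic fixed point the iterates fluctuate around the solution, and
window averaging is the cheapest consistent estimator.

Choosing κ: assuming small binding-energy fluctuations, a D_KL gradient of
0.5β nm⁻¹ is balanced against the regularization gradient produced by a
1 kcal/mol affinity error, giving κ = 0.25β/(4.184·⟨∇θV_bind⟩).  With the
observed gradient scale ⟨∇θV_bind⟩ ≈ 1 nm⁻¹ this yields κ ≈ 0.1/4.184
(kJ/mol)⁻² near physiological temperature — the default.

## Rule-based fixed constants

A_IJ comes from the bead charges in multiples of 10 kcal/mol: 10 for
like-sign pairs (sgn 0 counts as matching — the weakest tier), 100 for
Q_I·Q_J < −1 e².  The rule anchors only these two cases; for intermediate
opposite-sign products this package interpolates linearly in |Q_I Q_J|
between the anchors and rounds up to the next multiple — a documented
convention, overridable by an explicit table.  R_rep is the largest radius
below the first peak of the pair distance distribution where
p(R) ≤ 0.05 p_max; peaks are detected on a 3-bin moving average (default
bin width 0.02 nm, maxima below 10 % of the global maximum ignored, a
smoothed single-bin plateau reports its center).  R_att is the first-peak
radius.  Multimer mode uses the milder flat A = 25 kcal/mol,
R_rep = ½(R_gyr,I + R_gyr,J) from per-type gyration radii, and R_att as the
minimum over monomer pairs of the mean inter-monomer type-pair distance.

## Synthetic reference systems

The fixtures module generates the study systems from known ground truth;
every fixture carries its generating amplitudes θ*, springs k* and mapping,
and recovery tests read only the trajectory and topology until the final
comparison.

* **Bound dimer** (strong-binding regime): two 5-bead monomers — a central
  bead with four arms spread in the transverse plane — bound rung-by-rung
  through five trainable Gaussian wells, with complementary rung charges
  and fixed (non-trainable) arm-to-center cross wells.  Every pair's
  repulsive shoulder starts at 0.93 of its native distance, emulating a
  snugly complementary interface: the fixed steric cage, not the trainable
  wells, carries most of the structural rigidity, as in real protein
  interfaces.  The confining wall (1.05 nm) is deliberately snug; with a
  roomier volume this 10-bead complex supports a long-lived mis-registered
  pose that a 50-bead protein complex would exclude sterically.  At the
  ground truth the reference is fully bound with mean V_bind ≈ −25 kJ/mol
  and mean RMSD ≈ 1.5 Å to the native structure.
* **Trimer lattice** (multimer regime): three identical 4-bead monomers on
  a C3 ring, all sharing one type-pair table; training acts on the
  designated pair (0, 1).  Ground-truth designated-pair mean binding
  energy ≈ −40 kJ/mol.
* **Weak duplex** (weak-binding regime): two 4-bead strands paired rung by
  rung, terminal wells half as deep as central ones.  In long bound-state
  runs the terminal rung distances exceed the central ones (fraying), and
  at elevated temperature the strands unbind and rebind repeatedly inside
  the wall.  Ground-truth mean binding energy ≈ −15 kJ/mol.
* **Fine chain** (mapping/hENM ground truth): a bead chain with
  heterogeneous springs is sampled first; each bead is then expanded into a
  tight cluster of fine particles (fixed ring offsets plus small jitter),
  so the essential-dynamics optimum is the generating cluster structure and
  the summed cluster charges/masses reproduce the bead values.

What the fixtures do **not** emulate: real protein or nucleic-acid
geometry, sequence specificity, solvent-mediated many-body effects, or the
system sizes of production studies (tens of beads per monomer, hundreds to
thousands of monomers).  Tests passing on these fixtures demonstrate the
estimators, the optimization behavior and the qualitative regimes — not
chemical accuracy for any real system.

## Problem sizes and numerical choices

Training studies use references of 2000 recorded frames (200k Langevin
steps), 200–250 training iterations of 50k steps each, and final windows
of 20 iterations; parameter-recovery studies use 60k-frame references and
150k-step iterations, sizes at which the reference-side sampling noise
(which shifts the REM fixed point by roughly the noise amplified by the
inverse gradient-sensitivity) sits well below the 10 % recovery bands.
The overstabilization demonstration samples the training trajectories in a
roomier wall (2.5 nm) than the bound-only reference, so the model is free
to explore dissociation the reference never shows; at desk scale the
demonstrated property is a smoothed binding energy that keeps dropping
past the generating model's true mean and never returns toward it within
the training window.  A literal "no plateau ever" is not demonstrable in a
matched model family, which possesses an REM fixed point; the production
failure mode corresponds to the pre-plateau regime shown here.

Gradient estimators are validated against independent quadrature oracles
on a two-bead system with numerically integrable Boltzmann distributions
(both a flat and an R² distance measure), to 10⁻³ relative.  Forces are
validated against central finite differences of the energy (10⁻⁶ nm
displacements), and the zero-friction integrator conserves energy to 10⁻⁴
relative over 10⁴ steps at 1 fs, tying forces and energies together.

Degenerate inputs: overlapping beads raise errors rather than returning
infinities; a frozen (zero-fluctuation) hENM reference drives every spring
to the stiffness clamp; an unstable simulation aborts with the index of
the first non-finite frame.

## Known limitations

* No periodic boundary conditions, Ewald electrostatics, pressure
  coupling, solvent beads, or tabulated potentials; the wall is the only
  concentration control.
* All-pairs nonbonded evaluation — appropriate for the tens-of-beads
  systems here, quadratic beyond that.
* Only the Gaussian amplitudes are trainable; A, R_rep, R_att, σ and the
  electrostatics are fixed by rule.
* CG potentials of this kind are free energies at the training
  temperature; models are not temperature transferable, and simulations at
  other temperatures (as in the duplex unbinding demonstration) probe
  robustness, not calibrated thermodynamics.
* The affinity target V0 refers to the mean CG interaction energy, not a
  binding free energy; free-volume entropy corrections are out of scope.
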