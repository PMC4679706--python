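# Methods

## The model

`dnamelt` simulates the melting (heat denaturation) of short double-stranded
DNA with a coarse-grained, three-site-per-nucleotide representation: each
nucleotide contributes a phosphate bead (charge −1 e), a sugar bead and a
base bead; the 5′-terminal residue of each strand lacks its phosphate, so an
N-bp duplex has 2(3N − 1) beads.  The duplex is built as an ideal B-form
helix (36° twist and 3.38 Å rise per residue by default; both are
configurable geometry constants).  Strand 2 is produced from strand 1 by a
proper rigid motion — a 180° rotation about an axis perpendicular to the
helix axis (which reverses the chain direction, keeping the two strands
antiparallel and preserving chirality) followed by an azimuthal alignment
and an upward shift — so that every base bead faces its Watson–Crick
partner across the helix axis.

The potential has three interaction sets:

1. **Intra-strand (chain structure).**  Bonds (harmonic + quartic), angles
   (harmonic), backbone torsions (periodic, `k(1 − cos(φ − φ₀))`), and
   Gō-type 12-10 wells between native neighbouring bases of the same strand
   (stacking).  All equilibrium values are measured from the ideal B-form
   reference structure (Gō convention), so the built helix is an exact
   minimum of this set; only stiffnesses live in the parameter table.
2. **Inter-strand (hybridization).**  Morse wells between paired base beads
   — deeper for G-C (three hydrogen bonds) than A-T (two) — plus Morse
   *cross-stacking* wells between each base and the partner base of the
   neighbouring pair.  Cross-stacking breaks only when the strands locally
   separate; it is the term that gives melting its cooperativity.  Without
   it the duplex melts by uncorrelated single-pair events with no unzipping
   front and is not even metastable at 300 K, which is why it is part of
   this model even though it goes one term beyond the minimal
   three-bead-per-nucleotide picture.
3. **Solvent-mediated terms.**  Screened Coulomb (Debye-Hückel) repulsion
   between all phosphate pairs, with the Debye length
   κ_D = √(ε₀ ε_k R T / (2 N_A² e² I)) and the water dielectric constant
   held at its room-temperature value (78.3) at all simulation
   temperatures; and a purely repulsive r⁻¹² excluded-volume term between
   all bead pairs not covered by the terms above.  Salt enters the model
   *only* through κ_D.

All parameters are read from a versioned YAML table
(`src/dnamelt/parameters/default.yaml`); the code fixes only the functional
forms.  Internal units are Å, ps, amu and kJ/mol.

## Parameter calibration

The numerical values of the published three-site parameter sets are
deliberately out of scope (the table is pluggable); the defaults shipped
here are an own parameterization calibrated once, by exploratory
simulation, to reproduce the qualitative regime the melting study needs:

* the 11-bp duplex is kinetically stable at 300 K on the nanosecond scale
  (end pairs fray transiently but re-close),
* after a temperature jump to 360–520 K it melts completely within
  nanoseconds (well inside the 10-ns production cap of the desk-scale
  protocol),
* G-C pairs outlive A-T pairs, and lower salt accelerates melting through
  reduced screening of the phosphate repulsion.

Key defaults: ε_AT = 12, ε_GC = 15.5, cross-stacking 14 kJ/mol, Morse width
α = 3 Å⁻¹ at a native base-base contact distance of 2.0 Å; the base-sugar
bond and base-sugar-phosphate angles are deliberately stiff (k₂ = 100
kJ/mol/Å², k_θ = 100 kJ/mol/rad²) so that the screened phosphate repulsion
is transmitted into the pairing coordinate — this coupling is what makes
the melting speed salt-dependent.

## Dynamics

Beads follow the inertial Langevin equation
m r̈ = −∇U − γ m ṙ + W(t) with γ = 0.05 ps⁻¹ and ⟨W W⟩ set by the
fluctuation-dissipation relation at the target temperature.  Integration is
velocity Verlet (dt = 0.01 ps) with the friction/noise pair applied as an
exactly integrated Ornstein-Uhlenbeck substep in the middle of the step
(BAOAB splitting).  Temperature is controlled by a Nosé-Hoover chain
(length 2, coupling 0.1 ps) whose half-steps bracket the Verlet step; the
combination of the chain with the Langevin channel is the
Nosé-Hoover-Langevin (NHL) thermostat.  Either channel can be switched off;
with both off the integrator is symplectic NVE (energy conserved to ~10⁻⁴
relative over 10⁵ steps).

The melting protocol may apply the Langevin substep every 10th step (with
the OU decay integrated over the full interval) — the Nosé-Hoover chain
still acts every step — which roughly halves the cost per step at γ as
small as 0.05 ps⁻¹.  The dynamics-module default remains a stride of 1.

Degrees of freedom: 3n when the Langevin channel is on (noise breaks
momentum conservation), 3n − 3 for NVE/pure-NH runs.  The pure-NH
augmented invariant H + Σ Q v_ξ²/2 + N_f kT ξ₁ + kT Σ ξ_k is tracked and
drifts < 1% over 10⁵ steps; with noise on it is not conserved and is not
reported as such.

## Melting protocol and event detection

Each replica runs: steepest-descent minimization → NHL equilibration at
298 K → instantaneous retarget of the thermostat set-point and noise
temperature to the jump temperature (velocities kept) → production with
on-the-fly event detection until all monitored pairs are dissociated or a
time cap is hit.  Replicas derive independent noise streams from
(master seed, replica id), so ensembles are order- and batch-invariant and
each replica is individually reproducible.

A monitored basepair (all pairs except the first nucleotide of each strand,
i.e. N − 2 of N) dissociates at the first 1-ps detection frame where its
base-base distance exceeds the class threshold (G-C 2.8694 Å, A-T 2.9002 Å,
treated as absolute distances; an offset-from-native reading is available
as a configuration switch) *and* the radial relative velocity is positive,
with both conditions holding for 3 consecutive frames (debouncing).  Events
are first-passage: a pair that re-closes afterwards stays counted, matching
the monotone melting curves the observables assume.  When a stored
trajectory carries no velocities, the sign of the separation increment
replaces the radial velocity.

Observables zero each replica's clock at its first dissociation: melting
duration (first-to-last event gap), interval series Δt between rank-adjacent
events, mean time versus number of dissociated pairs, mean time versus pair
position, and an opening-end classification: a replica is `AT_end`
(`GC_end`) if its first k = 3 events all fall in the terminal 3-pair window
at the A-T-rich (G-C-rich) end, else `both`.  The A-T-rich end is the end
whose terminal window holds more A-T pairs, ties broken by the proximity of
the nearest A-T pair to the terminus (for the 11-bp study sequence this is
the 5′ end of strand 1).  Ensemble means are taken over fully melted
replicas; cap-hits are reported separately and never imputed.

## Problem sizes

The desk-scale preset uses 20 replicas, 2,000 minimization steps, 0.1 ns
equilibration and a 10 ns production cap; `paper_preset()` switches to 100
replicas, 40,000 minimization steps and 1 ns equilibration.  The statistical
melting tests and `scripts/acceptance.py` use the desk-scale preset (the
acceptance script runs 14 replicas per condition); these sizes are the
package's choice of a configuration that keeps a full grid — three
temperatures, three salt concentrations, four chain lengths — runnable on a
single CPU while leaving the trend statistics (one-sided Mann-Whitney,
Spearman, binomial at α = 0.05) well powered for the effects that survive
them.

## What the synthetic fixtures do and do not show

`scripted_trajectory` produces trajectories whose monitored-pair
separations follow a baseline and then ramp monotonically through the
threshold at prescribed times, with velocities consistent with the finite
difference of the positions.  These fixtures validate the entire analysis
stage (detection including debouncing and the opposite-motion clause,
duration/interval identities, curve shapes, classification) independently
of the force field.  They are event-structure doubles only: passing them
says nothing about force-field realism, and the dynamical tests (NVE
conservation, equipartition, stability at 300 K, melting trends) carry that
burden instead.  Likewise, trends reproduced at desk scale with 14–20
replicas establish ordering and sign, not publication-grade rate constants.

## Numerical choices and degenerate inputs

* Angle forces guard sin θ ≥ 10⁻⁸; collinear torsions (degenerate normals)
  contribute zero force for that term.
* The excluded-volume term is truncated at 3σ and energy-shifted to zero
  there; its value at contact differs from ε by < 10⁻⁶ ε.
* Electrostatics are evaluated over all phosphate pairs with no cutoff (the
  chains are tiny); the kernels treat κ_D ≤ 0 as "electrostatics off".
* Minimization is steepest descent with backtracking; energy never
  increases across accepted moves, and a rise triggers a diagnostic error.
  Integrator blow-ups (non-finite coordinates) surface as flagged replica
  results, never as silently dropped replicas.
* Determinism: a simulation segment is a pure function of (state, config,
  seed, invocation counter); identical seeds give bit-identical
  trajectories.

## Known limitations

* The 300 K / 360 K separation is kinetic, not thermodynamic: the model's
  equilibrium melting curve is not computed (out of scope), and stability
  at 300 K is demonstrated as threshold occupancy over 1 ns rather than as
  a free-energy statement.
* At 360 K this parameterization melts the 11-bp duplex through a mixture
  of A-T-end fraying and interior A-T (TAT-block) bubble nucleation.  The
  strict all-three-first-events-in-one-window opening classifier therefore
  almost never returns `AT_end`/`GC_end` even when the position-resolved
  mean dissociation times show the A-T end opening earliest; the
  high-salt AT-end-opening statistic should be read with that in mind.
* At desk scale (20 replicas, 10 ns cap) the salt dependence of the
  melting duration at 360 K, though present in the expected direction
  (slower at higher salt), is smaller than the replica-to-replica spread,
  so the three study concentrations do not order significantly; the cap
  additionally censors the slowest replicas of the slowest condition.
* Melting at 520 K is quasi-parallel (independent per-pair first
  passages), so the gaps between late rank-ordered dissociations grow like
  the tail of order statistics instead of levelling off into the constant
  interval time expected of a sequential unzipping front.
* Mismatches, bulges, circular DNA, tethered chains, crowding and explicit
  ions are out of scope.  The groove structure of real B-DNA is not
  represented (bases sit symmetrically on the helix axis).
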