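# Default force-field parameter table for the three-site-per-nucleotide
# duplex model (version 1).
#
# Units: energies kJ/mol, lengths angstrom, angles handled internally in
# radians, masses amu, charges elementary charge.
#
# The functional forms are fixed by the code (harmonic+quartic bonds,
# harmonic angles, periodic dihedrals, 12-10 Go stacking on native
# intra-strand contacts, Morse wells on native basepairs, r^-12 excluded
# volume, Debye-Hueckel screened Coulomb between phosphates).  Equilibrium
# bond lengths / angles / torsions are taken from the ideal B-form reference
# structure (Go convention), so only stiffnesses appear here.  The
# stiffnesses and well depths below were calibrated once so that an 11-bp
# duplex is kinetically stable at 300 K on the nanosecond scale yet melts
# within nanoseconds after a jump to the 360-520 K study range.
version: 1
masses:              # amu
  phosphate: 94.97
  sugar: 83.11
  A: 134.1
  G: 150.1
  C: 110.1
  T: 125.1
charges:
  phosphate: -1.0    # elementary charges; sugar and base are neutral
bonds:               # V = k2 (r-r0)^2 + k4 (r-r0)^4
  SB:  {k2: 100.0, k4: 60.0}   # sugar - base (stiff: slaves bases to backbone)
  S3P: {k2: 60.0, k4: 60.0}    # sugar(3') - phosphate of next residue
  PS5: {k2: 60.0, k4: 60.0}    # phosphate - sugar(5') of same residue
angles:              # V = k (theta-theta0)^2
  SPS:  {k: 40.0}
  PSP:  {k: 40.0}
  BSP5: {k: 100.0}   # base - sugar - 5' phosphate (stiff: couples backbone
  BSP3: {k: 100.0}   #   repulsion into the pairing coordinate)
dihedrals:           # V = k (1 - cos(phi-phi0))
  SPSP: {k: 5.0}
  PSPS: {k: 5.0}
stacking:            # native intra-strand base-base contacts, 12-10 Go well
  eps: 5.0
base_pair:           # Morse wells between paired base beads
  eps_AT: 12.0
  eps_GC: 15.5
  sigma_AT: 2.0
  sigma_GC: 2.0
  alpha: 3.0         # 1/angstrom, well width
  # cross-stacking: Morse wells between a base and the partner base of the
  # neighbouring pair (duplex cooperativity; breaks on strand separation)
  cross_eps: 14.0
excluded_volume:     # V = eps (sigma/r)^12, shifted to zero at cutoff
  eps: 2.0
  sigma: 2.0
  cutoff_factor: 3.0
electrostatics:
  relative_permittivity: 78.3
dissociation:        # basepair separation beyond which a pair counts as open
  threshold_AT: 2.9002
  threshold_GC: 2.8694
  mode: absolute     # "absolute" or "offset" (offset adds the native sigma)
geometry:            # ideal B-form construction
  twist_deg: 36.0
  rise: 3.38
  r_base: 1.0
  r_sugar: 6.9
  r_phosphate: 8.9
  sugar_angle: -0.30      # rad, azimuthal offset from the base bead
  phosphate_angle: -0.60
  phosphate_dz: -1.69     # phosphate sits half a rise below its sugar
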