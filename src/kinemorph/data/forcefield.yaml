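# Heavy-atom (united-atom-style) nonbonded parameters for steric-clash
# screening.  Lennard-Jones rmin/2 (Angstrom) and well depth (kcal/mol) per
# element; partial charges (e) from a per-residue-neutral backbone template,
# side-chain heavy atoms neutral by default.  Override any entry via the
# ForceFieldParams constructor or a user YAML.
elements:
  C: {rmin2: 1.908, epsilon: 0.086}
  N: {rmin2: 1.824, epsilon: 0.170}
  O: {rmin2: 1.6612, epsilon: 0.210}
  S: {rmin2: 2.000, epsilon: 0.250}
  H: {rmin2: 0.600, epsilon: 0.0157}
# Backbone charges are the Cornell et al. all-atom values with each
# hydrogen's charge folded into its bonded heavy atom (N+H, CA+HA), keeping
# every residue net-neutral without explicit hydrogens.
charges:
  backbone:
    N: -0.1438
    CA: 0.1160
    C: 0.5973
    O: -0.5679
    OXT: -0.5679
  default: 0.0
scaling:
  elec14: 1.2   # divisor for 1-4 electrostatics
  vdw14: 2.0    # divisor for 1-4 van der Waals
coulomb_constant: 332.06  # kcal*Angstrom/(mol*e^2)
dielectric: 1.0
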