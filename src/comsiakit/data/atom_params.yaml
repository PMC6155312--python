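# Per-element parameters for similarity-index atom weights.
#
# vdw_radius: Bondi van der Waals radii (Angstrom).  Steric weights are the
#   cube of these values.
# hydrophobic: simplified atomic hydrophobicity contributions (dimensionless,
#   roughly the sign/scale of fragmental logP schemes: apolar atoms positive,
#   heteroatoms negative).  A coarse table is sufficient because the field is
#   regressed, not interpreted absolutely; it is pluggable via config.
version: 1
vdw_radius:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  P: 1.80
  S: 1.80
  Cl: 1.75
  Br: 1.85
  I: 1.98
hydrophobic:
  H: 0.0
  C: 0.5
  N: -0.5
  O: -0.5
  F: 0.2
  P: 0.1
  S: 0.3
  Cl: 0.4
  Br: 0.5
  I: 0.6
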