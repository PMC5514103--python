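# Van der Waals radii for solvent-accessibility work, Chothia-style class values
# (tetrahedral C 1.87, trigonal/carbonyl C 1.76, N 1.65, O 1.40, S 1.85),
# enumerated per residue for the sp2 carbons and falling back to the element.
name: chothia-class-radii
probe_radius: 1.4
elements:
  C: 1.87
  N: 1.65
  O: 1.40
  S: 1.85
  P: 1.80
  SE: 1.90
residue_atoms:
  "*":        # backbone carbonyl carbon of every amino acid
    C: 1.76
  ARG: {CZ: 1.76}
  ASP: {CG: 1.76}
  ASN: {CG: 1.76}
  GLU: {CD: 1.76}
  GLN: {CD: 1.76}
  HIS: {CG: 1.76, CD2: 1.76, CE1: 1.76}
  PHE: {CG: 1.76, CD1: 1.76, CD2: 1.76, CE1: 1.76, CE2: 1.76, CZ: 1.76}
  TYR: {CG: 1.76, CD1: 1.76, CD2: 1.76, CE1: 1.76, CE2: 1.76, CZ: 1.76}
  TRP: {CG: 1.76, CD1: 1.76, CD2: 1.76, NE1: 1.65, CE2: 1.76, CE3: 1.76,
        CZ2: 1.76, CZ3: 1.76, CH2: 1.76}
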