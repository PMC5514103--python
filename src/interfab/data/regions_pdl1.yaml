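# Strand/loop region map for the IgSF V-set domain of human PD-L1
# (author numbering, crystallized construct aa 18-134).
#
# The V-set beta-sandwich strands are labelled A..G in the immunoglobulin
# convention; the front CC'FG sheet and its flanking loops carry the receptor
# and antibody binding sites. Exact boundary residues are an editorial choice;
# these were drawn so that the canonical assignments of the interface residues
# (e.g. E45/D49 in the BC loop, I54/Y56/E58 in strand C, E60/D61 in the CC'
# loop, V68/H69 in the C'C'' loop, Y118/G119 in the FG loop, A121..T127 in
# strand G) hold.
antigen: PD-L1
regions:
  N-term:      [[18, 22]]
  A:           [[23, 30]]
  AB-loop:     [[31, 32]]
  B:           [[33, 44]]
  BC-loop:     [[45, 53]]
  C:           [[54, 59]]
  CC'-loop:    [[60, 65]]
  C':          [[66, 67]]
  C'C''-loop:  [[68, 71]]
  C'':         [[72, 76]]
  D:           [[77, 82]]
  DE-loop:     [[83, 88]]
  E:           [[89, 98]]
  EF-loop:     [[99, 105]]
  F:           [[106, 117]]
  FG-loop:     [[118, 120]]
  G:           [[121, 127]]
  C-term:      [[128, 134]]
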