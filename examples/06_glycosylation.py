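"""N-glycosylation sites of PD-L1 and whether an epitope could feel them.

N-linked glycans attach at N-X-S/T sequons (X != P). For an antibody whose
epitope lies far from every glycosylated asparagine — or whose construct
does not even contain them — binding is expected to be glycosylation-
independent. The scan below finds the sequons of full-length human PD-L1;
the distance flagging is demonstrated on a synthetic complex.
"""

from importlib import resources

from interfab import EpitopeSet, find_sequons, glyco_epitope_distance, read_fasta
from interfab.fixtures import make_homolog_pair

text = (resources.files("interfab.data") / "pdl1_human.fasta").read_text()
sequence = next(iter(read_fasta(text).values()))

print("sequons of full-length human PD-L1 (precursor numbering):")
for hit in find_sequons(sequence):
    print(f"  N{hit.position}  ({hit.triplet})")
print()
print("N35 sits in the B strand of the V-set domain; N192/N200/N219 belong to")
print("the C-set domain, outside the usual V-set antibody epitopes.")
print()

# distance flagging on a synthetic complex: the epitope is residue 5,
# candidate 'glyco' sites are residues 5 (inside) and 1 (four residues away)
complex_model, _, _, _ = make_homolog_pair(1.0, substitute=False)
epitope = EpitopeSet("toy-ab", {complex_model.chains["A"][4].key})
for pos, info in glyco_epitope_distance(complex_model, [5, 1, 400], epitope).items():
    dist = "n/a" if info["min_distance_A"] is None else f"{info['min_distance_A']:.1f} A"
    print(f"site {pos}: present={info['present']}  min distance {dist}  "
          f"independent={info['independent']}")
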