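# Methods

This note documents the models, criteria and numerical choices behind
interfab, what the synthetic fixtures do and do not emulate, and the design
decisions taken where several defensible options existed.

## Coordinate model

Structures are parsed with gemmi (PDB and mmCIF) into a plain
chain → residue → atom hierarchy keyed by author numbering, so residue
labels used in the structural literature on PD-L1 (E58, R113, A121, …) map
directly onto model keys. Conventions applied at parse time:

* **Hydrogens are dropped.** All downstream criteria are heavy-atom based;
  the crystal structures this package targets (2.6–3.1 Å) carry no reliable
  hydrogen positions, and a criterion that pretended otherwise would be
  false precision.
* **Alternate locations** are resolved to the highest-occupancy conformer,
  ties broken by altloc letter order — deterministic and matching common
  practice. Altloc resolution never changes the residue count.
* **Multi-model files**: the first model is used unless another is
  requested.
* **Waters** are retained and always carry the role `water`, regardless of
  the chain they were deposited in.

Chain roles (`antigen`, `heavy`, `light`, `water`, `other`) come either
from an explicit per-chain role map or from sequence inference:
antigen chains by global-alignment identity to a supplied antigen sequence,
Fab heavy/light chains by the N-terminal signatures of the human IgG1 CH1
(`ASTKGPSVFPLAP`) and kappa CL (`TVAAPSVFIFPP`) constant domains, and each
antigen paired with its spatially nearest heavy/light chains to define one
complex copy of a crystal asymmetric unit.

## SASA

The Shrake–Rupley implementation tests, for every atom, a fixed lattice of
points on its solvent-expanded sphere (radius r_i + r_probe) against the
expanded spheres of all neighbors found with a k-d tree.

* **Point set**: a generalized golden-angle spiral — deterministic, no RNG,
  so areas are bit-for-bit reproducible. Default 960 points/atom: against
  the exact two-sphere spherical-cap solution the per-atom error stays
  below 0.5% across a grid of radii and separations (the acceptance script
  measures ~0.48% worst-case). Rigid-motion invariance is a stricter test
  because errors no longer cancel between configurations; at 7680 points
  the drift is a few hundredths of a percent, which is the lattice used
  where 0.1%-level invariance matters.
* **Radii**: one explicit Chothia-class table shipped as YAML (tetrahedral
  C 1.87 Å, trigonal/carbonyl C 1.76 Å, N 1.65 Å, O 1.40 Å, S 1.85 Å,
  probe 1.4 Å), with element-level fallback. Published interface areas
  rarely state their radii; pinning one table makes results reproducible
  and comparisons honest. Every `SasaResult` records table id, probe and
  point count. The `*` (backbone) entries of the table apply to standard
  amino acids only, so a ligand atom named `C` falls back to its element.
* **Waters and hetero ligands** are excluded from SASA and buried-area
  computations unless selected explicitly; the buried areas reported here
  are protein–protein quantities.

Buried surface area is `SASA(A) + SASA(B) − SASA(A∪B)`, i.e. the total
over both partners — the convention under which an Fab interface buries
~1600–2100 Å². Per-chain contribution fractions divide each chain's summed
per-atom ΔSASA by the side total; they sum to 1 by construction.

## Contact typing

All criteria are distances between heavy atoms, configurable and echoed in
every report; defaults:

| category | criterion | default |
| --- | --- | --- |
| hydrogen bond | donor/acceptor N/O pair (typing table per residue; backbone N donates except Pro, backbone O/OXT accepts) | ≤ 3.5 Å |
| salt bridge | Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 vs Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT | ≤ 4.0 Å |
| van der Waals | any remaining cross-side pair | ≤ 4.0 Å |
| water bridge | water O ≤ cutoff from ≥1 polar atom of each side | ≤ 3.5 Å |

Category precedence is salt bridge > hydrogen bond > vdW, so one atom pair
is counted exactly once; an ionic pair is reported as a salt bridge, not
double-counted as a hydrogen bond — this matches how interface inventories
separate "n hydrogen bonds, m salt bridges". In summary counts, hydrogen
bonds and vdW contacts are atom pairs, salt bridges are distinct residue
pairs (a bidentate guanidinium–carboxylate interaction counts once), and
water bridges are distinct waters. Sulfur atoms are excluded from
hydrogen-bond typing; aromatic-stacking and cation-π geometries are not
classified separately and fall under vdW — a documented simplification, not
a modeling claim.

An optional donor-angle proxy exists as a configuration knob but is off by
default: without hydrogens any angle term is a guess, and the package
prefers a transparent distance-only criterion.

Interface residues combine two signals: per-residue ΔSASA > 0.1 Å² (the
burial signal) unioned with residues having any cross-side pair within the
vdW cutoff (so a contact residue whose burial falls below the
discretization floor is still counted).

## Superposition, epitopes, plasticity

Rigid fits use the Kabsch SVD solution with the reflection correction;
collinear or <3-point inputs are rejected as ill-conditioned. Rotation
magnitude is `arccos((tr R − 1)/2)`, axis-agnostic; the sign of an elbow
rotation is not reported. Near 0° the arccos amplifies floating-point
noise to ~1e-6 degrees, which tests treat as zero at 1e-4°.

Cross-complex comparisons superpose every complex onto a reference via the
antigen Cα atoms shared by author numbering (all deposited PD-L1 complexes
share that numbering, so no alignment step is needed within one antigen).
Epitopes are the antigen-side interface residues, labelled by a region map.
The shipped PD-L1 map names the V-set strands A–G and their loops; exact
boundary residues are an editorial choice drawn so the canonical
assignments hold (E45/D49 in the BC loop, I54–E58 in strand C, E60/D61 in
the CC′ loop, V68/H69 in the C′C″ loop, V111–S117 in strand F, Y118/G119 in
the FG loop, A121–T127 in strand G, N35 in strand B). Mid-domain boundaries
far from any epitope are plausible but load-bearing for nothing.

Loop deviation superposes two antigens on all shared Cα *excluding* the
region of interest, then measures per-residue displacement over that
region — a mobile loop must not be averaged into its own reference frame.

The Fab elbow swing between two copies: align on variable-module Cα, fit
the constant modules, report the residual rotation; the maximum over all
copy pairs is the headline number. The measurement is symmetric in pair
order and invariant to global rigid motions (tested to 0.1°). Variable and
constant residue ranges are configuration, not inferred.

For multi-copy asymmetric units the pipeline computes every copy and
reports each plus mean and spread; a single published number is compared
against the closest copy, with the spread logged rather than hidden.

## Cross-reactivity and glycosylation

The homolog analysis seeds an iterative structural alignment with a
Needleman–Wunsch global alignment (linear gaps, deterministic diagonal-first
tie-breaking), then alternates Kabsch fitting with re-pairing of Cα atoms
within 3.5 Å. Re-pairing is a dynamic program over the inter-Cα distance
matrix that maximizes summed (cutoff − distance) subject to sequence-order
preservation — monotonicity prevents topology-violating pairings on
β-sandwich folds. Iteration stops when the pair set is stable (≤ 20
rounds). Unpaired regions (e.g. a loop present in one homolog only) simply
remain unpaired; they are detected, not modeled.

The graft clash scan carries the homolog's own side-chain coordinates into
the complex frame via that alignment — no rotamer rebuilding, exactly as a
superposition overlay figure would — and reports heavy-atom pairs with van
der Waals overlap `r_i + r_j − d > 0.4 Å` between the grafted residue's
side chain and the binder. The 0.4 Å threshold is the conventional
severe-clash margin and is configurable. A self-graft (identical residue,
identical coordinates) yields zero clashes by construction and serves as
the negative control.

Sequon scanning is the textbook N-X-[S/T], X ≠ P rule in author numbering.
A glycosylation site is flagged independent of an epitope when its Asn
side chain lies more than 10 Å (configurable) from every epitope atom, or
when the site lies outside the crystallized construct entirely — the
correct statement for C-set-domain sites against a V-set-domain epitope is
"absent from the construct", and the report says so rather than inventing a
distance.

## Synthetic fixtures: what they do and do not show

The generators build coordinate models whose correct answers are known by
construction: sphere clusters with closed-form SASA and exhaustive pair
lists; two-chain toy complexes with one planted contact per 15 Å slot
(residues with real atom names — SER OG, ARG NH1/NH2, GLU OE1/OE2 … — so
the typing tables are exercised), engineered so no unplanned cross-chain
pair comes within 4.5 Å; hinged two-domain Cα chains with an exact known
rotation; and antigen/homolog pairs with an alanine→tryptophan substitution
whose ring tip overlaps a partner atom by a stated margin. Planted
distances are sampled away from the classification cutoffs (e.g. hydrogen
bonds in 2.6–3.4 Å against a 3.5 Å criterion) so recovery tests assert
classification, not boundary rounding. A fixed seed gives byte-identical
PDB output.

These fixtures are geometric test instruments, not proteins: backbone
geometry is idealized, domains are random blobs, no stereochemistry is
enforced. Passing them demonstrates that the *measurements* are correct —
areas against closed forms, detectors against constructions, angles against
planted rotations — not that any biological conclusion holds. Conclusions
about the real complexes come only from the deposited coordinates, which
are resolved against a local cache (`data/structures/`) that the user
populates explicitly; the tools never download implicitly, and analyses
that need those files state their absence instead of silently skipping.

## Problem sizes and determinism

Default problem sizes were chosen so the whole synthetic suite runs in
seconds on one core: 500-atom clusters for neighbor-search exactness (20
seeds), 50 random toy complexes for detector recovery, length ≤ 7 sequences
for alignment-vs-enumeration (the exponential oracle explores the full
alignment tree), 960-point lattices for closed-form agreement and 7680 for
invariance checks. All randomness flows through seeded generators; reports
serialize with sorted keys and no timestamps, so identical inputs give
byte-identical output.

## Known limitations

* Distance-only hydrogen bonds over-count relative to criteria with angle
  terms at hydrogen-aware resolutions; counts should be compared at stated
  cutoffs, which every report echoes.
* SASA is Shrake–Rupley, not an analytic Lee–Richards or power-diagram
  method; accuracy is bounded by the lattice (quantified above), and exact
  agreement with other software additionally depends on their radii tables.
* No symmetry-mate generation: analyses see the deposited asymmetric unit.
* π-stacking geometries are not classified; CDR boundaries and Fab V/C
  ranges are configuration inputs, not predictions.
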