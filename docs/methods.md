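# Methods

## Scope and model

`ptmstructkit` characterizes post-translational modification (PTM)
substrate sites in the context of protein tertiary structure. Its core
quantities, for a substrate residue *p* localized on a crystal
structure and a neighboring residue *k*:

* **Substrate-direction vector** `S_k = X_p^mod − X_k^Cα`, from the
  neighbor's Cα to the substrate's *modified atom* — the side-chain
  atom that carries the modification chemistry (OG for phosphoserine,
  ND2 for N-glycosylated asparagine, NZ for acetyl/ubiquityl-lysine).
* **Side-chain vector** `V_k = X_k^F − X_k^Cα`, from the neighbor's Cα
  to its *functional atom*, the designated terminal side-chain atom of
  its residue type.
* **Orientation angle** `θ_k = arccos(S_k·V_k / ‖S_k‖‖V_k‖)`, in
  degrees. A neighbor with `θ_k < 80°` points its side chain toward the
  substrate and is classified a *functional residue* for that site. The
  threshold is strict (`80.0°` itself is not functional) and
  configurable.

Both the substrate's modified atom and each neighbor's functional atom
come from one fixed lookup table (S→OG, T→OG1, Y→OH, C→SG, K→NZ, R→CZ,
N→ND2, Q→NE2, D→CG, E→CD, H→NE2, W→NE1, F→CZ, M→SD, L→CG, I→CD1, V→CB,
A→CB, P→CG; glycine has none). The table encodes the "chemical business
end" convention; when the designated atom is unresolved in the
coordinates, the outermost resolved side-chain atom substitutes and the
result is flagged. Treating the substrate's modified atom as its
functional atom generalizes the construction uniformly across PTM
types.

Around a site the toolkit reports **sequential neighbors** (offsets −6
to +6, truncated at termini), **spatial neighbors** (residues whose Cα
lies within 10 Å of the site's modified atom, ≤ convention at the
boundary, sorted by distance), and the **radial cumulative amino-acid
composition**: for each radius r ∈ {2, 3, …, 10} Å, the 20-vector of
counts of residues with Cα within r, and its normalized frequencies.
Counts are cumulative and therefore monotone in r; an empty shell has a
NaN frequency vector. The distance reference is configurable
(`functional_atom`, `calpha`, `any_sidechain_atom`) because "distance
to the side chain" and "distance to the Cα" are both sensible
conventions; the default is the site's modified atom with neighbors
measured at their Cα.

## Structure handling

PDB files are parsed with gemmi and reduced to an explicit model:
first coordinate model only; alternate locations resolved at parse time
(highest occupancy wins, ties by alphabetically first altloc code);
waters and non-amino-acid HETATM groups routed to a het store;
resolution taken from REMARK 2. Chain sequences are derived from the
residues actually present in the coordinates (not SEQRES), because
per-residue geometry requires resolved residues; non-standard residues
render as `X`.

Peptide-to-structure mapping is exact-substring matching at 100%
identity across all chains. Ambiguous placements (more than one match)
are errors listing the candidates — correctness over recall. With the
default filter, a structure qualifies only when its recorded resolution
is strictly better than 2.5 Å; a missing resolution record fails the
filter unless filtering is disabled. User-facing residue numbering is
the author numbering (with insertion codes) of the coordinate file.

## Solvent accessibility

SASA uses the Shrake–Rupley construction: each heavy atom's sphere is
expanded by the probe radius (1.4 Å water) and sampled with a
deterministic golden-spiral point set (960 points by default); a point
is accessible when outside every other expanded sphere. Radii: C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80, Se 1.90 Å; unknown elements fall back
to 1.7 Å with a warning. Relative accessibility divides residue SASA by
the Tien et al. (2013) theoretical Gly-X-Gly maxima; values above ~1
occur for unusually extended or isolated residues and are flagged above
1.2. Numerical properties: an isolated atom reproduces 4π(r+probe)²
within the quadrature error (<1 % at 960 points); adding an occluder
never increases another atom's SASA; results are exactly
translation-invariant but only rotation-invariant to quadrature
resolution (~2 %), because the sample directions are fixed in the lab
frame. DSSP-derived SASA values differ from Shrake–Rupley by small
systematic amounts; no agreement with DSSP is claimed.

## Drug-binding proximity

Het groups are partitioned into ligands by (chemical component code,
chain, residue number), excluding water and a configurable list of
crystallization ions/buffers/cryoprotectants. A site is
drug-binding-associated when the minimum distance between its
side-chain heavy atoms (Cα fallback for glycine) and a ligand's heavy
atoms is ≤ 10 Å. The atom-minimum metric is the strict literal reading
of "side chain within 10 Å"; centroid distance would be laxer.
Corpus-level drug keyword filters and DrugBank joins are metadata, not
geometry: users may supply a het-code → drug-label annotation table.

## Benchmark construction and evaluation

Positive examples are 21-mer windows (2n+1, n = 10; pad `-` at termini)
centered at annotated sites of the target residue type; negatives are
windows at every other occurrence of that residue type *in the same,
modified, proteins* — unmodified proteins contribute nothing, so
negatives share the proteins (and composition biases) of the positives.
Redundancy removal is greedy incremental clustering in input order: a
fragment joins the first cluster whose founder it matches at ≥ 50%
identity (identity = identical non-pad characters over the full window
length), else founds a new cluster; founders are the representatives.
A cross-set purge then removes negatives identical (100%) to any
positive. This reimplements the CD-HIT-style procedure at desk scale;
the guaranteed contract is the non-homology invariant (no retained
within-set pair at ≥ threshold, no cross-set duplicate), not
bit-for-bit agreement with CD-HIT's heuristics. Predictors are scored
with Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc, and MCC (reported as 0 with
a flag when a denominator term vanishes).

## Network assembly

Given query proteins, pathway membership, pathway edges and PPI edges
(all user-supplied TSVs — pathway and interaction databases are
resources, not algorithms), the network contains the queries, all
members of pathways touched by a query, and PPI partners of queries.
Pathway edges between included members and PPI edges incident to a
query are retained, labelled by kind; node attributes record query
status, pathway mapping, and PTM types. The builder is deterministic
and independent of input row order. Exports: GraphML (lossless
attributes), SIF, edge TSV.

## Synthetic data

The fixture generator defines the test conditions; all randomness flows
from one integer seed and identical specs give byte-identical outputs.

*Toy structure*: a serine substrate with, by default, four planted
neighbors at (4.0 Å, 27.9°), (6.5 Å, 95.0°), (9.9 Å, 45.0°),
(10.1 Å, 120.0°) — covering a functional and a non-functional side
chain and both sides of the 10 Å cutoff, with 27.9° matching the value
the toolkit reports for the kinase worked example — and four one-atom
ligands at 5.0, 6.4, 10.0 and 12.0 Å (6.4 Å mirrors a reported
drug-contact distance; 10.0/12.0 probe the cutoff). Coordinates realize
the planted values exactly (neighbor Cα placed on the sphere of the
planted radius; the side chain laid along a direction at exactly the
planted angle to `S_k`), so analysis must invert the construction to
1e-6. Placement directions are re-drawn on steric collisions; planting
an infeasible geometry raises.

*Synthetic proteome*: 40 proteins of 150–400 residues, target residue
(lysine) at 6% frequency, 60 planted ubiquitylation sites on ~60% of
proteins, plus 5 injected cross-set duplicate windows and 5 within-set
duplicate negatives, spliced so as not to disturb planted sites. The
manifest's expected counts are computed by an independent vectorized
redundancy scan over the final sequences, so the benchmark pipeline is
checked against a second code path, not against itself. The generator
emulates composition and redundancy structure only — no real motif
signal, no homologous families beyond the injected duplicates — so
passing tests demonstrate the bookkeeping and non-homology contracts,
not predictive performance on real proteomes. Random blob structures
used by the geometry oracles are likewise not physically realistic
conformations; they exercise distance bookkeeping only.

## Numerical choices

* Dot products are clamped to [−1, 1] before arccos; zero-length
  vectors are errors, and coincident functional/Cα atoms are flagged
  degenerate.
* Distance boundaries are inclusive (≤ cutoff) so a documented cutoff
  is attainable; the resolution filter is exclusive (< 2.5 Å) because
  "better than" is strict.
* Angle recovery through a PDB file round trip is limited by the
  format's 3-decimal coordinates (~0.02° for typical vector lengths);
  in-memory recovery is exact to 1e-6°.
* Ties in neighbor ordering break by (chain id, residue number,
  insertion code); clustering ties resolve to the earliest founder.

## Problem sizes

Default test and acceptance runs use: 100 random structures of 50–1000
residues for the neighbor/radial oracles; 960-point quadrature (4000
for convergence checks); a 40-protein proteome (~430 raw fragments);
10 000 fragments for the random-predictor MCC check. These sizes give
stable statistics at interactive runtimes.

## Known limitations

* mmCIF input, SEQRES-based renumbering and NMR ensembles are not
  supported; X-ray-style single-model PDB files are assumed.
* Secondary structure is not computed; if needed it should be supplied
  as an external annotation.
* The radial profile reports raw cumulative frequencies; a
  background-corrected propensity normalization is a documented
  possible extension.
* SASA ignores hydrogens and does not decompose polar/apolar surface.
* The functional-atom table is a convention; alternative choices (e.g.
  CG vs OD1 for aspartate) shift θ by residue-dependent amounts.
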