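# ptmstructkit

A toolkit for the structural characterization of post-translational
modification (PTM) substrate sites on protein 3D structures. It is
aimed at structural bioinformaticians who have site-level PTM
annotations (e.g. phosphosites, ubiquitylation sites) and want to place
them on crystal structures and quantify their spatial context — and at
tool builders who need clean, non-homologous benchmark datasets to
evaluate PTM site predictors.

## What it computes

Given a substrate residue *p* localized on a structure and a
neighboring residue *k*:

* **S**ₖ = X_p^mod − X_k^Cα — vector from the neighbor's Cα to the
  substrate's modified side-chain atom,
* **V**ₖ = X_k^F − X_k^Cα — the neighbor's side-chain direction, Cα to
  its functional atom (OG for Ser, NZ for Lys, …),
* θₖ = arccos(**S**ₖ·**V**ₖ / ‖**S**ₖ‖‖**V**ₖ‖) — the side-chain
  orientation angle; neighbors with θₖ < 80° are classified as
  *functional residues* whose side chains point at the site.

Around each mapped site the toolkit reports sequential neighbors
(positions −6…+6), spatial neighbors (Cα within 10 Å of the site's
side chain), the radial cumulative amino-acid composition over 2–10 Å,
Shrake–Rupley solvent-accessible surface area, and ligand proximity
(a site is drug-binding-associated when its side chain lies within
10 Å of a bound ligand's heavy atoms). It also builds non-homologous
benchmark datasets — 21-residue windows around modified / unmodified
residues of the same type, greedily clustered at 50% identity with a
100%-identity cross-set purge — scores predictors (Sn, Sp, Acc, MCC),
and assembles PTM regulatory networks from pathway membership and
protein–protein interaction tables.

Peptides are mapped to structure chains at 100% sequence identity on
X-ray structures better than 2.5 Å resolution; ambiguous placements are
reported, never guessed. See `docs/methods.md` for conventions,
tolerances and limitations.

## Worked example

Every analysis is testable without downloads: the fixtures module
writes a small PDB file whose geometry is planted by construction.

```bash
ptmstructkit fixtures make --seed 7 --out example
ptmstructkit analyze-site --pdb example/toy_structure.pdb \
    --chain A --resnum 338 --out example/site_report.json
```

prints `3 neighbors within 10.0 A` and writes a report whose neighbor
table reads:

```json
"neighbors": [
  {"residue": "B:SER1", "aa": "S", "distance": 4.0,
   "theta_deg": 27.9, "functional": true},
  {"residue": "B:SER2", "aa": "S", "distance": 6.5,
   "theta_deg": 95.0, "functional": false},
  {"residue": "B:SER3", "aa": "S", "distance": 9.9,
   "theta_deg": 45.0, "functional": true}
]
```

The nearest neighbor sits 4.0 Å from the substrate serine's OG atom
with its side chain at 27.9° to the substrate direction — well under
the 80° threshold, so it is flagged functional; the 95° neighbor points
away and is not. A fourth planted neighbor at 10.1 Å is correctly
outside the 10 Å cutoff. The same fixture carries four planted
ligands:

```bash
ptmstructkit drugscan --pdb example/toy_structure.pdb \
    --chain A --resnum 338 --out example/contacts.tsv
```

```text
het_code  ligand     min_distance  within_cutoff
LIG       L:LIG900   5.0           True
LIG       L:LIG901   6.4           True
LIG       L:LIG902   10.0          False
LIG       L:LIG903   12.0          False
```

The contacts at 5.0 and 6.4 Å mark this site as
drug-binding-associated. The third ligand illustrates a boundary
subtlety: it was planted at exactly 10.0 Å (included by the toolkit's
≤ convention when analysed in memory), but PDB files carry 3-decimal
coordinates, and after the write/read round trip its distance is
10.0003 Å — marginally outside the cutoff, displayed rounded as 10.0.

The benchmark pipeline runs from FASTA + site-table inputs:

```bash
ptmstructkit benchmark build --fasta example/proteome.fasta \
    --sites example/sites.tsv --residue K --ptm Ubiquitylation \
    --out example/dataset
ptmstructkit benchmark eval --dataset example/dataset \
    --pred preds.tsv --out metrics.json
```

For the kinase worked example on a real structure (phosphosite Ser338
of the cAMP-dependent protein kinase catalytic subunit), place a copy
of PDB entry 2QCS at `scratch/2qcs.pdb` and run
`python -m pytest tests/test_acceptance.py -k Kinase`; the suite checks
the reported neighbor geometry of that entry (Ser114 at 27.9°, nearest
neighbors Asn113/Ser114/Arg336, arginine modal in the radial profile).

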