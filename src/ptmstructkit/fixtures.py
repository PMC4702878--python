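"""Deterministic synthetic fixtures with known ground truth.

Two generators cover the toolkit's inputs without any download:

* :func:`make_toy_structure` writes a small, valid PDB file in which the
  planted quantities -- neighbor Calpha distances, side-chain orientation
  angles, and ligand minimum distances -- are realized exactly by
  construction, so every geometric analysis can be checked against the
  plan it was built from.
* :func:`make_synthetic_proteome` writes a FASTA + site-table pair with
  planted modification sites and deliberately injected duplicate
  windows, together with a manifest of expected benchmark counts
  computed by an independent (vectorized) redundancy scan.

All randomness flows from the single integer seed in the spec; the same
spec yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ptmstructkit.mapping import MappedSite
from ptmstructkit.structio import (
    Atom,
    Residue,
    SiteRecord,
    StructureModel,
)
from ptmstructkit.geometry import AMINO_ACIDS, FUNCTIONAL_ATOMS

__all__ = [
    "FixtureSpec",
    "make_toy_structure",
    "toy_mapped_site",
    "make_chain_structure",
    "make_random_structure",
    "make_synthetic_proteome",
]

#: 1-letter -> 3-letter codes for sequence-driven structure synthesis.
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_ELEMENT_OF_PREFIX = {"C": "C", "N": "N", "O": "O", "S": "S", "P": "P"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_OF_PREFIX.get(atom_name[0], "C")


@dataclass
class FixtureSpec:
    """Directives for the synthetic generators.

    Geometry: ``neighbors`` is a list of (Calpha distance A, orientation
    angle deg or None for a glycine neighbor); ``ligand_distances`` are
    planted minimum side-chain-to-ligand distances in A.  Proteome:
    protein count, length range, target-residue frequency, number of
    planted sites and injected duplicate windows.
    """

    seed: int = 0
    # structure directives
    neighbors: tuple[tuple[float, float | None], ...] = (
        (4.0, 27.9),
        (6.5, 95.0),
        (9.9, 45.0),
        (10.1, 120.0),
    )
    ligand_distances: tuple[float, ...] = (5.0, 6.4, 10.0, 12.0)
    resolution: float = 2.0
    site_seq_id: int = 338
    # proteome directives
    n_proteins: int = 40
    length_range: tuple[int, int] = (150, 400)
    target_residue: str = "K"
    target_frequency: float = 0.06
    ptm_type: str = "Ubiquitylation"
    n_sites: int = 60
    n_cross_duplicates: int = 5
    n_within_duplicates: int = 5
    window_n: int = 10
    identity_threshold: float = 0.5

    def __post_init__(self) -> None:
        for d, theta in self.neighbors:
            if d <= 0:
                raise ValueError(f"planted distance {d} must be > 0")
            if theta is not None and not 0.0 <= theta <= 180.0:
                raise ValueError(f"planted angle {theta} outside [0, 180]")
        if any(d <= 0 for d in self.ligand_distances):
            raise ValueError("planted ligand distances must be > 0")


def _backbone(ca: np.ndarray) -> list[Atom]:
    """Minimal backbone around a Calpha (fixed local offsets)."""
    return [
        Atom("N", "N", ca + np.array([-1.20, 0.80, 0.0])),
        Atom("CA", "C", ca.copy()),
        Atom("C", "C", ca + np.array([1.20, 0.80, 0.0])),
        Atom("O", "O", ca + np.array([1.40, 2.00, 0.0])),
    ]


def _perpendicular(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(v)))] = 1.0
    p = np.cross(v, axis)
    return p / np.linalg.norm(p)


def make_toy_structure(spec: FixtureSpec) -> tuple[StructureModel, pd.DataFrame]:
    """Build a structure realizing the spec's planted geometry exactly.

    Chain A holds a single serine substrate residue (OG is its
    functional atom).  Chain B holds one serine neighbor per planted
    (distance, angle) pair -- the neighbor's Calpha sits exactly at the
    planted distance from the site OG, and its CB/OG side chain is laid
    along a direction making exactly the planted angle with the
    substrate-direction vector.  Glycine neighbors (angle None) get a
    bare backbone.  Each planted ligand is a one-atom het group whose
    minimum distance to the site side chain equals the planted value.

    Returns the model plus a ground-truth table (kind, label, distance,
    angle).  Raises ``ValueError`` when the construction would place two
    atoms on top of each other.
    """
    rng = np.random.default_rng(spec.seed)
    ca_site = np.zeros(3)
    site = Residue(
        chain_id="A",
        seq_id=spec.site_seq_id,
        res_name="SER",
        atoms=_backbone(ca_site)
        + [
            Atom("CB", "C", ca_site + np.array([0.0, -0.5, 1.4])),
            Atom("OG", "O", ca_site + np.array([0.0, -0.8, 2.7])),
        ],
    )
    ref = site.atom("OG").coord  # site functional atom = reference point

    placed = [a.coord for a in site.atoms]

    def _collides(atoms: list[Atom], min_sep: float = 0.5) -> bool:
        coords = [a.coord for a in atoms]
        for i, c1 in enumerate(coords):
            for c2 in coords[i + 1:]:  # side chain may fold onto backbone
                if np.linalg.norm(c1 - c2) < min_sep:
                    return True
            for c in placed:
                if np.linalg.norm(c1 - c) < min_sep:
                    return True
        return False

    truth_rows = []
    neighbors: list[Residue] = []
    for i, (dist, theta) in enumerate(spec.neighbors):
        res = None
        for _ in range(64):  # re-draw the direction on atom collisions
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            ca_k = ref + dist * u
            s_k = ref - ca_k  # substrate-direction vector
            if theta is None:
                candidate = Residue("B", i + 1, "GLY", _backbone(ca_k))
            else:
                s_hat = s_k / np.linalg.norm(s_k)
                w = _perpendicular(s_hat)
                v_hat = (
                    np.cos(np.radians(theta)) * s_hat
                    + np.sin(np.radians(theta)) * w
                )
                candidate = Residue(
                    "B",
                    i + 1,
                    "SER",
                    _backbone(ca_k)
                    + [
                        Atom("CB", "C", ca_k + 1.5 * v_hat),
                        Atom("OG", "O", ca_k + 2.4 * v_hat),
                    ],
                )
            if not _collides(candidate.atoms):
                res = candidate
                break
        if res is None:
            raise ValueError(
                f"infeasible geometry: cannot place neighbor at {dist} A "
                "without overlapping atoms"
            )
        placed.extend(a.coord for a in res.atoms)
        neighbors.append(res)
        truth_rows.append(
            {
                "kind": "neighbor",
                "label": res.label(),
                "distance": dist,
                "angle": theta if theta is not None else np.nan,
            }
        )

    site_side = np.array([a.coord for a in site.sidechain_atoms()])
    ligands: list[Residue] = []
    for j, dist in enumerate(spec.ligand_distances):
        for _ in range(64):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = ref + dist * u
            d_all = np.linalg.norm(site_side - pos, axis=1)
            if abs(d_all.min() - dist) < 1e-9 and all(
                np.linalg.norm(pos - c) >= 0.5 for c in placed
            ):
                placed.append(pos)
                break
        else:
            raise ValueError(f"could not place ligand at {dist} A")
        lig = Residue(
            "L", 900 + j, "LIG", [Atom("C1", "C", pos, is_het=True)]
        )
        ligands.append(lig)
        truth_rows.append(
            {"kind": "ligand", "label": lig.label(), "distance": dist, "angle": np.nan}
        )

    model = StructureModel(
        pdb_id="toy1",
        resolution=spec.resolution,
        experiment="X-RAY DIFFRACTION",
        chains={"A": [site], "B": neighbors},
        het_residues=ligands,
    )
    _check_no_overlap(model)
    return model, pd.DataFrame(truth_rows)


def _check_no_overlap(model: StructureModel, min_sep: float = 0.4) -> None:
    coords = np.array(
        [
            a.coord
            for ch in model.chains.values()
            for r in ch
            for a in r.atoms
        ]
        + [a.coord for r in model.het_residues for a in r.atoms]
    )
    if len(coords) < 2:
        return
    from scipy.spatial.distance import pdist

    if pdist(coords).min() < min_sep:
        raise ValueError("infeasible geometry: overlapping atoms in fixture")


def toy_mapped_site(model: StructureModel, spec: FixtureSpec) -> MappedSite:
    """The MappedSite addressing the toy structure's substrate serine."""
    return MappedSite(
        site=SiteRecord("TOY1", 1, "S", "Phosphorylation"),
        pdb_id=model.pdb_id,
        chain_id="A",
        seq_id=spec.site_seq_id,
        icode="",
        peptide_span=(0, 1),
    )


def make_chain_structure(
    sequence: str,
    chain_id: str = "A",
    start_seq_id: int = 1,
    resolution: float = 2.0,
    pdb_id: str = "chn1",
    spacing: float = 3.8,
) -> StructureModel:
    """A single-chain structure whose residues carry the given sequence.

    Calphas are laid out on a loose helix at ~3.8 A spacing; each
    residue gets a backbone, a CB and its designated functional atom, so
    sequence-driven tests (peptide mapping, sequence extraction) operate
    on a structurally valid model.
    """
    residues = []
    for i, aa in enumerate(sequence.upper()):
        t = i * 0.6
        ca = np.array([6.0 * np.cos(t), 6.0 * np.sin(t), i * spacing * 0.4])
        res_name = ONE_TO_THREE.get(aa, "UNK")
        atoms = _backbone(ca)
        if aa != "G":
            direction = np.array([np.cos(t), np.sin(t), 0.3])
            direction /= np.linalg.norm(direction)
            atoms.append(Atom("CB", "C", ca + 1.5 * direction))
            fname = FUNCTIONAL_ATOMS.get(aa)
            if fname and fname != "CB":
                atoms.append(Atom(fname, _element_of(fname), ca + 2.6 * direction))
        residues.append(
            Residue(chain_id, start_seq_id + i, res_name, atoms)
        )
    return StructureModel(
        pdb_id=pdb_id,
        resolution=resolution,
        experiment="X-RAY DIFFRACTION",
        chains={chain_id: residues},
    )


def make_random_structure(
    n_residues: int, seed: int = 0, density: float = 0.01
) -> StructureModel:
    """A random blob of residues for oracle comparisons.

    Residue types are drawn uniformly from the 20 amino acids; Calphas
    are uniform in a cube sized so the point density is ``density``
    residues per cubic A; side chains point in random directions.  Not
    physically realistic -- intended for brute-force distance oracles.
    """
    rng = np.random.default_rng(seed)
    box = (n_residues / density) ** (1.0 / 3.0)
    residues = []
    for i in range(n_residues):
        aa = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
        ca = rng.uniform(0.0, box, size=3)
        atoms = _backbone(ca)
        if aa != "G":
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            atoms.append(Atom("CB", "C", ca + 1.5 * d))
            fname = FUNCTIONAL_ATOMS.get(aa)
            if fname and fname != "CB":
                atoms.append(Atom(fname, _element_of(fname), ca + 2.6 * d))
        residues.append(Residue("A", i + 1, ONE_TO_THREE[aa], atoms))
    return StructureModel(
        pdb_id="rnd1",
        resolution=1.8,
        experiment="X-RAY DIFFRACTION",
        chains={"A": residues},
    )


# ---------------------------------------------------------------------------
# synthetic proteome


def _window(seq: str, pos: int, n: int, pad: str = "-") -> str:
    """Independent window slicing used for manifest bookkeeping."""
    i = pos - 1
    left = seq[max(0, i - n): i]
    right = seq[i + 1: i + 1 + n]
    return pad * (n - len(left)) + left + seq[i] + right + pad * (n - len(right))


def _greedy_survivors(windows: list[str], threshold: float) -> list[int]:
    """Vectorized greedy redundancy scan used as the manifest oracle.

    Returns indices of cluster founders under the same contract as the
    benchmark clustering (input order, founder representatives, identity
    over the full window with pads counting as mismatches).
    """
    if not windows:
        return []
    width = len(windows[0])
    arr = np.frombuffer("".join(windows).encode(), dtype=np.uint8).reshape(
        len(windows), width
    )
    pad_code = ord("-")
    founders: list[int] = []
    for i in range(len(windows)):
        if founders:
            reps = arr[founders]
            ident = (
                ((reps == arr[i]) & (arr[i] != pad_code)).sum(axis=1) / width
            )
            if (ident >= threshold).any():
                continue
        founders.append(i)
    return founders


def make_synthetic_proteome(
    spec: FixtureSpec,
) -> tuple[dict[str, str], list[SiteRecord], dict]:
    """Random proteome with planted sites and injected duplicate windows.

    Sequences are drawn with the target residue at ``target_frequency``
    and the other 19 amino acids uniform.  ``n_sites`` target-residue
    positions across a subset of proteins are annotated as modified.
    ``n_cross_duplicates`` negative windows are made byte-identical to
    positive windows (they must be removed by the cross-set purge) and
    ``n_within_duplicates`` negative windows are duplicated elsewhere
    (they must collapse in within-set clustering).

    The manifest reports expected benchmark counts derived from the
    final sequences by an independent vectorized scan: raw
    positive/negative counts, post-clustering survivor counts and the
    post-purge negative count.
    """
    rng = np.random.default_rng(spec.seed)
    tr = spec.target_residue
    others = [aa for aa in AMINO_ACIDS if aa != tr]
    p_other = (1.0 - spec.target_frequency) / len(others)
    alphabet = list(others) + [tr]
    probs = [p_other] * len(others) + [spec.target_frequency]

    seqs: dict[str, list[str]] = {}
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seqs[f"SYN{i + 1:04d}"] = list(
            rng.choice(alphabet, size=length, p=probs)
        )

    # plant modification sites on a subset of proteins
    n_modified = max(1, int(round(spec.n_proteins * 0.6)))
    accessions = list(seqs)
    modified_accs = list(rng.choice(accessions, size=n_modified, replace=False))
    candidates = [
        (acc, pos)
        for acc in modified_accs
        for pos, aa in enumerate(seqs[acc], start=1)
        if aa == tr
    ]
    if len(candidates) < spec.n_sites:
        raise ValueError("not enough target residues to plant the requested sites")
    picked = rng.choice(len(candidates), size=spec.n_sites, replace=False)
    site_positions: dict[str, set[int]] = {}
    for idx in sorted(picked):
        acc, pos = candidates[idx]
        site_positions.setdefault(acc, set()).add(pos)

    n_w = spec.window_n
    used_spans: dict[str, list[tuple[int, int]]] = {acc: [] for acc in seqs}
    for acc, positions in site_positions.items():
        for pos in positions:
            used_spans[acc].append((pos - n_w - 1, pos + n_w))

    def _splice_copy(source_window: str) -> bool:
        """Overwrite a random interior span of a modified protein with
        source_window, avoiding planted sites and earlier splices."""
        for _ in range(200):
            acc = modified_accs[int(rng.integers(len(modified_accs)))]
            seq = seqs[acc]
            if len(seq) < 2 * n_w + 3:
                continue
            center = int(rng.integers(n_w + 1, len(seq) - n_w))  # 0-based
            lo, hi = center - n_w, center + n_w + 1
            if any(lo < e and s < hi for s, e in used_spans[acc]):
                continue
            seq[lo:hi] = list(source_window)
            used_spans[acc].append((lo, hi))
            return True
        return False

    # cross-set duplicates: copy a pad-free positive window onto an
    # unmodified center elsewhere
    interior_positives = [
        (acc, pos)
        for acc, positions in site_positions.items()
        for pos in positions
        if n_w < pos <= len(seqs[acc]) - n_w
    ]
    for _ in range(spec.n_cross_duplicates):
        acc, pos = interior_positives[int(rng.integers(len(interior_positives)))]
        w = "".join(seqs[acc][pos - 1 - n_w: pos + n_w])
        if not _splice_copy(w):
            raise ValueError("could not inject cross-set duplicate window")

    # within-set duplicates: duplicate an unmodified-center window
    for _ in range(spec.n_within_duplicates):
        for _ in range(200):
            acc = modified_accs[int(rng.integers(len(modified_accs)))]
            seq = seqs[acc]
            negs = [
                p
                for p, aa in enumerate(seq, start=1)
                if aa == tr
                and p not in site_positions.get(acc, set())
                and n_w < p <= len(seq) - n_w
                and not any(
                    p - n_w - 1 < e and s < p + n_w
                    for s, e in used_spans[acc]
                )
            ]
            if not negs:
                continue
            p = negs[int(rng.integers(len(negs)))]
            w = "".join(seq[p - 1 - n_w: p + n_w])
            if _splice_copy(w):
                break
        else:
            raise ValueError("could not inject within-set duplicate window")

    proteins = {acc: "".join(seq) for acc, seq in seqs.items()}
    sites = [
        SiteRecord(acc, pos, tr, spec.ptm_type)
        for acc in sorted(site_positions)
        for pos in sorted(site_positions[acc])
    ]

    # manifest bookkeeping on the final sequences (independent scan)
    pos_windows, neg_windows = [], []
    for acc in sorted(site_positions):
        seq = proteins[acc]
        planted = site_positions[acc]
        for pos in sorted(planted):
            pos_windows.append(_window(seq, pos, n_w))
        for p, aa in enumerate(seq, start=1):
            if aa == tr and p not in planted:
                neg_windows.append(_window(seq, p, n_w))
    pos_nr = [pos_windows[i] for i in _greedy_survivors(pos_windows, spec.identity_threshold)]
    neg_nr = [neg_windows[i] for i in _greedy_survivors(neg_windows, spec.identity_threshold)]
    pos_set = set(pos_nr)
    neg_final = [w for w in neg_nr if w not in pos_set]

    manifest = {
        "seed": spec.seed,
        "target_residue": tr,
        "ptm_type": spec.ptm_type,
        "window_n": n_w,
        "identity_threshold": spec.identity_threshold,
        "n_proteins": spec.n_proteins,
        "n_modified_proteins": len(site_positions),
        "positives_raw": len(pos_windows),
        "negatives_raw": len(neg_windows),
        "positives_nonredundant": len(pos_nr),
        "negatives_nonredundant": len(neg_nr),
        "negatives_after_purge": len(neg_final),
    }
    return proteins, sites, manifest


def write_proteome(
    proteins: dict[str, str],
    sites: list[SiteRecord],
    manifest: dict,
    out_dir: str | Path,
) -> None:
    """Write FASTA, site TSV and manifest JSON for a synthetic proteome."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "proteome.fasta", "w") as fh:
        for acc, seq in proteins.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")
    rows = [
        {
            "accession": s.accession,
            "position": s.position,
            "residue": s.residue,
            "ptm_type": s.ptm_type,
            "pubmed_ids": ";".join(s.evidence),
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(out / "sites.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
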