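"""Structure, sequence and site-table I/O plus the core data model.

PDB files are parsed with :mod:`gemmi` and converted into a small,
explicit data model (:class:`Atom`, :class:`Residue`,
:class:`StructureModel`) that the geometry, surface and ligand modules
operate on.  Only the first model of a multi-model file is retained, and
alternate locations are resolved at parse time so that downstream code
never sees two atoms with the same name in one residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "SiteRecord",
    "StructioError",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "chain_sequence",
    "read_fasta",
    "read_site_table",
    "THREE_TO_ONE",
]


class StructioError(ValueError):
    """Base error for structure/sequence/site-table I/O."""


class PDBParseError(StructioError):
    """Raised when a PDB file cannot be parsed."""


#: Standard 20 amino acids, 3-letter -> 1-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Backbone heavy-atom names (used to tell side chain from main chain).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Atom:
    """A heavy atom with crystallographic coordinates in angstroms."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_het: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructioError(
                f"atom {self.name!r}: coord must be 3 finite components"
            )
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructioError(
                f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]"
            )


@dataclass
class Residue:
    """One residue of a chain, addressed by author numbering.

    ``seq_id`` is the author residue number as written in the coordinate
    file (the numbering users see, e.g. "Ser338"), with ``icode`` the
    insertion code or empty string.
    """

    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        """Return the atom with the given name, or None."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        """1-letter code; 'X' for non-standard residues."""
        return THREE_TO_ONE.get(self.res_name, "X")

    @property
    def is_standard(self) -> bool:
        return self.res_name in THREE_TO_ONE

    def sidechain_atoms(self) -> list[Atom]:
        """Heavy atoms that are not part of the backbone."""
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    def label(self) -> str:
        return f"{self.chain_id}:{self.res_name}{self.seq_id}{self.icode}".rstrip()


@dataclass
class StructureModel:
    """A parsed 3D structure: chains of residues plus het groups.

    ``chains`` maps chain id to polymer residues in file order.
    ``het_residues`` holds all heteroatom groups (waters, ions, ligands);
    the :mod:`ptmstructkit.drugsite` module partitions them into ligand
    groups.  ``resolution`` is in angstroms or None when the file carries
    no REMARK 2 record.
    """

    pdb_id: str = ""
    resolution: float | None = None
    experiment: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    het_residues: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise StructioError(
                f"chain {chain_id!r} not found; have {sorted(self.chains)}"
            )
        return self.chains[chain_id]

    def find_residue(self, chain_id: str, seq_id: int, icode: str = "") -> Residue:
        for res in self.chain(chain_id):
            if res.seq_id == seq_id and res.icode == icode:
                return res
        raise StructioError(
            f"residue {seq_id}{icode} not found in chain {chain_id!r}"
        )


@dataclass(frozen=True)
class SiteRecord:
    """An experimentally observed PTM site on a protein sequence.

    ``position`` is 1-based; ``residue`` is the 1-letter code of the
    modified amino acid; ``evidence`` lists supporting PubMed ids.
    """

    accession: str
    position: int
    residue: str
    ptm_type: str
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise StructioError(
                f"site {self.accession}: position must be >= 1, got {self.position}"
            )


def _resolve_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by
    alphabetically first altloc code."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in raw_atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        resolved.append(best)
    return resolved


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    """Amino-acid residues (including HETATM ones like MSE) belong to the
    polymer; waters and other het groups go to the ligand store."""
    if res.name == "HOH":
        return False
    if res.het_flag != "H":
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


def read_pdb(path: str | Path, altloc_policy: str = "highest_occupancy") -> StructureModel:
    """Parse a PDB-format file into a :class:`StructureModel`.

    Only the first model is kept.  Alternate locations are resolved per
    ``altloc_policy`` ("highest_occupancy", the only supported policy:
    the highest-occupancy conformer wins, ties broken by alphabetically
    first altloc).  Waters and non-amino-acid HETATM groups are routed to
    ``het_residues``; resolution is read from REMARK 2 when present.

    Raises :class:`PDBParseError` on malformed or empty input.
    """
    if altloc_policy != "highest_occupancy":
        raise StructioError(f"unknown altloc policy {altloc_policy!r}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PDBParseError(f"{path}: empty file")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line number
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no coordinate records")

    # the HEADER idCode when present, otherwise the file stem
    first = text.splitlines()[0]
    header_id = first[62:66].strip() if first.startswith("HEADER") else ""
    model = StructureModel(
        pdb_id=header_id.lower() or path.stem.lower(),
        resolution=st.resolution if st.resolution > 0 else None,
        experiment=dict(st.info.items()).get("_exptl.method", ""),
    )
    gmodel = st[0]
    for gchain in gmodel:
        for gres in gchain:
            raw = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coord=np.array(a.pos.tolist(), dtype=float),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc != "\0" else "",
                    is_het=gres.het_flag == "H",
                )
                for a in gres
            ]
            res = Residue(
                chain_id=gchain.name,
                seq_id=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                res_name=gres.name,
                atoms=_resolve_altlocs(raw),
            )
            if _is_polymer_residue(gres):
                model.chains.setdefault(gchain.name, []).append(res)
            else:
                model.het_residues.append(res)
    if not model.chains and not model.het_residues:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` back to PDB format (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.pdb_id.upper()
    if model.resolution is not None:
        st.resolution = model.resolution
    if model.experiment:
        st.info["_exptl.method"] = model.experiment
    gmodel = gemmi.Model("1")

    def add_residue(gchain: gemmi.Chain, res: Residue, het: bool) -> None:
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
        gres.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = a.occupancy
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        gchain.add_residue(gres)

    het_by_chain: dict[str, list[Residue]] = {}
    for res in model.het_residues:
        het_by_chain.setdefault(res.chain_id, []).append(res)
    chain_ids = list(model.chains) + [c for c in het_by_chain if c not in model.chains]
    for cid in chain_ids:
        gchain = gemmi.Chain(cid)
        for res in model.chains.get(cid, []):
            add_residue(gchain, res, het=any(a.is_het for a in res.atoms))
        for res in het_by_chain.get(cid, []):
            add_residue(gchain, res, het=True)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def chain_sequence(
    model: StructureModel, chain_id: str
) -> tuple[str, list[tuple[int, str]]]:
    """Derive the 1-letter sequence of a chain from its resolved residues.

    Returns ``(sequence, index_map)`` where ``index_map[i]`` is the
    ``(seq_id, icode)`` author numbering of sequence position ``i``
    (0-based).  Non-standard residues are rendered as 'X'.  The sequence
    reflects residues actually present in the coordinate records, which
    is what peptide-to-structure mapping at 100% identity requires.
    """
    residues = model.chain(chain_id)
    seq = "".join(res.one_letter for res in residues)
    index_map = [(res.seq_id, res.icode) for res in residues]
    return seq, index_map


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an accession -> sequence map.

    The accession is the first whitespace-delimited token of the header.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seqs[record.id] = str(record.seq).upper()
    if not seqs:
        raise StructioError(f"{path}: no FASTA records")
    return seqs


def read_site_table(
    path: str | Path, sequences: dict[str, str] | None = None
) -> list[SiteRecord]:
    """Read a PTM site table (TSV) into validated :class:`SiteRecord`s.

    Expected columns: ``accession``, ``position`` (1-based), ``residue``
    (1-letter), ``ptm_type`` and optionally ``pubmed_ids``
    (semicolon-separated).  When ``sequences`` is supplied, rows whose
    residue letter disagrees with the sequence at that position are
    dropped with a warning listing the offending row numbers, mirroring
    the removal of peptides that cannot be located on their protein.
    Duplicate (accession, position, ptm_type) rows are collapsed with a
    warning.  Positions < 1 are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "position", "residue", "ptm_type"}
    missing = required - set(df.columns)
    if missing:
        raise StructioError(f"{path}: missing columns {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    bad_pos = df.index[df["position"] < 1].tolist()
    if bad_pos:
        raise StructioError(
            f"{path}: non-positive positions at rows {[i + 2 for i in bad_pos]}"
        )

    dups = df.duplicated(subset=["accession", "position", "ptm_type"], keep="first")
    if dups.any():
        warnings.warn(
            f"{path}: collapsed {int(dups.sum())} duplicate site rows",
            stacklevel=2,
        )
        df = df[~dups]

    records: list[SiteRecord] = []
    rejected_rows: list[int] = []
    for idx, row in df.iterrows():
        acc, pos, res = row["accession"], int(row["position"]), row["residue"].upper()
        if sequences is not None and acc in sequences:
            seq = sequences[acc]
            if pos > len(seq) or seq[pos - 1] != res:
                rejected_rows.append(idx + 2)  # 1-based, counting the header
                continue
        pubmed = row.get("pubmed_ids")
        evidence = (
            tuple(p for p in str(pubmed).split(";") if p and p != "nan")
            if pd.notna(pubmed)
            else ()
        )
        records.append(
            SiteRecord(
                accession=acc,
                position=pos,
                residue=res,
                ptm_type=row["ptm_type"],
                evidence=evidence,
            )
        )
    if rejected_rows:
        warnings.warn(
            f"{path}: rejected {len(rejected_rows)} rows with residue/sequence "
            f"mismatch (rows {rejected_rows})",
            stacklevel=2,
        )
    return records
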