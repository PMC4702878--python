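"""Ligand proximity of PTM substrate sites.

A PTM site is drug-binding-associated when its side chain lies within
10 A of a bound ligand.  Het groups are partitioned into ligand groups
by (chemical component code, chain, residue number); waters and a
configurable list of crystallization ions/solvents are excluded.
Distances are heavy-atom minima: the minimum over all (site side-chain
atom, ligand heavy atom) pairs, with the Calpha as fallback for glycine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ptmstructkit.mapping import MappedSite
from ptmstructkit.structio import Atom, StructureModel

__all__ = [
    "DEFAULT_EXCLUDED_HET",
    "LigandGroup",
    "LigandContact",
    "extract_ligands",
    "screen_drug_proximity",
]

#: Chemical component codes excluded from ligand extraction by default:
#: water plus common crystallization ions, buffers and cryoprotectants.
DEFAULT_EXCLUDED_HET = frozenset({
    "HOH", "DOD", "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "FE2",
    "NI", "CU", "CO", "CD", "BR", "IOD", "SO4", "PO4", "NO3", "ACT",
    "FMT", "GOL", "EDO", "PEG", "PGE", "PG4", "MPD", "DMS", "TRS",
    "BME", "MES", "EPE", "IMD", "AZI", "SCN",
})

DEFAULT_CUTOFF = 10.0


@dataclass
class LigandGroup:
    """One bound chemical group: a het residue that is not water/solvent."""

    het_code: str
    chain_id: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    annotation: str = ""

    def label(self) -> str:
        return f"{self.chain_id}:{self.het_code}{self.seq_id}"

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if a.element.upper() not in ("H", "D")]
        return np.array(coords) if coords else np.empty((0, 3))


@dataclass
class LigandContact:
    """Minimum distance between a site's side chain and one ligand."""

    ligand: LigandGroup
    min_distance: float
    within_cutoff: bool


def extract_ligands(
    model: StructureModel,
    exclude: frozenset[str] | set[str] | None = None,
    annotations: dict[str, str] | None = None,
) -> list[LigandGroup]:
    """Partition the model's het residues into ligand groups.

    Groups are keyed by (het code, chain, residue number).  Codes in
    ``exclude`` (default :data:`DEFAULT_EXCLUDED_HET`) are dropped.
    ``annotations`` optionally maps het codes to user-supplied drug
    labels (e.g. DrugBank names).
    """
    exclude = DEFAULT_EXCLUDED_HET if exclude is None else frozenset(exclude)
    annotations = annotations or {}
    groups: dict[tuple[str, str, int], LigandGroup] = {}
    for res in model.het_residues:
        if res.res_name in exclude:
            continue
        key = (res.res_name, res.chain_id, res.seq_id)
        group = groups.get(key)
        if group is None:
            group = LigandGroup(
                het_code=res.res_name,
                chain_id=res.chain_id,
                seq_id=res.seq_id,
                annotation=annotations.get(res.res_name, ""),
            )
            groups[key] = group
        group.atoms.extend(res.atoms)
    return list(groups.values())


def screen_drug_proximity(
    model: StructureModel,
    mapped: MappedSite,
    cutoff: float = DEFAULT_CUTOFF,
    exclude: frozenset[str] | set[str] | None = None,
    annotations: dict[str, str] | None = None,
) -> list[LigandContact]:
    """Minimum side-chain-to-ligand distance for every ligand in the model.

    The site contributes its side-chain heavy atoms (Calpha fallback for
    glycine or stripped side chains); each ligand contributes its heavy
    atoms.  A contact is ``within_cutoff`` when the minimum distance is
    at or below ``cutoff`` (default 10 A).  Contacts are sorted by
    ascending distance.  No ligands yields an empty list.
    """
    site_residue = model.find_residue(mapped.chain_id, mapped.seq_id, mapped.icode)
    side = site_residue.sidechain_atoms()
    if not side:
        ca = site_residue.atom("CA")
        if ca is None:
            raise ValueError(f"{site_residue.label()}: no side chain and no CA")
        side = [ca]
    site_coords = np.array([a.coord for a in side])

    contacts = []
    for ligand in extract_ligands(model, exclude=exclude, annotations=annotations):
        lig_coords = ligand.heavy_coords()
        if lig_coords.shape[0] == 0:
            continue
        dmin = float(cdist(site_coords, lig_coords).min())
        contacts.append(
            LigandContact(
                ligand=ligand,
                min_distance=dmin,
                within_cutoff=dmin <= cutoff,
            )
        )
    contacts.sort(key=lambda c: c.min_distance)
    return contacts
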