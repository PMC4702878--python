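"""Solvent-accessible surface area by the Shrake-Rupley method.

Each heavy atom is expanded by the probe radius (1.4 A water probe) and
sampled with a deterministic golden-spiral point set; a sample point is
accessible when it falls outside every other expanded sphere.  The
atom's SASA is the accessible fraction of its expanded-sphere area.
Relative per-residue accessibility divides the residue SASA by a
Gly-X-Gly extended-conformation maximum (theoretical values of Tien et
al. 2013), and may slightly exceed 1 for unusually extended residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ptmstructkit.structio import Residue, StructureModel

__all__ = [
    "SasaResult",
    "sphere_points",
    "compute_sasa",
    "VDW_RADII",
    "MAX_ACC",
]

#: Van der Waals radii (A) for the elements that dominate protein heavy
#: atoms; anything else falls back to ``default_radius``.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

#: Theoretical maximum accessibility (A^2) per residue type in a
#: Gly-X-Gly tripeptide (Tien et al. 2013, theoretical column).
MAX_ACC: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent accessibility.

    ``per_atom[(residue_key, atom_name)]`` and ``per_residue[residue_key]``
    are in A^2, with ``residue_key = (chain_id, seq_id, icode)``.
    ``relative`` is the per-residue fraction of the residue-type maximum
    (NaN for residue types without a tabulated maximum).
    """

    per_atom: dict[tuple[tuple[str, int, str], str], float]
    per_residue: dict[tuple[str, int, str], float]
    relative: dict[tuple[str, int, str], float]

    def residue_sasa(self, chain_id: str, seq_id: int, icode: str = "") -> float:
        return self.per_residue[(chain_id, seq_id, icode)]


def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors via the golden-spiral construction.

    Deterministic for a given ``n``; all rows have unit norm.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    # offset by 0.5 avoids placing points exactly at the poles
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _collect_atoms(
    model: StructureModel, include_het: bool
) -> list[tuple[Residue, str, np.ndarray, str]]:
    atoms = []
    residues: list[Residue] = [r for ch in model.chains.values() for r in ch]
    if include_het:
        residues += model.het_residues
    for res in residues:
        for a in res.atoms:
            if a.element.upper() in ("H", "D"):
                continue
            atoms.append((res, a.name, a.coord, a.element.upper()))
    return atoms


def compute_sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii_table: dict[str, float] | None = None,
    default_radius: float = 1.7,
    include_het: bool = False,
) -> SasaResult:
    """Shrake-Rupley SASA for every heavy atom of the model.

    Hydrogens are ignored.  ``radii_table`` maps element symbols to van
    der Waals radii (defaults to :data:`VDW_RADII`); unknown elements use
    ``default_radius`` with a warning.  Het groups are excluded from both
    the surface and the occlusion set unless ``include_het`` is True.
    """
    radii_table = radii_table or VDW_RADII
    entries = _collect_atoms(model, include_het)
    if not entries:
        raise ValueError("model has no heavy atoms")

    coords = np.array([e[2] for e in entries])
    radii = np.empty(len(entries))
    warned: set[str] = set()
    for i, (_, _, _, elem) in enumerate(entries):
        if elem in radii_table:
            radii[i] = radii_table[elem]
        else:
            if elem not in warned:
                warnings.warn(
                    f"no vdW radius for element {elem!r}; using "
                    f"{default_radius} A",
                    stacklevel=2,
                )
                warned.add(elem)
            radii[i] = default_radius
    expanded = radii + probe

    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom_area = np.zeros(len(entries))
    for i in range(len(entries)):
        pts = coords[i] + expanded[i] * unit
        # candidate occluders: spheres that could reach any sample point
        neighbor_idx = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        per_atom_area[i] = frac * 4.0 * np.pi * expanded[i] ** 2

    per_atom: dict[tuple[tuple[str, int, str], str], float] = {}
    per_residue: dict[tuple[str, int, str], float] = {}
    res_names: dict[tuple[str, int, str], str] = {}
    for (res, name, _, _), area in zip(entries, per_atom_area):
        key = (res.chain_id, res.seq_id, res.icode)
        per_atom[(key, name)] = float(area)
        per_residue[key] = per_residue.get(key, 0.0) + float(area)
        res_names[key] = res.res_name
    relative = {
        key: (sasa / MAX_ACC[res_names[key]] if res_names[key] in MAX_ACC else float("nan"))
        for key, sasa in per_residue.items()
    }
    for key, rel in relative.items():
        if rel > 1.2:
            warnings.warn(
                f"relative accessibility {rel:.2f} > 1.2 for residue {key}",
                stacklevel=2,
            )
    return SasaResult(per_atom=per_atom, per_residue=per_residue, relative=relative)
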