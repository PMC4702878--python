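"""Side-chain orientation geometry and spatial context of substrate sites.

For a substrate residue *p* and a spatially neighboring residue *k*, the
substrate-direction vector is

    S_k = X_p(modified atom) - X_k(Calpha)

and the side-chain direction of the neighbor is

    V_k = X_k(functional atom) - X_k(Calpha),

where the functional atom is the designated terminal side-chain atom of
the residue type (OG for Ser, NZ for Lys, ...).  The orientation angle

    theta_k = arccos( S_k . V_k / (|S_k| |V_k|) )

measures whether the neighbor's side chain points toward the substrate;
a neighbor with theta_k < 80 degrees is classified as a functional
residue with respect to the modification site.

This module also enumerates sequential neighbors (positions -6..+6 by
default) and spatial neighbors (Calpha within 10 A of the site's
side-chain reference point by default), and accumulates the radial
cumulative amino-acid composition on a 2-10 A radius grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ptmstructkit.mapping import MappedSite
from ptmstructkit.structio import Atom, Residue, StructureModel

__all__ = [
    "FUNCTIONAL_ATOMS",
    "AMINO_ACIDS",
    "GeometryError",
    "OrientationResult",
    "NeighborRecord",
    "RadialProfile",
    "functional_atom",
    "substrate_vector",
    "sidechain_vector",
    "orientation_angle",
    "classify_functional",
    "spatial_neighbors",
    "sequential_neighbors",
    "radial_composition",
]

#: Alphabetical 1-letter amino-acid order used for composition vectors.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Designated side-chain functional atom per residue type (1-letter code).
#: Glycine has no side chain and is deliberately absent.
FUNCTIONAL_ATOMS: dict[str, str] = {
    "S": "OG", "T": "OG1", "Y": "OH", "C": "SG", "K": "NZ",
    "R": "CZ", "N": "ND2", "Q": "NE2", "D": "CG", "E": "CD",
    "H": "NE2", "W": "NE1", "F": "CZ", "M": "SD", "L": "CG",
    "I": "CD1", "V": "CB", "A": "CB", "P": "CG",
}

#: Angle below which a neighbor's side chain counts as functional (deg).
FUNCTIONAL_ANGLE_THRESHOLD = 80.0

#: Default spatial-neighbor cutoff (A) and sequence window.
DEFAULT_CUTOFF = 10.0
DEFAULT_WINDOW = 6

#: Default radius grid for radial composition (A).
DEFAULT_RADII = tuple(float(r) for r in range(2, 11))


class GeometryError(ValueError):
    """Raised on degenerate geometric input."""


@dataclass(frozen=True)
class OrientationResult:
    """Orientation of one neighbor side chain relative to the site.

    ``S`` and ``V`` are the substrate-direction and side-chain vectors in
    angstroms; ``theta_deg`` their angle in [0, 180]; ``functional`` is
    True when the angle falls below the functional threshold.
    ``fallback_atom`` flags that the designated functional atom was
    unresolved and the outermost side-chain atom was used instead.
    """

    S: np.ndarray
    V: np.ndarray
    theta_deg: float
    functional: bool
    fallback_atom: bool = False


@dataclass(frozen=True)
class NeighborRecord:
    """A sequentially or spatially neighboring residue of a site."""

    residue: Residue | None
    kind: str  # "sequential" | "spatial"
    seq_offset: int | None = None
    distance: float | None = None
    orientation: OrientationResult | None = None
    aa: str = ""


@dataclass
class RadialProfile:
    """Cumulative amino-acid composition on a radius grid around a site.

    ``cumulative_counts[i]`` is the 20-vector (order :data:`AMINO_ACIDS`)
    of residues whose Calpha lies within ``radii[i]`` of the reference
    point; counts are cumulative, hence non-decreasing in the radius.
    ``cumulative_freqs`` are the corresponding relative frequencies; a
    shell with zero residues yields a NaN frequency vector.
    ``nonstandard_counts`` tracks residues outside the standard 20.
    """

    radii: np.ndarray
    cumulative_counts: np.ndarray  # (n_radii, 20) ints
    cumulative_freqs: np.ndarray  # (n_radii, 20) floats, NaN when empty
    nonstandard_counts: np.ndarray  # (n_radii,) ints

    def modal_amino_acid(self, radius_index: int = -1) -> str:
        """Most abundant amino acid within the given radius (ties: first
        in alphabetical order)."""
        counts = self.cumulative_counts[radius_index]
        if counts.sum() == 0:
            raise GeometryError("no residues within the requested radius")
        return AMINO_ACIDS[int(np.argmax(counts))]


def functional_atom(residue: Residue) -> tuple[Atom | None, bool]:
    """The designated side-chain functional atom of ``residue``.

    Returns ``(atom, used_fallback)``.  Glycine (no side chain) and
    residues with no resolved side-chain atoms yield ``(None, False)``.
    When the designated atom is unresolved, the outermost resolved
    side-chain atom (farthest from Calpha) is returned with the fallback
    flag set.
    """
    code = residue.one_letter
    if code == "G":
        return None, False
    name = FUNCTIONAL_ATOMS.get(code)
    if name is not None:
        atom = residue.atom(name)
        if atom is not None:
            return atom, False
    side = residue.sidechain_atoms()
    if not side:
        return None, False
    ca = residue.atom("CA")
    if ca is None:
        return side[-1], True
    outermost = max(side, key=lambda a: float(np.linalg.norm(a.coord - ca.coord)))
    return outermost, True


def _site_modified_atom(residue: Residue) -> tuple[Atom, bool]:
    """The substrate's modified atom: its functional atom, with Calpha as
    the glycine/unresolved fallback."""
    atom, fallback = functional_atom(residue)
    if atom is not None:
        return atom, fallback
    ca = residue.atom("CA")
    if ca is None:
        raise GeometryError(f"{residue.label()}: no side-chain atom and no CA")
    return ca, True


def substrate_vector(site_residue: Residue, neighbor: Residue) -> np.ndarray:
    """S_k: from the neighbor's Calpha to the site's modified atom (A)."""
    ca = neighbor.atom("CA")
    if ca is None:
        raise GeometryError(f"{neighbor.label()}: missing CA atom")
    modified, _ = _site_modified_atom(site_residue)
    return modified.coord - ca.coord


def sidechain_vector(residue: Residue) -> np.ndarray | None:
    """V_k: from the residue's Calpha to its functional atom (A).

    Returns None for glycine or when no side-chain atom is resolved.
    Raises :class:`GeometryError` when the two atoms coincide.
    """
    atom, _ = functional_atom(residue)
    if atom is None:
        return None
    ca = residue.atom("CA")
    if ca is None:
        raise GeometryError(f"{residue.label()}: missing CA atom")
    v = atom.coord - ca.coord
    if np.linalg.norm(v) == 0.0:
        raise GeometryError(
            f"{residue.label()}: functional atom coincides with CA"
        )
    return v


def orientation_angle(S: np.ndarray, V: np.ndarray) -> float:
    """Angle between S and V in degrees, in [0, 180].

    The normalized dot product is clamped to [-1, 1] so numerically
    parallel vectors do not fall outside the arccos domain.
    """
    S = np.asarray(S, dtype=float)
    V = np.asarray(V, dtype=float)
    ns, nv = np.linalg.norm(S), np.linalg.norm(V)
    if ns == 0.0 or nv == 0.0:
        raise GeometryError("orientation angle undefined for zero vector")
    cosang = np.clip(np.dot(S, V) / (ns * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def classify_functional(
    theta_deg: float, threshold: float = FUNCTIONAL_ANGLE_THRESHOLD
) -> bool:
    """True iff the angle is strictly below the functional threshold."""
    if not 0.0 <= theta_deg <= 180.0:
        raise GeometryError(f"theta {theta_deg} outside [0, 180]")
    return theta_deg < threshold


def _orientation_for(
    site_residue: Residue, neighbor: Residue
) -> OrientationResult | None:
    """Full orientation record for a neighbor, or None when the neighbor
    has no usable side-chain vector (glycine)."""
    try:
        V = sidechain_vector(neighbor)
    except GeometryError:
        return None
    if V is None:
        return None
    _, fallback = functional_atom(neighbor)
    S = substrate_vector(site_residue, neighbor)
    if np.linalg.norm(S) == 0.0:
        return None
    theta = orientation_angle(S, V)
    return OrientationResult(
        S=S,
        V=V,
        theta_deg=theta,
        functional=classify_functional(theta),
        fallback_atom=fallback,
    )


def _reference_points(site_residue: Residue, reference: str) -> np.ndarray:
    """Coordinates defining the site's reference for neighbor distances."""
    if reference == "functional_atom":
        atom, _ = _site_modified_atom(site_residue)
        return atom.coord[None, :]
    if reference == "calpha":
        ca = site_residue.atom("CA")
        if ca is None:
            raise GeometryError(
                f"{site_residue.label()}: no CA atom; cannot use reference="
                "'calpha'"
            )
        return ca.coord[None, :]
    if reference == "any_sidechain_atom":
        side = site_residue.sidechain_atoms()
        if not side:
            raise GeometryError(
                f"{site_residue.label()}: no side-chain atoms; try "
                "reference='calpha'"
            )
        return np.array([a.coord for a in side])
    raise GeometryError(f"unknown reference {reference!r}")


def _neighbor_distances(
    model: StructureModel, site_residue: Residue, reference: str
) -> list[tuple[Residue, float]]:
    """(residue, distance) for every other residue with a Calpha, where
    distance is from the neighbor's Calpha to the site reference point
    (minimum over reference atoms)."""
    refs = _reference_points(site_residue, reference)
    cas, residues = [], []
    for chain_residues in model.chains.values():
        for res in chain_residues:
            if res is site_residue:
                continue
            ca = res.atom("CA")
            if ca is None:
                continue
            residues.append(res)
            cas.append(ca.coord)
    if not residues:
        return []
    dists = cdist(np.array(cas), refs).min(axis=1)
    return list(zip(residues, dists.tolist()))


def spatial_neighbors(
    model: StructureModel,
    mapped: MappedSite,
    cutoff: float = DEFAULT_CUTOFF,
    reference: str = "functional_atom",
) -> list[NeighborRecord]:
    """Residues whose Calpha lies within ``cutoff`` of the site reference.

    The reference point is, by default, the site's modified (functional)
    atom; ``reference='calpha'`` and ``'any_sidechain_atom'`` select the
    site Calpha or the nearest site side-chain atom instead.  The site
    residue itself is excluded.  Distances at exactly the cutoff are
    included.  Records are sorted by ascending distance, ties broken by
    (chain id, residue number), and carry an orientation result whenever
    the neighbor has a side chain.
    """
    site_residue = model.find_residue(mapped.chain_id, mapped.seq_id, mapped.icode)
    pairs = [
        (res, d)
        for res, d in _neighbor_distances(model, site_residue, reference)
        if d <= cutoff
    ]
    pairs.sort(key=lambda rd: (rd[1], rd[0].chain_id, rd[0].seq_id, rd[0].icode))
    return [
        NeighborRecord(
            residue=res,
            kind="spatial",
            distance=d,
            orientation=_orientation_for(site_residue, res),
            aa=res.one_letter,
        )
        for res, d in pairs
    ]


def sequential_neighbors(
    sequence: str, position: int, window: int = DEFAULT_WINDOW
) -> list[NeighborRecord]:
    """Sequence neighbors at offsets -window..-1 and +1..+window.

    ``position`` is 1-based.  Offsets falling outside the sequence are
    truncated, so a terminal site yields fewer than 2*window records.
    """
    if not 1 <= position <= len(sequence):
        raise GeometryError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    records = []
    for off in range(-window, window + 1):
        if off == 0:
            continue
        pos = position + off
        if 1 <= pos <= len(sequence):
            records.append(
                NeighborRecord(
                    residue=None,
                    kind="sequential",
                    seq_offset=off,
                    aa=sequence[pos - 1],
                )
            )
    return records


def radial_composition(
    model: StructureModel,
    mapped: MappedSite,
    radii: tuple[float, ...] = DEFAULT_RADII,
    reference: str = "functional_atom",
) -> RadialProfile:
    """Cumulative 20-amino-acid composition around a site.

    For each radius r in ``radii`` (default 2, 3, ..., 10 A), counts the
    residues whose Calpha lies within r of the site reference point
    (site excluded) by 1-letter code, and normalizes to relative
    frequencies.  Non-standard residues are excluded from the 20-vector
    and tallied separately.
    """
    site_residue = model.find_residue(mapped.chain_id, mapped.seq_id, mapped.icode)
    pairs = _neighbor_distances(model, site_residue, reference)
    radii_arr = np.asarray(sorted(radii), dtype=float)
    counts = np.zeros((len(radii_arr), len(AMINO_ACIDS)), dtype=int)
    nonstandard = np.zeros(len(radii_arr), dtype=int)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for res, d in pairs:
        within = radii_arr >= d
        if not within.any():
            continue
        idx = aa_index.get(res.one_letter)
        if idx is None:
            nonstandard[within] += 1
        else:
            counts[within, idx] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), np.nan)
    return RadialProfile(
        radii=radii_arr,
        cumulative_counts=counts,
        cumulative_freqs=freqs,
        nonstandard_counts=nonstandard,
    )
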