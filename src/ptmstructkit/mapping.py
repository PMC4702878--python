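"""Localize PTM peptides on structure chains at 100% sequence identity.

A modified peptide is placed on a structure only when it matches the
chain's ATOM-derived sequence exactly; no mismatches are tolerated.
Ambiguous placements (the peptide occurs more than once across the
scanned chains) are reported as errors rather than silently resolved,
and structures whose resolution does not beat the configured threshold
are rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass

from ptmstructkit.structio import SiteRecord, StructureModel, chain_sequence

__all__ = [
    "MappedSite",
    "MappingError",
    "AmbiguousMappingError",
    "ResolutionError",
    "locate_peptide",
    "map_site",
]

#: Default resolution cutoff in angstroms; structures must be strictly
#: better (smaller) to qualify.
DEFAULT_MAX_RESOLUTION = 2.5


class MappingError(ValueError):
    """A site could not be placed on the structure."""


class AmbiguousMappingError(MappingError):
    """The peptide matches at more than one location."""

    def __init__(self, candidates: list[tuple[str, int]]):
        self.candidates = candidates
        locs = ", ".join(f"{c}:{o}" for c, o in candidates)
        super().__init__(f"ambiguous peptide placement; candidates at {locs}")


class ResolutionError(MappingError):
    """The structure fails the resolution filter."""


@dataclass(frozen=True)
class MappedSite:
    """A PTM site localized on a structure chain.

    ``seq_id``/``icode`` give the author numbering of the substrate
    residue; ``peptide_span`` is the 0-based half-open interval of the
    matched peptide on the chain sequence.
    """

    site: SiteRecord
    pdb_id: str
    chain_id: str
    seq_id: int
    icode: str
    peptide_span: tuple[int, int]


def locate_peptide(peptide: str, chain_seq: str) -> list[int]:
    """All exact-substring offsets of ``peptide`` in ``chain_seq``, ascending.

    Overlapping occurrences are all reported.  An empty result means the
    peptide has no 100%-identity match on the chain.
    """
    if not peptide:
        raise MappingError("peptide must be non-empty")
    offsets = []
    start = 0
    while True:
        idx = chain_seq.find(peptide, start)
        if idx < 0:
            break
        offsets.append(idx)
        start = idx + 1
    return offsets


def map_site(
    site: SiteRecord,
    peptide: str,
    offset_in_peptide: int,
    model: StructureModel,
    max_resolution: float | None = DEFAULT_MAX_RESOLUTION,
) -> MappedSite:
    """Place ``site`` on ``model`` by exact peptide match across all chains.

    ``offset_in_peptide`` is the 0-based index of the modified residue
    within ``peptide``.  With the default ``max_resolution`` of 2.5 A,
    models lacking a resolution or at 2.5 A or worse are rejected; pass
    ``max_resolution=None`` to disable the filter.

    Raises :class:`ResolutionError`, :class:`AmbiguousMappingError` or
    :class:`MappingError` when the site cannot be placed uniquely.
    """
    if not 0 <= offset_in_peptide < len(peptide):
        raise MappingError(
            f"offset_in_peptide {offset_in_peptide} outside peptide of "
            f"length {len(peptide)}"
        )
    if peptide[offset_in_peptide] != site.residue:
        raise MappingError(
            f"peptide has {peptide[offset_in_peptide]!r} at the site offset "
            f"but the site record says {site.residue!r}"
        )
    if max_resolution is not None:
        if model.resolution is None:
            raise ResolutionError(
                f"{model.pdb_id}: no resolution record; structure rejected "
                f"(filter requires < {max_resolution} A)"
            )
        if model.resolution >= max_resolution:
            raise ResolutionError(
                f"{model.pdb_id}: resolution {model.resolution} A is not "
                f"better than {max_resolution} A"
            )

    candidates: list[tuple[str, int]] = []
    for chain_id in model.chains:
        seq, _ = chain_sequence(model, chain_id)
        for off in locate_peptide(peptide, seq):
            candidates.append((chain_id, off))
    if not candidates:
        raise MappingError(
            f"peptide {peptide!r} has no 100%-identity match in {model.pdb_id}"
        )
    if len(candidates) > 1:
        raise AmbiguousMappingError(candidates)

    chain_id, off = candidates[0]
    _, index_map = chain_sequence(model, chain_id)
    pos = off + offset_in_peptide
    seq_id, icode = index_map[pos]
    residue = model.find_residue(chain_id, seq_id, icode)
    if residue.one_letter != site.residue:
        raise MappingError(
            f"mapped residue {residue.label()} is {residue.one_letter!r}, "
            f"site record says {site.residue!r}"
        )
    return MappedSite(
        site=site,
        pdb_id=model.pdb_id,
        chain_id=chain_id,
        seq_id=seq_id,
        icode=icode,
        peptide_span=(off, off + len(peptide)),
    )
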