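"""Non-homologous benchmark datasets and predictor evaluation.

Positive fragments are fixed-width sequence windows (2n+1, n=10 by
default) centered at experimentally verified modification sites;
negatives are windows centered at every unmodified residue of the same
type in the same, modified, proteins.  Redundancy is removed by greedy
incremental clustering at a within-set identity threshold (50% by
default, one representative per cluster), followed by a cross-set purge
that removes negatives identical to a positive (100% identity by
default).  Predictor output is scored with the standard confusion-matrix
statistics Sn, Sp, Acc and MCC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from ptmstructkit.structio import SiteRecord

__all__ = [
    "Fragment",
    "BenchmarkDataset",
    "EvalMetrics",
    "extract_window",
    "build_sets",
    "fragment_identity",
    "greedy_cluster",
    "cross_purge",
    "evaluate",
]

DEFAULT_WINDOW_N = 10
DEFAULT_IDENTITY = 0.5
DEFAULT_CROSS_IDENTITY = 1.0
PAD = "-"


@dataclass(frozen=True)
class Fragment:
    """A fixed-width window around one residue of a protein sequence."""

    accession: str
    position: int  # 1-based center position
    window_n: int
    seq: str
    label: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if len(self.seq) != 2 * self.window_n + 1:
            raise ValueError(
                f"fragment length {len(self.seq)} != 2*{self.window_n}+1"
            )

    @property
    def key(self) -> str:
        return f"{self.accession}|{self.position}|{self.label}"


@dataclass
class BenchmarkDataset:
    """Positive/negative fragments after redundancy reduction."""

    positives: list[Fragment]
    negatives: list[Fragment]
    target_residue: str
    ptm_type: str
    identity_threshold: float = DEFAULT_IDENTITY
    cross_identity: float = DEFAULT_CROSS_IDENTITY


@dataclass
class EvalMetrics:
    """Confusion counts and derived rates for a binary predictor."""

    TP: int
    FP: int
    TN: int
    FN: int
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    mcc_undefined: bool = False


def extract_window(
    sequence: str, position: int, n: int = DEFAULT_WINDOW_N, pad: str = PAD
) -> str:
    """The 2n+1 window of ``sequence`` centered at 1-based ``position``.

    Positions past either terminus are filled with the pad character.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    if n < 0:
        raise ValueError("window n must be >= 0")
    i = position - 1
    left = sequence[max(0, i - n): i]
    right = sequence[i + 1: i + 1 + n]
    return pad * (n - len(left)) + left + sequence[i] + right + pad * (n - len(right))


def build_sets(
    proteins: dict[str, str],
    sites: list[SiteRecord],
    target_residue: str,
    n: int = DEFAULT_WINDOW_N,
    pad: str = PAD,
) -> tuple[list[Fragment], list[Fragment]]:
    """Raw positive and negative fragments before redundancy reduction.

    Positives are windows at annotated sites whose residue equals
    ``target_residue``; negatives are windows at every other occurrence
    of that residue type in the same proteins.  Proteins without any
    annotated site contribute nothing.  Sites of a different residue
    type are skipped with a warning.
    """
    site_positions: dict[str, set[int]] = {}
    for site in sites:
        if site.residue != target_residue:
            warnings.warn(
                f"site {site.accession}:{site.position} has residue "
                f"{site.residue!r}, expected {target_residue!r}; skipped",
                stacklevel=2,
            )
            continue
        if site.accession not in proteins:
            warnings.warn(
                f"site {site.accession}:{site.position}: unknown accession; "
                "skipped",
                stacklevel=2,
            )
            continue
        site_positions.setdefault(site.accession, set()).add(site.position)

    positives, negatives = [], []
    for acc in sorted(site_positions):
        seq = proteins[acc]
        modified = site_positions[acc]
        for pos in sorted(modified):
            if seq[pos - 1] != target_residue:
                warnings.warn(
                    f"site {acc}:{pos} does not sit on a {target_residue!r} "
                    "in the sequence; skipped",
                    stacklevel=2,
                )
                continue
            positives.append(
                Fragment(acc, pos, n, extract_window(seq, pos, n, pad), "positive")
            )
        for i, aa in enumerate(seq, start=1):
            if aa == target_residue and i not in modified:
                negatives.append(
                    Fragment(acc, i, n, extract_window(seq, i, n, pad), "negative")
                )
    return positives, negatives


def fragment_identity(a: str, b: str) -> float:
    """Pairwise identity of two equal-length fragments.

    Identical non-pad characters over the full window length; pad
    positions count as mismatches.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != PAD)
    return matches / len(a)


def greedy_cluster(
    fragments: list[Fragment], threshold: float = DEFAULT_IDENTITY
) -> list[Fragment]:
    """One representative per cluster by greedy incremental clustering.

    Fragments are scanned in input order; each joins the first existing
    cluster whose representative (founder) it matches at >= ``threshold``
    identity, otherwise it founds a new cluster.  Returns the founders,
    in input order.
    """
    representatives: list[Fragment] = []
    for frag in fragments:
        for rep in representatives:
            if fragment_identity(frag.seq, rep.seq) >= threshold:
                break
        else:
            representatives.append(frag)
    return representatives


def cross_purge(
    positives: list[Fragment],
    negatives: list[Fragment],
    identity: float = DEFAULT_CROSS_IDENTITY,
) -> list[Fragment]:
    """Drop negatives at >= ``identity`` to any positive.

    At the default 1.0 this removes negatives whose window is an exact
    duplicate of a positive window, which would otherwise corrupt both
    sides of an evaluation.
    """
    if identity >= 1.0:
        pos_seqs = {p.seq for p in positives}
        return [n for n in negatives if n.seq not in pos_seqs]
    return [
        n
        for n in negatives
        if all(fragment_identity(n.seq, p.seq) < identity for p in positives)
    ]


def build_benchmark(
    proteins: dict[str, str],
    sites: list[SiteRecord],
    target_residue: str,
    ptm_type: str,
    n: int = DEFAULT_WINDOW_N,
    identity: float = DEFAULT_IDENTITY,
    cross_identity: float = DEFAULT_CROSS_IDENTITY,
) -> BenchmarkDataset:
    """Full pipeline: build windows, cluster each set, purge cross-set
    duplicates."""
    positives, negatives = build_sets(proteins, sites, target_residue, n)
    positives = greedy_cluster(positives, identity)
    negatives = greedy_cluster(negatives, identity)
    negatives = cross_purge(positives, negatives, cross_identity)
    return BenchmarkDataset(
        positives=positives,
        negatives=negatives,
        target_residue=target_residue,
        ptm_type=ptm_type,
        identity_threshold=identity,
        cross_identity=cross_identity,
    )


def evaluate(
    dataset: BenchmarkDataset,
    predictions: dict[str, bool],
    missing_policy: str = "error",
) -> EvalMetrics:
    """Score a predictor against the benchmark.

    ``predictions`` maps :attr:`Fragment.key` to the predicted call.
    ``missing_policy`` is "error" or "negative" (treat missing fragments
    as negative calls).  Unknown keys in ``predictions`` are an error.
    MCC is reported as 0 with ``mcc_undefined=True`` when a denominator
    term vanishes.
    """
    keys = {f.key for f in dataset.positives} | {f.key for f in dataset.negatives}
    unknown = set(predictions) - keys
    if unknown:
        raise ValueError(f"predictions for unknown fragments: {sorted(unknown)[:5]}")

    def call(frag: Fragment) -> bool:
        if frag.key in predictions:
            return predictions[frag.key]
        if missing_policy == "negative":
            return False
        raise ValueError(f"no prediction for fragment {frag.key}")

    tp = sum(1 for f in dataset.positives if call(f))
    fn = len(dataset.positives) - tp
    fp = sum(1 for f in dataset.negatives if call(f))
    tn = len(dataset.negatives) - fp

    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else 0.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0.0:
        mcc, undefined = 0.0, True
    else:
        mcc, undefined = (tp * tn - fp * fn) / denom, False
    return EvalMetrics(
        TP=tp, FP=fp, TN=tn, FN=fn, Sn=sn, Sp=sp, Acc=acc, MCC=mcc,
        mcc_undefined=undefined,
    )
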