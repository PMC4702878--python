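import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptmstructkit.benchmark import (
    BenchmarkDataset,
    Fragment,
    build_benchmark,
    build_sets,
    cross_purge,
    evaluate,
    extract_window,
    fragment_identity,
    greedy_cluster,
)
from ptmstructkit.structio import SiteRecord


class TestExtractWindow:
    def test_mid_sequence_21mer(self):
        seq = "A" * 15 + "K" + "C" * 15
        w = extract_window(seq, 16, n=10)
        assert len(w) == 21 and w[10] == "K"
        assert w == "A" * 10 + "K" + "C" * 10

    def test_terminal_padding(self):
        w = extract_window("KACDEFGHIKLMN", 1, n=10)
        assert w == "-" * 10 + "KACDEFGHIKL"

    def test_zero_window(self):
        assert extract_window("AKC", 2, n=0) == "K"

    def test_invalid_position(self):
        with pytest.raises(ValueError):
            extract_window("AKC", 4)


@settings(max_examples=100, derandomize=True)
@given(
    seq=st.text(alphabet="ACDK", min_size=1, max_size=60),
    n=st.integers(0, 12),
    data=st.data(),
)
def test_window_length_and_center_invariant(seq, n, data):
    pos = data.draw(st.integers(1, len(seq)))
    w = extract_window(seq, pos, n=n)
    assert len(w) == 2 * n + 1
    assert w[n] == seq[pos - 1]
    # pads appear only as a prefix and/or suffix
    assert "-" not in w.strip("-")


class TestBuildSets:
    def test_counting_on_tiny_protein(self):
        proteins = {"P1": "KAKAK"}
        sites = [SiteRecord("P1", 1, "K", "Ubiquitylation")]
        pos, neg = build_sets(proteins, sites, "K", n=2)
        assert len(pos) == 1 and len(neg) == 2
        assert {f.position for f in neg} == {3, 5}

    def test_unmodified_proteins_contribute_nothing(self):
        proteins = {"P1": "KAKAK", "P2": "KKKKK"}
        sites = [SiteRecord("P1", 1, "K", "Ubiquitylation")]
        pos, neg = build_sets(proteins, sites, "K", n=2)
        assert all(f.accession == "P1" for f in pos + neg)

    def test_wrong_residue_site_skipped_with_warning(self):
        proteins = {"P1": "KASAK"}
        sites = [SiteRecord("P1", 3, "S", "Phosphorylation")]
        with pytest.warns(UserWarning, match="skipped"):
            pos, neg = build_sets(proteins, sites, "K", n=2)
        assert pos == [] and neg == []

    def test_count_conservation(self, proteome):
        proteins, sites, _ = proteome
        pos, neg = build_sets(proteins, sites, "K")
        modified = {s.accession for s in sites}
        total_k = sum(seq.count("K") for acc, seq in proteins.items()
                      if acc in modified)
        assert len(pos) + len(neg) == total_k


class TestIdentity:
    def test_direct_counts(self):
        a = "A" * 21
        assert fragment_identity(a, a) == 1.0
        assert fragment_identity(a, "C" * 21) == 0.0
        half = "A" * 10 + "C" * 11
        assert fragment_identity(a, half) == pytest.approx(10 / 21)

    def test_pads_count_as_mismatches(self):
        a = "-" * 10 + "K" + "A" * 10
        assert fragment_identity(a, a) == pytest.approx(11 / 21)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fragment_identity("AAA", "AAAA")

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.text(alphabet="ACDK-", min_size=21, max_size=21),
        b=st.text(alphabet="ACDK-", min_size=21, max_size=21),
    )
    def test_symmetric_and_bounded(self, a, b):
        assert fragment_identity(a, b) == fragment_identity(b, a)
        assert 0.0 <= fragment_identity(a, b) <= 1.0


def _frag(seq, acc="P", pos=1, label="positive"):
    n = (len(seq) - 1) // 2
    return Fragment(acc, pos, n, seq, label)


class TestGreedyCluster:
    def test_identical_fragments_collapse(self):
        frags = [_frag("A" * 21, pos=i + 1) for i in range(5)]
        assert len(greedy_cluster(frags)) == 1

    def test_dissimilar_fragments_survive(self):
        frags = [_frag("A" * 21), _frag("A" * 8 + "C" * 13, pos=2)]
        assert fragment_identity(frags[0].seq, frags[1].seq) < 0.5
        assert len(greedy_cluster(frags, threshold=0.5)) == 2

    def test_representatives_pairwise_below_threshold(self):
        rng = np.random.default_rng(12)
        alphabet = np.array(list("ACDEFK"))
        frags = []
        for i in range(120):
            if i % 4 == 0 and frags:  # inject near-duplicates
                base = list(frags[rng.integers(len(frags))].seq)
                for j in rng.choice(21, size=4, replace=False):
                    base[j] = str(rng.choice(alphabet))
                seq = "".join(base)
            else:
                seq = "".join(rng.choice(alphabet, size=21))
            frags.append(_frag(seq, pos=i + 1))
        reps = greedy_cluster(frags, threshold=0.5)
        # all-pairs oracle: no two representatives at >= 50% identity
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert fragment_identity(reps[i].seq, reps[j].seq) < 0.5
        # every dropped fragment matches some representative
        rep_seqs = [r.seq for r in reps]
        for f in frags:
            assert any(fragment_identity(f.seq, s) >= 0.5 for s in rep_seqs)


class TestCrossPurge:
    def test_exact_duplicates_removed(self):
        pos = [_frag("A" * 21)]
        neg = [_frag("A" * 21, label="negative"),
               _frag("C" * 21, label="negative")]
        purged = cross_purge(pos, neg)
        assert [f.seq for f in purged] == ["C" * 21]

    def test_near_duplicates_retained_at_full_identity(self):
        pos = [_frag("A" * 21)]
        near = _frag("A" * 20 + "C", label="negative")  # 95% identical
        assert cross_purge(pos, [near]) == [near]
        # but a stricter threshold removes it
        assert cross_purge(pos, [near], identity=0.9) == []

    def test_planted_duplicates_exact_count(self, proteome):
        proteins, sites, manifest = proteome
        ds = build_benchmark(proteins, sites, manifest["target_residue"],
                             manifest["ptm_type"])
        assert len(ds.positives) == manifest["positives_nonredundant"]
        assert len(ds.negatives) == manifest["negatives_after_purge"]


def _balanced_dataset(n):
    rng = np.random.default_rng(99)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    frags = ["".join(rng.choice(alphabet, size=21)) for _ in range(n)]
    half = n // 2
    pos = [_frag(s, pos=i + 1) for i, s in enumerate(frags[:half])]
    neg = [_frag(s, pos=i + 1, label="negative")
           for i, s in enumerate(frags[half:])]
    return BenchmarkDataset(pos, neg, "K", "Ubiquitylation")


class TestEvaluate:
    def test_perfect_predictor(self):
        ds = _balanced_dataset(200)
        preds = {f.key: True for f in ds.positives}
        preds.update({f.key: False for f in ds.negatives})
        m = evaluate(ds, preds)
        assert (m.Sn, m.Sp, m.Acc, m.MCC) == (1.0, 1.0, 1.0, 1.0)

    def test_all_positive_predictor(self):
        ds = _balanced_dataset(200)
        preds = {f.key: True for f in ds.positives + ds.negatives}
        m = evaluate(ds, preds)
        assert m.Sn == 1.0 and m.Sp == 0.0
        assert m.mcc_undefined and m.MCC == 0.0

    def test_mcc_matches_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        ds = _balanced_dataset(400)
        rng = np.random.default_rng(17)
        preds = {f.key: bool(rng.integers(2))
                 for f in ds.positives + ds.negatives}
        m = evaluate(ds, preds)
        y_true = [1] * len(ds.positives) + [0] * len(ds.negatives)
        y_pred = [int(preds[f.key]) for f in ds.positives + ds.negatives]
        assert m.MCC == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_missing_prediction_policies(self):
        ds = _balanced_dataset(10)
        with pytest.raises(ValueError, match="no prediction"):
            evaluate(ds, {})
        m = evaluate(ds, {}, missing_policy="negative")
        assert m.Sn == 0.0 and m.Sp == 1.0

    def test_unknown_fragment_rejected(self):
        ds = _balanced_dataset(10)
        with pytest.raises(ValueError, match="unknown"):
            evaluate(ds, {"nope|1|positive": True}, missing_policy="negative")
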