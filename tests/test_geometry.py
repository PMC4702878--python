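import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptmstructkit import fixtures as fx
from ptmstructkit.geometry import (
    AMINO_ACIDS,
    GeometryError,
    classify_functional,
    functional_atom,
    orientation_angle,
    radial_composition,
    sequential_neighbors,
    sidechain_vector,
    spatial_neighbors,
    substrate_vector,
)
from ptmstructkit.structio import Atom, Residue

from conftest import brute_force_neighbors


def _residue(name, atoms):
    return Residue("A", 1, name, [Atom(n, e, c) for n, e, c in atoms])


class TestFunctionalAtom:
    def test_serine_og(self):
        res = _residue("SER", [("CA", "C", [0, 0, 0]), ("CB", "C", [0, 0, 1.5]),
                               ("OG", "O", [0, 0, 2.4])])
        atom, fallback = functional_atom(res)
        assert atom.name == "OG" and not fallback

    def test_glycine_has_none(self):
        res = _residue("GLY", [("CA", "C", [0, 0, 0])])
        assert functional_atom(res) == (None, False)

    def test_fallback_to_outermost_sidechain_atom(self):
        res = _residue("LYS", [("CA", "C", [0, 0, 0]), ("CB", "C", [0, 0, 1.5]),
                               ("CG", "C", [0, 0, 2.6]), ("CE", "C", [0, 0, 3.8])])
        atom, fallback = functional_atom(res)
        assert atom.name == "CE" and fallback


def test_vectors_from_known_coordinates():
    site = _residue("SER", [("CA", "C", [5, 5, 5]), ("CB", "C", [5, 5, 6.5]),
                            ("OG", "O", [5, 5, 7.4])])
    nbr = _residue("SER", [("CA", "C", [0, 0, 0]), ("CB", "C", [1.5, 0, 0]),
                           ("OG", "O", [2.4, 0, 0])])
    assert np.allclose(substrate_vector(site, nbr), [5, 5, 7.4])
    assert np.allclose(sidechain_vector(nbr), [2.4, 0, 0])
    # translation of everything leaves S_k unchanged
    t = np.array([3.0, -2.0, 9.0])
    site_t = _residue("SER", [(a.name, a.element, a.coord + t) for a in site.atoms])
    nbr_t = _residue("SER", [(a.name, a.element, a.coord + t) for a in nbr.atoms])
    assert np.allclose(substrate_vector(site_t, nbr_t), substrate_vector(site, nbr))


def test_degenerate_sidechain_vector_is_an_error():
    res = _residue("SER", [("CA", "C", [1, 1, 1]), ("OG", "O", [1, 1, 1])])
    with pytest.raises(GeometryError):
        sidechain_vector(res)


@pytest.mark.parametrize(
    "S,V,expected",
    [
        ([1, 0, 0], [1, 0, 0], 0.0),
        ([1, 0, 0], [0, 1, 0], 90.0),
        ([1, 0, 0], [-1, 0, 0], 180.0),
        ([1, 0, 0], [2, 0, 0], 0.0),  # scale invariance
    ],
)
def test_orientation_angle_trivial_cases(S, V, expected):
    assert orientation_angle(S, V) == pytest.approx(expected, abs=1e-12)


def test_orientation_angle_rejects_zero_vectors():
    with pytest.raises(GeometryError):
        orientation_angle([0, 0, 0], [1, 0, 0])


finite3 = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=3, max_size=3
).filter(lambda v: np.linalg.norm(v) > 1e-6)


@settings(max_examples=200, derandomize=True)
@given(S=finite3, V=finite3)
def test_angle_of_negated_vector_is_supplementary(S, V):
    total = orientation_angle(S, V) + orientation_angle(S, [-x for x in V])
    assert total == pytest.approx(180.0, abs=1e-7)


@settings(max_examples=100, derandomize=True)
@given(
    S=finite3, V=finite3,
    scale=st.floats(1e-3, 1e3),
    seed=st.integers(0, 2**16),
)
def test_angle_invariant_under_rotation_and_scaling(S, V, scale, seed):
    from scipy.spatial.transform import Rotation

    base = orientation_angle(S, V)
    R = Rotation.random(random_state=seed).as_matrix()
    # near-parallel vectors lose precision through arccos (derivative
    # diverges at +-1), so the bound here is looser than for generic pairs
    assert orientation_angle(R @ np.array(S), R @ np.array(V)) == pytest.approx(
        base, abs=1e-5
    )
    assert orientation_angle(np.array(S) * scale, V) == pytest.approx(base, abs=1e-5)


@pytest.mark.parametrize(
    "theta,expected",
    [(27.9, True), (79.999, True), (80.0, False), (80.001, False), (179.9, False)],
)
def test_functional_classification_is_strict(theta, expected):
    assert classify_functional(theta) is expected


class TestSpatialNeighbors:
    def test_planted_distances_and_angles_recovered(self, toy):
        model, truth, mapped = toy
        records = spatial_neighbors(model, mapped, cutoff=10.0)
        planted = truth[truth.kind == "neighbor"].set_index("label")
        got = {r.residue.label(): r for r in records}
        for label, row in planted.iterrows():
            if row.distance <= 10.0:
                assert label in got
                rec = got[label]
                assert rec.distance == pytest.approx(row.distance, abs=1e-6)
                if not np.isnan(row.angle):
                    assert rec.orientation.theta_deg == pytest.approx(
                        row.angle, abs=1e-6
                    )
                    assert rec.orientation.functional == (row.angle < 80.0)
            else:
                assert label not in got  # 10.1 A neighbor stays out

    def test_sorted_ascending_and_site_excluded(self, toy):
        model, _, mapped = toy
        records = spatial_neighbors(model, mapped, cutoff=50.0)
        dists = [r.distance for r in records]
        assert dists == sorted(dists)
        labels = {r.residue.label() for r in records}
        assert f"A:SER{mapped.seq_id}" not in labels

    def test_lone_residue_has_no_neighbors(self):
        spec = fx.FixtureSpec(seed=0, neighbors=(), ligand_distances=())
        model, _ = fx.make_toy_structure(spec)
        mapped = fx.toy_mapped_site(model, spec)
        assert spatial_neighbors(model, mapped) == []
        profile = radial_composition(model, mapped)
        assert profile.cumulative_counts.sum() == 0

    def test_glycine_neighbor_has_no_orientation(self):
        spec = fx.FixtureSpec(seed=3, neighbors=((5.0, None), (6.0, 30.0)))
        model, _ = fx.make_toy_structure(spec)
        mapped = fx.toy_mapped_site(model, spec)
        records = spatial_neighbors(model, mapped)
        by_name = {r.residue.res_name: r for r in records}
        assert by_name["GLY"].orientation is None
        assert by_name["SER"].orientation is not None

    def test_matches_brute_force_oracle_on_random_structure(self, toy_spec):
        model = fx.make_random_structure(400, seed=11)
        site_residue = model.chains["A"][0]
        mapped = fx.toy_mapped_site(model, toy_spec)
        mapped = type(mapped)(
            site=mapped.site, pdb_id=model.pdb_id, chain_id="A",
            seq_id=1, icode="", peptide_span=(0, 1),
        )
        ref, _ = functional_atom(site_residue)
        ref_point = ref.coord if ref is not None else site_residue.atom("CA").coord
        expected = brute_force_neighbors(model, site_residue, ref_point, 12.0)
        records = spatial_neighbors(model, mapped, cutoff=12.0)
        got = [(r.residue.chain_id, r.residue.seq_id, r.distance) for r in records]
        assert len(got) == len(expected)
        for (c1, s1, d1), (c2, s2, d2) in zip(got, expected):
            assert (c1, s1) == (c2, s2) and d1 == pytest.approx(d2, abs=1e-9)


class TestSequentialNeighbors:
    def test_terminal_position_truncates(self):
        records = sequential_neighbors("ACDEFGHIKL", 1, window=6)
        assert [r.seq_offset for r in records] == [1, 2, 3, 4, 5, 6]
        assert [r.aa for r in records] == list("CDEFGH")

    def test_mid_sequence_yields_twelve(self):
        records = sequential_neighbors("A" * 30, 15, window=6)
        assert [r.seq_offset for r in records] == [-6, -5, -4, -3, -2, -1,
                                                   1, 2, 3, 4, 5, 6]

    def test_zero_window_is_empty(self):
        assert sequential_neighbors("ACDEF", 3, window=0) == []

    def test_invalid_position(self):
        with pytest.raises(GeometryError):
            sequential_neighbors("ACDEF", 9)


class TestRadialComposition:
    def test_single_neighbor_shells(self):
        site = Residue("A", 1, "SER", [
            Atom("CA", "C", [0, 0, 0]), Atom("CB", "C", [0, 0, 1.5]),
            Atom("OG", "O", [0, 0, 2.4]),
        ])
        ala = Residue("A", 2, "ALA", [
            Atom("CA", "C", [0, 0, 7.4]),  # 5.0 A from OG
            Atom("CB", "C", [0, 1.5, 7.4]),
        ])
        model = fx.StructureModel(pdb_id="x", resolution=2.0,
                                  chains={"A": [site, ala]})
        spec = fx.FixtureSpec(seed=0, site_seq_id=1)
        mapped = fx.toy_mapped_site(model, spec)
        profile = radial_composition(model, mapped)
        i4 = list(profile.radii).index(4.0)
        i6 = list(profile.radii).index(6.0)
        assert profile.cumulative_counts[i4].sum() == 0
        assert np.isnan(profile.cumulative_freqs[i4]).all()  # empty shell
        a_idx = AMINO_ACIDS.index("A")
        assert profile.cumulative_counts[i6, a_idx] == 1
        assert profile.cumulative_freqs[i6, a_idx] == 1.0

    def test_counts_monotone_and_frequencies_normalized(self, toy):
        model, _, mapped = toy
        profile = radial_composition(model, mapped)
        diffs = np.diff(profile.cumulative_counts, axis=0)
        assert (diffs >= 0).all()
        totals = profile.cumulative_counts.sum(axis=1)
        for i, total in enumerate(totals):
            if total > 0:
                assert profile.cumulative_freqs[i].sum() == pytest.approx(1.0)

    def test_matches_brute_force_recount(self, toy_spec):
        model = fx.make_random_structure(300, seed=23)
        site_residue = model.chains["A"][0]
        mapped = type(fx.toy_mapped_site(model, toy_spec))(
            site=fx.toy_mapped_site(model, toy_spec).site,
            pdb_id=model.pdb_id, chain_id="A", seq_id=1, icode="",
            peptide_span=(0, 1),
        )
        ref, _ = functional_atom(site_residue)
        ref_point = ref.coord if ref is not None else site_residue.atom("CA").coord
        profile = radial_composition(model, mapped)
        for i, r in enumerate(profile.radii):
            neighbors = brute_force_neighbors(model, site_residue, ref_point, r)
            count = sum(
                1
                for c, s, _ in neighbors
                if model.find_residue(c, s).one_letter in AMINO_ACIDS
            )
            assert profile.cumulative_counts[i].sum() == count
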