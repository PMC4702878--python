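import numpy as np
import pytest

from ptmstructkit import fixtures as fx


@pytest.fixture(scope="session")
def toy_spec():
    return fx.FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def toy(toy_spec):
    """(model, ground-truth table, mapped site) for the planted structure."""
    model, truth = fx.make_toy_structure(toy_spec)
    return model, truth, fx.toy_mapped_site(model, toy_spec)


@pytest.fixture(scope="session")
def proteome(toy_spec):
    """Synthetic proteome with manifest bookkeeping."""
    return fx.make_synthetic_proteome(toy_spec)


def brute_force_neighbors(model, site_residue, ref_point, cutoff):
    """All-pairs oracle: (chain, seq_id, distance) of residues whose CA
    is within cutoff of the reference point."""
    found = []
    for chain_id, residues in model.chains.items():
        for res in residues:
            if res is site_residue:
                continue
            ca = res.atom("CA")
            if ca is None:
                continue
            d = float(np.linalg.norm(ca.coord - ref_point))
            if d <= cutoff:
                found.append((chain_id, res.seq_id, d))
    return sorted(found, key=lambda t: (t[2], t[0], t[1]))
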