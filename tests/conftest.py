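import numpy as np
import pandas as pd
import pytest

import hyqsar as h


@pytest.fixture(scope="session")
def small_molecules():
    """A fixed set of small molecules covering rings, stereo, charge, halogens."""
    smiles = ["O", "C=O", "c1ccccc1", "CCO", "CC(N)C(=O)O", "C[C@H](N)C(=O)O",
              "CC(=O)[O-]", "ClCCl", "C#N", "CC(C)(C)C"]
    return [(f"m{i}", s) for i, s in enumerate(smiles)]


@pytest.fixture(scope="session")
def small_graphs(small_molecules):
    return [h.parse_smiles(s) for _, s in small_molecules]


@pytest.fixture(scope="session")
def synthetic_30():
    """30 seeded synthetic molecules encoded to a padded trajectory tensor."""
    spec = h.SyntheticSpec(n_molecules=30, seed=7)
    mols = h.generate_molecules(spec)
    graphs = [h.parse_smiles(s) for _, s in mols]
    tensor, records = h.encode_dataset(graphs, ids=[m for m, _ in mols])
    return tensor, records


@pytest.fixture()
def random_table():
    rng = np.random.default_rng(123)
    frame = pd.DataFrame(rng.normal(size=(20, 4)),
                         index=[f"c{i}" for i in range(20)],
                         columns=["d1", "d2", "d3", "d4"])
    return h.DescriptorTable(frame)
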