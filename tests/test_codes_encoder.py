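"""Activation-network encoding: weights, dynamics, padding, invariances."""

import numpy as np
import pytest

import hyqsar as h
from hyqsar.codes_encoder import initial_activations


def _cfg(**kw):
    return h.EncoderConfig(**kw)


# -- connection weights ------------------------------------------------------

def test_ethane_weight_matrix():
    g = h.parse_smiles("CC")
    w = h.connection_weights(g, _cfg())
    np.testing.assert_allclose(w, [[0, 0.10], [0.10, 0]])


def test_propane_nonbonded_ends_inhibit():
    g = h.parse_smiles("CCC")
    w = h.connection_weights(g, _cfg())
    assert w[0, 2] == pytest.approx(-0.01)
    assert w[0, 1] == pytest.approx(0.10)
    assert np.all(np.diag(w) == 0)


def test_weight_matrix_matches_bruteforce_on_random_tree():
    spec = h.SyntheticSpec(n_molecules=1, size_range=(8, 8), ring_probability=0.0,
                           seed=5, n_informative=2, coefficients=(1.0, 1.0))
    _, smiles = h.generate_molecules(spec)[0]
    g = h.parse_smiles(smiles)
    cfg = _cfg()
    w = h.connection_weights(g, cfg)
    bonded = {(min(i, j), max(i, j)): order for i, j, order in g.bonds}
    for i in range(g.n_atoms):
        for j in range(g.n_atoms):
            if i == j:
                expected = 0.0
            elif (min(i, j), max(i, j)) in bonded:
                expected = cfg.bond_weights[bonded[(min(i, j), max(i, j))]]
            else:
                expected = cfg.inhibition
            assert w[i, j] == expected
    np.testing.assert_array_equal(w, w.T)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        _cfg(inhibition=0.01)
    with pytest.raises(ValueError):
        _cfg(bond_weights={"single": -0.1})
    with pytest.raises(ValueError):
        _cfg(epsilon=0.0)


# -- dynamics ----------------------------------------------------------------

def test_single_atom_without_feedback_reaches_half():
    """With beta=0 an isolated neuron has zero net input: sigma(0) = 0.5."""
    t = h.iterate_to_equilibrium(h.parse_smiles("O"), _cfg(self_feedback=0.0))
    assert t.matrix[0, 1] == pytest.approx(0.5)
    assert t.converged
    assert t.n_iterations <= 3


def test_symmetric_molecule_rows_identical():
    t = h.iterate_to_equilibrium(h.parse_smiles("CC"))
    np.testing.assert_allclose(t.matrix[0], t.matrix[1], atol=0)


def test_trajectory_matches_straightline_recomputation():
    """Independent step-by-step recomputation of the sigmoid dynamics."""
    g = h.parse_smiles("CCO")
    cfg = _cfg(epsilon=1e-6)
    t = h.iterate_to_equilibrium(g, cfg)
    w = h.connection_weights(g, cfg)
    state = initial_activations(g, cfg)
    ref = [state]
    for _ in range(cfg.max_iterations):
        new = 1.0 / (1.0 + np.exp(-(cfg.gain * (cfg.self_feedback * state + w @ state))))
        ref.append(new)
        if np.max(np.abs(new - state)) < cfg.epsilon:
            break
        state = new
    np.testing.assert_allclose(t.matrix, np.column_stack(ref), atol=1e-12)


def test_stereo_perturbs_initial_state():
    achiral = h.parse_smiles("CC(N)C(=O)O")
    chiral = h.parse_smiles("C[C@H](N)C(=O)O")
    cfg = _cfg()
    a0 = initial_activations(achiral, cfg)
    c0 = initial_activations(chiral, cfg)
    assert not np.allclose(sorted(a0), sorted(c0))


def test_enantiomers_encode_differently():
    """The R/S perturbation decays toward equilibrium (the update contracts to
    a fixed point), so enantiomer information lives in the transient columns
    that the dynamic matrix records."""
    r = h.iterate_to_equilibrium(h.parse_smiles("C[C@@H](N)C(=O)O"))
    s = h.iterate_to_equilibrium(h.parse_smiles("C[C@H](N)C(=O)O"))
    early = min(3, r.n_iterations, s.n_iterations)
    assert not np.allclose(np.sort(r.matrix[:, :early], axis=0),
                           np.sort(s.matrix[:, :early], axis=0), atol=1e-3)


def test_activations_bounded_and_deterministic(small_graphs):
    for g in small_graphs:
        t1 = h.iterate_to_equilibrium(g)
        t2 = h.iterate_to_equilibrium(g)
        assert np.all(t1.matrix > 0) and np.all(t1.matrix < 1)
        np.testing.assert_array_equal(t1.matrix, t2.matrix)  # bit determinism


def test_all_small_fixtures_converge(small_graphs):
    for g in small_graphs:
        assert h.iterate_to_equilibrium(g).converged


def test_isomorphism_invariance_of_row_multiset():
    """Relabeling atoms permutes trajectory rows; row multiset is unchanged."""
    from rdkit import Chem

    base = "CC(N)C(=O)O"
    cfg = _cfg()
    ref = h.iterate_to_equilibrium(h.parse_smiles(base), cfg)
    ref_rows = np.sort(ref.matrix[:, -1])
    mol = Chem.MolFromSmiles(base)
    rng = np.random.default_rng(0)
    for _ in range(20):
        perm = list(rng.permutation(mol.GetNumAtoms()))
        renum = Chem.RenumberAtoms(mol, [int(p) for p in perm])
        smi = Chem.MolToSmiles(renum, canonical=False)
        t = h.iterate_to_equilibrium(h.parse_smiles(smi), cfg)
        assert t.matrix.shape == ref.matrix.shape
        np.testing.assert_allclose(np.sort(t.matrix[:, -1]), ref_rows, atol=1e-12)


def test_iac_rule_stays_in_unit_interval():
    t = h.iterate_to_equilibrium(h.parse_smiles("CCO"), _cfg(update_rule="iac"))
    assert np.all(t.matrix > 0) and np.all(t.matrix < 1)


# -- dataset padding ---------------------------------------------------------

def test_padding_to_common_shape():
    graphs = [h.parse_smiles("CC"), h.parse_smiles("CCO")]
    tensor, records = h.encode_dataset(graphs, ids=["a", "b"])
    a_max = max(r["A"] for r in records)
    r_max = max(r["R"] for r in records)
    assert tensor.shape == (2, a_max, r_max)


def test_padding_columns_repeat_equilibrium_and_rows_zero():
    graphs = [h.parse_smiles("CC"), h.parse_smiles("CC(N)C(=O)O")]
    tensor, records = h.encode_dataset(graphs, ids=["a", "b"])
    rec = records[0]
    if rec["R"] < tensor.shape[2]:
        last = tensor[0, : rec["A"], rec["R"] - 1]
        for col in range(rec["R"], tensor.shape[2]):
            np.testing.assert_array_equal(tensor[0, : rec["A"], col], last)
    assert np.all(tensor[0, rec["A"]:, :] == 0)


def test_unpadding_recovers_original_matrices():
    graphs = [h.parse_smiles(s) for s in ["CC", "CCO", "c1ccccc1"]]
    trajectories = [h.iterate_to_equilibrium(g) for g in graphs]
    tensor, records = h.encode_dataset(graphs, ids=["a", "b", "c"])
    for original, recovered in zip(trajectories, h.unpad_trajectories(tensor, records)):
        np.testing.assert_array_equal(original.matrix, recovered)


def test_nonconvergence_warns_and_strict_raises():
    cfg = _cfg(max_iterations=2, epsilon=1e-12)
    graphs = [h.parse_smiles("CCO")]
    with pytest.warns(h.codes_encoder.NonConvergenceWarning):
        h.encode_dataset(graphs, cfg, ids=["a"])
    with pytest.raises(RuntimeError, match="a"):
        h.encode_dataset(graphs, cfg, ids=["a"], strict=True)


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        h.encode_dataset([])
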