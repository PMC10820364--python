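import numpy as np
import pytest

from aopqsar.encoders import (
    FeaturePreprocessor,
    HashedNGramEncoder,
    NGramAutoencoder,
    build_vocabulary,
    compute_circular_fp,
    compute_descriptors,
    compute_maccs_fp,
    devectorize,
    featurize_graph,
    latent_encode,
    preprocess_features,
    vectorize_smiles,
)
from aopqsar.encoders.tabular import FeatureBundle
from aopqsar.encoders.tokens import nearest_rank_percentile


# -- descriptors ------------------------------------------------------------


def test_descriptor_block_shape_and_determinism():
    bundle = compute_descriptors(["CCO", "c1ccccc1", "CCO"])
    assert bundle.matrix.shape == (3, len(bundle.feature_names))
    assert np.array_equal(
        bundle.matrix[0], bundle.matrix[2], equal_nan=True
    )  # identical molecules -> identical rows


def test_methane_count_descriptors():
    bundle = compute_descriptors(["C"])
    row = dict(zip(bundle.feature_names, bundle.matrix[0]))
    assert row["HeavyAtomCount"] == 1.0
    assert row["RingCount"] == 0.0
    assert np.isfinite(row["MolWt"])


# -- fingerprints -----------------------------------------------------------


def test_circular_fp_radius0_separates_cco_ccc():
    bundle = compute_circular_fp(["CCO", "CCC"], radius=0)
    assert not np.array_equal(bundle.matrix[0], bundle.matrix[1])


def test_circular_fp_width_and_determinism():
    bundle = compute_circular_fp(["CCO", "CCO"])
    assert bundle.matrix.shape == (2, 2048)
    assert np.array_equal(bundle.matrix[0], bundle.matrix[1])
    assert set(np.unique(bundle.matrix)) <= {0.0, 1.0}


def test_circular_fp_parameter_validation():
    with pytest.raises(ValueError):
        compute_circular_fp(["C"], radius=-1)
    with pytest.raises(ValueError):
        compute_circular_fp(["C"], n_bits=4)


def test_maccs_aromatic_key():
    benzene = compute_maccs_fp(["c1ccccc1"]).matrix[0]
    methane = compute_maccs_fp(["C"]).matrix[0]
    # key 162 is the aromaticity key in the public 166-key set
    assert benzene[162] == 1.0
    assert methane[162] == 0.0
    assert methane.sum() <= 3  # methane sets almost nothing


def test_maccs_determinism():
    a = compute_maccs_fp(["CC(=O)O"]).matrix
    b = compute_maccs_fp(["CC(=O)O"]).matrix
    assert np.array_equal(a, b)


# -- graphs -----------------------------------------------------------------


def test_graph_path_molecule():
    g = featurize_graph("CCO")
    assert g.n_nodes == 3 and g.n_edges == 2
    assert g.node_features[:, 0].tolist() == [6.0, 6.0, 8.0]


def test_graph_benzene_conjugation():
    g = featurize_graph("c1ccccc1")
    assert g.n_nodes == 6 and g.n_edges == 6
    assert np.all(g.edge_features[:, 1] == 1.0)  # all bonds conjugated
    assert np.all(g.edge_features[:, 0] == 4.0)  # aromatic bond code


def test_graph_single_atom():
    g = featurize_graph("C")
    assert g.n_nodes == 1 and g.n_edges == 0


def test_graph_edges_reference_valid_nodes(small_smiles):
    for s in small_smiles[:20]:
        g = featurize_graph(s)
        if g.n_edges:
            assert g.edges.min() >= 0 and g.edges.max() < g.n_nodes
            assert np.all(g.edges[:, 0] < g.edges[:, 1])  # stored once, i < j


# -- tokens -----------------------------------------------------------------


def test_vocabulary_characters_and_specials():
    vocab = build_vocabulary(["CCO", "CCN"])
    assert set(vocab.characters) == {"<pad>", "<unk>", "<s>", "C", "O", "N"}


def test_nearest_rank_percentile_definition():
    lengths = list(range(1, 101))
    assert nearest_rank_percentile(lengths, 95) == 95
    assert nearest_rank_percentile([7], 95) == 7


def test_vocabulary_output_length_is_percentile():
    corpus = ["C" * n for n in range(1, 101)]
    assert build_vocabulary(corpus, 95).output_length == 95


def test_empty_corpus_rejected():
    with pytest.raises(ValueError):
        build_vocabulary([])


def test_vectorize_pads_truncates_and_round_trips():
    vocab = build_vocabulary(["CCO", "CCN", "CCCCCC"])
    empty = vectorize_smiles("", vocab)
    assert np.all(empty.token_ids == vocab.pad_id)
    long = vectorize_smiles("C" * 50, vocab)
    assert len(long.token_ids) == vocab.output_length
    short = vectorize_smiles("CON", vocab)
    assert devectorize(short, vocab) == "CON"


def test_unknown_character_maps_to_unk():
    vocab = build_vocabulary(["CCO"])
    ids = vectorize_smiles("Z", vocab).token_ids
    assert ids[0] == vocab.unk_id


# -- latent -----------------------------------------------------------------


def test_hashed_encoder_contract():
    enc = HashedNGramEncoder(width=64)
    bundle = latent_encode(["CCO", "CCO", "c1ccccc1"], enc)
    assert bundle.matrix.shape == (3, 64)
    assert np.array_equal(bundle.matrix[0], bundle.matrix[1])
    assert not np.array_equal(bundle.matrix[0], bundle.matrix[2])


def test_latent_requires_handle():
    with pytest.raises(ValueError, match="surrogate"):
        latent_encode(["C"], None)


def test_autoencoder_surrogate(small_smiles):
    ae = NGramAutoencoder(width=16, input_width=64, epochs=50, seed=3)
    ae.fit(small_smiles[:80])
    a = ae.encode(small_smiles[:5])
    b = ae.encode(small_smiles[:5])
    assert a.shape == (5, 16)
    assert np.array_equal(a, b)
    with pytest.raises(RuntimeError):
        NGramAutoencoder(width=4, input_width=16).encode(["C"])


# -- preprocessing ----------------------------------------------------------


def _bundle(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return FeatureBundle(
        "descriptors", matrix, [f"f{j}" for j in range(matrix.shape[1])]
    )


def test_constant_and_duplicate_columns_dropped(rng):
    base = rng.normal(size=(40, 1)) * 3
    X = np.hstack([base, base, np.full((40, 1), 7.0), rng.normal(size=(40, 1)) * 2])
    train, = preprocess_features(_bundle(X))
    # constant dropped; exactly one of the duplicated pair kept
    assert train.matrix.shape[1] == 2


def test_standardization_and_retention_contract(rng):
    X = rng.normal(size=(60, 5)) * np.array([1, 2, 3, 4, 5])
    prep = FeaturePreprocessor().fit(_bundle(X))
    train = prep.transform(_bundle(X))
    assert np.allclose(train.matrix.mean(0), 0, atol=1e-9)
    assert np.allclose(train.matrix.std(0), 1, atol=1e-9)
    kept = X[:, prep.kept_indices_]
    assert np.all(kept.var(0) >= 0.1)
    corr = np.corrcoef(kept, rowvar=False)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    assert np.all(np.abs(off) <= 0.9)


def test_fit_apply_separation(rng):
    X_train = rng.normal(size=(50, 3))
    X_test = rng.normal(size=(20, 3)) + 5.0
    train, test = preprocess_features(_bundle(X_train), _bundle(X_test))
    # held-out data transformed with training statistics, not its own
    assert np.abs(test.matrix.mean(0)).min() > 1.0
    assert np.allclose(train.matrix.mean(0), 0, atol=1e-9)


def test_missing_cells_imputed_with_training_median(rng):
    X = rng.normal(size=(30, 2)) * 4
    X[3, 0] = np.nan
    train, = preprocess_features(_bundle(X))
    assert np.isfinite(train.matrix).all()


def test_all_features_dropped_is_hard_error():
    X = np.ones((20, 3)) * 2.0  # all constant
    with pytest.raises(ValueError):
        preprocess_features(_bundle(X))
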