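import numpy as np
import pytest
from rdkit import Chem

from aopqsar.assay_labeling import aggregate_hitcalls
from aopqsar.synthetic_data import (
    DEFAULT_TOXICOPHORE,
    AssaySpec,
    InfeasiblePatternError,
    SyntheticConfig,
    generate_assay_matrix,
    generate_benchmark,
    generate_library,
    preset_config,
)


def test_exact_class_counts_and_valid_smiles(small_library):
    compounds, truth = small_library
    assert len(compounds) == 200 and truth.sum() == 60
    assert len({c.canonical_smiles for c in compounds}) == 200
    for c in compounds[:50]:
        assert Chem.MolFromSmiles(c.canonical_smiles) is not None


def test_toxicophore_defines_activity_exactly(small_library):
    compounds, truth = small_library
    pattern = Chem.MolFromSmarts(DEFAULT_TOXICOPHORE)
    for c, t in zip(compounds, truth):
        mol = Chem.MolFromSmiles(c.canonical_smiles)
        assert mol.HasSubstructMatch(pattern) == bool(t)


def test_same_seed_reproduces_library():
    cfg = SyntheticConfig(n_active=10, n_inactive=20, seed=5)
    a, ta = generate_library(cfg)
    b, tb = generate_library(cfg)
    assert [c.canonical_smiles for c in a] == [c.canonical_smiles for c in b]
    assert np.array_equal(ta, tb)


def test_label_noise_flips_expected_count():
    cfg = SyntheticConfig(n_active=50, n_inactive=50, label_noise=0.2, seed=3)
    compounds, truth = generate_library(cfg)
    pattern = Chem.MolFromSmarts(DEFAULT_TOXICOPHORE)
    has = np.array(
        [Chem.MolFromSmiles(c.canonical_smiles).HasSubstructMatch(pattern)
         for c in compounds]
    )
    assert (has != truth).sum() == 20  # exactly 20% flipped


def test_bad_toxicophore_rejected():
    with pytest.raises(InfeasiblePatternError):
        generate_library(SyntheticConfig(10, 10, toxicophore="[[["))


def test_noiseless_assays_recover_truth(small_library):
    compounds, truth = small_library
    cfg = SyntheticConfig(60, 140, assay_specs=[AssaySpec("a0"), AssaySpec("a1")], seed=1)
    matrix = generate_assay_matrix(compounds, truth, cfg)
    ds = aggregate_hitcalls(matrix, matrix.assays)
    assert np.array_equal(ds.labels, truth)


def test_all_missing_assays_exclude_everyone(small_library):
    compounds, truth = small_library
    cfg = SyntheticConfig(
        60, 140, assay_specs=[AssaySpec("a0", missing_rate=1.0)], seed=1
    )
    matrix = generate_assay_matrix(compounds, truth, cfg)
    ds = aggregate_hitcalls(matrix, matrix.assays)
    assert len(ds) == 0 and len(ds.excluded) == 200


def test_uninformative_assays_give_chance_level_cv():
    """Equal hit probabilities for both classes: labels carry no
    structural signal, so CV balanced accuracy sits at 0.5."""
    from aopqsar.encoders import compute_circular_fp
    from aopqsar.evaluation import repeated_kfold_cv
    from aopqsar.models.baselines import BaselineModel

    cfg = SyntheticConfig(
        n_active=500,
        n_inactive=1500,
        assay_specs=[AssaySpec("a0", p_hit_active=0.4, p_hit_inactive=0.4)],
        seed=21,
    )
    compounds, truth = generate_library(cfg)
    matrix = generate_assay_matrix(compounds, truth, cfg)
    ds = aggregate_hitcalls(matrix, matrix.assays)
    X = compute_circular_fp(ds.compounds).matrix
    result = repeated_kfold_cv(
        lambda s: BaselineModel("logreg", seed=s), X, ds.labels,
        k=3, iterations=1, seed=2,
    )
    assert result.mean["balanced_accuracy"] == pytest.approx(0.5, abs=0.03)


def test_held_out_accuracy_non_increasing_in_label_noise():
    from aopqsar.encoders import compute_circular_fp
    from aopqsar.evaluation import SplitPlan, compute_metrics, stratified_split
    from aopqsar.models.baselines import BaselineModel
    from aopqsar.assay_labeling import EndpointDataset

    scores = []
    for noise in (0.0, 0.1, 0.3):
        cfg = SyntheticConfig(n_active=200, n_inactive=400, label_noise=noise, seed=31)
        compounds, truth = generate_library(cfg)
        ds = EndpointDataset("noise", compounds, truth, n_assays_used=1)
        train_ds, test_ds = stratified_split(ds, SplitPlan(0.2, seed=1))
        model = BaselineModel("logreg", seed=0).fit(
            compute_circular_fp(train_ds.compounds).matrix, train_ds.labels
        )
        proba = model.predict_proba(compute_circular_fp(test_ds.compounds).matrix)
        scores.append(
            compute_metrics(test_ds.labels, (proba >= 0.5).astype(int)).balanced_accuracy
        )
    assert scores[0] >= 0.95  # noise-free signal is recoverable
    assert scores[0] >= scores[1] - 0.03
    assert scores[1] >= scores[2] - 0.03


@pytest.mark.parametrize(
    "preset,n,pct_active",
    [("mie1_like", 232, 79), ("ke1_like", 636, 30)],
)
def test_presets_match_published_shapes(preset, n, pct_active):
    from aopqsar.assay_labeling import dataset_summary

    ds = generate_benchmark(preset, seed=4)
    s = dataset_summary(ds)
    assert (s.n, s.pct_active) == (n, pct_active)


def test_preset_seeds_give_nearly_disjoint_libraries():
    a = {c.canonical_smiles for c in generate_benchmark("mie1_like", seed=0).compounds}
    b = {c.canonical_smiles for c in generate_benchmark("mie1_like", seed=1).compounds}
    assert len(a & b) / len(a) < 0.05


def test_preset_files_round_trip(tmp_path):
    generate_benchmark("mie1_like", seed=2, out_dir=tmp_path)
    assert (tmp_path / "mie1_like_compounds.csv").exists()
    assert (tmp_path / "mie1_like_hitcalls.csv").exists()
    assert (tmp_path / "mie1_like_endpoints.yaml").exists()

    import pandas as pd

    table = pd.read_csv(tmp_path / "mie1_like_compounds.csv")
    assert len(table) == 232


def test_unknown_preset_rejected():
    with pytest.raises(KeyError):
        preset_config("ke9_like")
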