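"""Reference benchmark experiments on the synthetic endpoint presets.

These functions bundle the package's end-to-end study conditions so the
same computation backs the test suite, the acceptance script and the
README numbers: generate a noise-free KE2-like benchmark (activity =
planted toxicophore), split it stratified 90-10, train the relevant
models, and report held-out balanced accuracy.

Network comparisons run on a stratified subset of the KE2-like library
with compact layer widths (documented in the methods note) so the full
battery stays tractable on one CPU; the architectures and training
schedule are the package defaults otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay_labeling import EndpointDataset
from .augmentation import augment_training_set
from .encoders import (
    HashedNGramEncoder,
    build_vocabulary,
    compute_circular_fp,
    compute_descriptors,
    compute_maccs_fp,
    latent_encode,
    preprocess_features,
    vectorize_corpus,
)
from .encoders.tabular import FeatureBundle
from .evaluation import SplitPlan, compute_metrics, stratified_split
from .models import EncodedDataset, ModelSpec, TrainConfig, predict, train
from .models.baselines import BaselineModel
from .synthetic_data import generate_benchmark, preset_config, generate_library
from .assay_labeling import aggregate_hitcalls
from .synthetic_data import generate_assay_matrix

#: compact network dimensions used by the benchmark battery
NEURAL_HP = {
    "dnn": {"hidden": [128, 64]},
    "nlp_seq": {"embed_dim": 32, "lstm_hidden": 64, "gru_hidden": 32},
    "nlp_small": {"embed_dim": 16, "lstm_hidden": 32, "gru_hidden": 16},
    "multimodal": {
        "embed_dim": 32, "lstm_hidden": 64, "gru_hidden": 32,
        "branch_hidden": {"maccs_fp": [64], "circular_fp": [256, 64],
                          "descriptors": [128, 64], "latent": [64]},
        "head_hidden": [128, 32],
    },
}

BENCH_TRAIN = dict(max_epochs=20, plateau_patience=4, early_stop_patience=8)


def _subsample(ds: EndpointDataset, n: int, seed: int) -> EndpointDataset:
    if n >= len(ds):
        return ds
    rng = np.random.default_rng(seed)
    labels = ds.labels
    take: list[int] = []
    classes, counts = np.unique(labels, return_counts=True)
    shares = counts * n / len(ds)
    alloc = np.floor(shares).astype(int)
    order = np.argsort(-(shares - alloc), kind="stable")
    for i in range(n - alloc.sum()):
        alloc[order[i]] += 1
    for cls, n_cls in zip(classes, alloc):
        cls_idx = np.flatnonzero(labels == cls)
        take.extend(rng.permutation(cls_idx)[:n_cls].tolist())
    return ds.subset(np.sort(np.array(take, dtype=int)), partition=None)


def fingerprint_baseline_ba(seed: int = 0) -> dict:
    """Circular-fingerprint logistic baseline on the noise-free KE2-like
    benchmark, stratified 90-10; returns held-out metrics and sizes."""
    ds = generate_benchmark("ke2_like", seed=seed)
    train_ds, test_ds = stratified_split(ds, SplitPlan(0.10, seed=seed + 1))
    fp_train = compute_circular_fp(train_ds.compounds).matrix
    fp_test = compute_circular_fp(test_ds.compounds).matrix
    model = BaselineModel("logreg", seed=seed).fit(fp_train, train_ds.labels)
    proba = model.predict_proba(fp_test)
    report = compute_metrics(test_ds.labels, (proba >= 0.5).astype(int))
    return {
        "balanced_accuracy": report.balanced_accuracy,
        "n": len(ds),
        "n_train": len(train_ds),
        "n_test": len(test_ds),
    }


def _encode_for_networks(train_ds, test_ds, seed):
    vocab = build_vocabulary([c.canonical_smiles for c in train_ds.compounds])
    latent = HashedNGramEncoder(width=64)
    desc_tr = compute_descriptors(train_ds.compounds)
    desc_te = compute_descriptors(test_ds.compounds)
    desc_tr, desc_te = preprocess_features(desc_tr, desc_te)

    def encoded(ds_part, desc):
        return EncodedDataset(
            ds_part.labels,
            tabular={
                "circular_fp": compute_circular_fp(ds_part.compounds).matrix,
                "maccs_fp": compute_maccs_fp(ds_part.compounds).matrix,
                "descriptors": desc.matrix,
                "latent": latent_encode(ds_part.compounds, latent).matrix,
            },
            tokens=vectorize_corpus(
                [c.canonical_smiles for c in ds_part.compounds], vocab
            ),
            vocab_size=len(vocab),
        )
    return encoded(train_ds, desc_tr), encoded(test_ds, desc_te), vocab


@dataclass
class NeuralComparison:
    branch_ba: dict[str, float]
    multimodal_ba: float

    @property
    def best_branch_ba(self) -> float:
        return max(self.branch_ba.values())


def neural_branch_comparison(seed: int = 0, n: int = 1200) -> NeuralComparison:
    """Held-out BA of each single-representation dense network vs the
    five-branch multimodal network, on a stratified KE2-like subset."""
    ds = _subsample(generate_benchmark("ke2_like", seed=seed), n, seed + 2)
    train_ds, test_ds = stratified_split(ds, SplitPlan(0.10, seed=seed + 3))
    enc_tr, enc_te, _ = _encode_for_networks(train_ds, test_ds, seed)
    cfg = TrainConfig(seed=seed, **BENCH_TRAIN)
    branch_ba = {}
    for enc_name in ("circular_fp", "maccs_fp", "descriptors", "latent"):
        spec = ModelSpec("dnn", [enc_name], dict(NEURAL_HP["dnn"]), seed=seed)
        tm = train(spec, enc_tr, cfg)
        _, labels = predict(tm, enc_te)
        branch_ba[enc_name] = compute_metrics(
            test_ds.labels, labels
        ).balanced_accuracy
    spec = ModelSpec(
        "multimodal",
        ["maccs_fp", "circular_fp", "descriptors", "latent", "smiles"],
        dict(NEURAL_HP["multimodal"]),
        seed=seed,
    )
    tm = train(spec, enc_tr, cfg)
    _, labels = predict(tm, enc_te)
    mm_ba = compute_metrics(test_ds.labels, labels).balanced_accuracy
    return NeuralComparison(branch_ba, mm_ba)


def augmentation_comparison(seed: int = 0, n: int = 400, factor: int = 10) -> dict:
    """Sequence model trained with vs without SMILES-enumeration
    augmentation of the training partition; same held-out fold."""
    ds = _subsample(generate_benchmark("ke2_like", seed=seed), n, seed + 4)
    train_ds, test_ds = stratified_split(ds, SplitPlan(0.10, seed=seed + 5))
    aug = augment_training_set(train_ds, factor=factor, seed=seed + 6)
    # vocabulary from the augmented corpus so enumerated renderings tokenize
    vocab = build_vocabulary(aug.smiles)
    test_smiles = [c.canonical_smiles for c in test_ds.compounds]
    enc_plain = EncodedDataset(
        train_ds.labels,
        tokens=vectorize_corpus(
            [c.canonical_smiles for c in train_ds.compounds], vocab
        ),
        vocab_size=len(vocab),
    )
    enc_aug = EncodedDataset(
        aug.labels, tokens=vectorize_corpus(aug.smiles, vocab), vocab_size=len(vocab)
    )
    enc_test = EncodedDataset(
        test_ds.labels, tokens=vectorize_corpus(test_smiles, vocab),
        vocab_size=len(vocab),
    )
    hp = dict(NEURAL_HP["nlp_small"])
    cfg = TrainConfig(seed=seed, **BENCH_TRAIN)
    out = {}
    for name, enc in (("plain", enc_plain), ("augmented", enc_aug)):
        tm = train(ModelSpec("nlp_seq", ["smiles"], hp, seed=seed), enc, cfg)
        _, labels = predict(tm, enc_test)
        out[name] = compute_metrics(test_ds.labels, labels).balanced_accuracy
    out["n_train_plain"] = len(enc_plain)
    out["n_train_augmented"] = len(enc_aug)
    return out


def ad_discard_rates(seed: int = 0, n: int = 600) -> dict:
    """Consensus AD discard rate on an in-distribution split vs a
    deliberately shifted copy of the same features."""
    from .applicability_domain import assess_all

    cfg = preset_config("ke1_like", seed=seed)
    compounds, truth = generate_library(cfg)
    matrix = generate_assay_matrix(compounds, truth, cfg)
    ds = aggregate_hitcalls(matrix, matrix.assays, endpoint_name="KE1")
    ds = _subsample(ds, n, seed)
    train_ds, test_ds = stratified_split(ds, SplitPlan(0.2, seed=seed + 7))
    feats = {
        "latent": (
            latent_encode(train_ds.compounds, HashedNGramEncoder(64)).matrix,
            latent_encode(test_ds.compounds, HashedNGramEncoder(64)).matrix,
        ),
        "maccs_fp": (
            compute_maccs_fp(train_ds.compounds).matrix,
            compute_maccs_fp(test_ds.compounds).matrix,
        ),
    }
    train_f = {k: v[0] for k, v in feats.items()}
    test_f = {k: v[1] for k, v in feats.items()}
    verdict = assess_all(train_f, test_f)
    shifted = {k: v + 25.0 for k, v in test_f.items()}
    verdict_shift = assess_all(train_f, shifted)
    return {
        "in_distribution": float(1.0 - verdict.consensus_keep.mean()),
        "shifted": float(1.0 - verdict_shift.consensus_keep.mean()),
    }
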