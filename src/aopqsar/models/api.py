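"""Uniform model interface: specs, building, training, prediction.

``ModelSpec`` names a family and the encoders it consumes; ``build_model``
constructs the untrained model; ``train`` dispatches to either the
scikit-learn-style baselines (with optional in-fold oversampling) or the
network training loop with its plateau schedule; ``predict`` emits
activity probabilities and hard labels at the 0.5 threshold (ties go to
active: label = probability >= 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..encoders.graphs import MolecularGraph
from ..imbalance import OversampleConfig, oversample
from ..nn.training import NetworkTrainConfig, TrainingHistory, fit_network, predict_proba
from .baselines import BASELINE_FAMILIES, BaselineModel
from .networks import (
    ArrayData,
    DNNClassifier,
    GraphData,
    MPNNClassifier,
    MultimodalClassifier,
    MultimodalData,
    SequenceClassifier,
    TokenData,
)

NETWORK_FAMILIES = ("dnn", "nlp_seq", "mpnn", "multimodal")

#: encoder names a family may consume
_TABULAR = ("descriptors", "circular_fp", "maccs_fp", "latent")
_FAMILY_ENCODERS = {
    **{f: _TABULAR for f in BASELINE_FAMILIES},
    "dnn": _TABULAR,
    "nlp_seq": ("smiles",),
    "mpnn": ("graph",),
    "multimodal": ("maccs_fp", "circular_fp", "descriptors", "latent", "smiles"),
}


@dataclass
class ModelSpec:
    family: str
    encoder_names: list[str]
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILY_ENCODERS:
            raise ValueError(f"unknown family {self.family!r}")
        allowed = set(_FAMILY_ENCODERS[self.family])
        bad = set(self.encoder_names) - allowed
        if bad:
            raise ValueError(
                f"family {self.family!r} cannot consume encoders {sorted(bad)}; "
                f"allowed: {sorted(allowed)}"
            )
        if self.family == "multimodal":
            if set(self.encoder_names) != allowed:
                raise ValueError(
                    "multimodal requires exactly the five branch encoders "
                    f"{sorted(allowed)}"
                )
        elif len(self.encoder_names) != 1:
            raise ValueError(f"family {self.family!r} takes exactly one encoder")


@dataclass
class TrainConfig(NetworkTrainConfig):
    """Network schedule plus the baseline-side oversampling hook."""

    oversample: OversampleConfig | None = None


@dataclass
class EncodedDataset:
    """Row-aligned encoded views of one compound set."""

    labels: np.ndarray
    tabular: dict[str, np.ndarray] = field(default_factory=dict)
    tokens: np.ndarray | None = None  # (n, T) int token ids
    graphs: list[MolecularGraph] | None = None
    vocab_size: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self):
        return len(self.labels)

    def view(self, spec: ModelSpec):
        """The model-consumable container for ``spec``'s encoders."""
        if spec.family == "mpnn":
            if self.graphs is None:
                raise ValueError("dataset has no graph encoding")
            return GraphData(self.graphs)
        if spec.family == "nlp_seq":
            if self.tokens is None:
                raise ValueError("dataset has no token encoding")
            return TokenData(self.tokens)
        if spec.family == "multimodal":
            parts: dict[str, object] = {
                name: ArrayData(self._tab(name))
                for name in MultimodalClassifier.TABULAR_BRANCHES
            }
            parts[MultimodalClassifier.SEQUENCE_BRANCH] = TokenData(self.tokens)
            return MultimodalData(parts)
        return ArrayData(self._tab(spec.encoder_names[0]))

    def _tab(self, name: str) -> np.ndarray:
        if name not in self.tabular:
            raise ValueError(f"dataset has no {name!r} features")
        return self.tabular[name]


@dataclass
class TrainedModel:
    spec: ModelSpec
    model: object
    history: TrainingHistory | None = None

    def is_network(self) -> bool:
        return self.spec.family in NETWORK_FAMILIES


def build_model(spec: ModelSpec, dataset: EncodedDataset | None = None):
    """Construct the untrained model for ``spec``.

    Network input widths are read from ``dataset`` (or from
    ``spec.hyperparameters`` when building without data).
    """
    hp = dict(spec.hyperparameters)
    if spec.family in BASELINE_FAMILIES:
        return BaselineModel(spec.family, hp, seed=spec.seed)
    if spec.family == "dnn":
        n_in = hp.pop("n_in", None)
        if n_in is None:
            n_in = dataset._tab(spec.encoder_names[0]).shape[1]
        return DNNClassifier(n_in, seed=spec.seed, **hp)
    if spec.family == "nlp_seq":
        vocab_size = hp.pop("vocab_size", None) or dataset.vocab_size
        return SequenceClassifier(vocab_size, seed=spec.seed, **hp)
    if spec.family == "mpnn":
        return MPNNClassifier(seed=spec.seed, **hp)
    if spec.family == "multimodal":
        widths = hp.pop("branch_inputs", None)
        if widths is None:
            widths = {
                name: dataset._tab(name).shape[1]
                for name in MultimodalClassifier.TABULAR_BRANCHES
            }
        vocab_size = hp.pop("vocab_size", None) or dataset.vocab_size
        return MultimodalClassifier(widths, vocab_size, seed=spec.seed, **hp)
    raise ValueError(spec.family)  # pragma: no cover


def train(
    spec: ModelSpec, dataset: EncodedDataset, cfg: TrainConfig | None = None
) -> TrainedModel:
    cfg = cfg or TrainConfig()
    model = build_model(spec, dataset)
    if spec.family in BASELINE_FAMILIES:
        X = dataset._tab(spec.encoder_names[0])
        y = dataset.labels
        if cfg.oversample is not None:
            X, y = oversample(X, y, cfg.oversample)
        model.fit(X, y)
        return TrainedModel(spec, model)
    history = fit_network(model, dataset.view(spec), dataset.labels, cfg)
    return TrainedModel(spec, model, history)


def predict(trained: TrainedModel, dataset: EncodedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Activity probabilities and labels (label = probability >= 0.5)."""
    if trained.is_network():
        proba = predict_proba(trained.model, dataset.view(trained.spec))
    else:
        proba = trained.model.predict_proba(
            dataset._tab(trained.spec.encoder_names[0])
        )
    return proba, (proba >= 0.5).astype(int)
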