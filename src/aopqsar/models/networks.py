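"""Neural architectures: dense, character-sequence, message-passing, multimodal.

Every classifier exposes ``forward(batch) -> logits`` plus an
``output_bias`` tensor (the final layer's bias, used for class-ratio
initialization) and consumes batches produced by the matching
:class:`~aopqsar.nn.training.NetworkData` container defined here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..encoders.graphs import MolecularGraph
from ..nn import autodiff as ad
from ..nn.autodiff import Tensor
from ..nn.layers import GRU, LSTM, MLP, Dense, Dropout, Embedding, Module

# fixed scales that bring raw node features (atomic number, valence, H
# count, hybridization code) to order one for the message-passing input
_NODE_SCALE = np.array([0.1, 0.25, 0.25, 0.2])


# ---------------------------------------------------------------------------
# batch containers


@dataclass
class ArrayData:
    X: np.ndarray

    def __len__(self):
        return len(self.X)

    def take(self, indices):
        return self.X[np.asarray(indices, dtype=int)]


@dataclass
class TokenData:
    ids: np.ndarray  # (n, T) int

    def __len__(self):
        return len(self.ids)

    def take(self, indices):
        return self.ids[np.asarray(indices, dtype=int)]


@dataclass
class BatchedGraphs:
    node_x: np.ndarray  # (N, 4) scaled node features
    edge_src: np.ndarray  # directed (both ways)
    edge_dst: np.ndarray
    edge_feat: np.ndarray  # (E, 2)
    graph_ids: np.ndarray  # (N,)
    n_graphs: int
    node_counts: np.ndarray  # (n_graphs,)


@dataclass
class GraphData:
    graphs: list[MolecularGraph]

    def __len__(self):
        return len(self.graphs)

    def take(self, indices) -> BatchedGraphs:
        nodes, srcs, dsts, feats, gids, counts = [], [], [], [], [], []
        offset = 0
        for b, i in enumerate(np.asarray(indices, dtype=int)):
            g = self.graphs[i]
            n = g.n_nodes
            nodes.append(g.node_features * _NODE_SCALE)
            if g.n_edges:
                e = g.edges + offset
                srcs.append(np.concatenate([e[:, 0], e[:, 1]]))
                dsts.append(np.concatenate([e[:, 1], e[:, 0]]))
                feats.append(np.vstack([g.edge_features, g.edge_features]))
            gids.append(np.full(n, b))
            counts.append(n)
            offset += n
        return BatchedGraphs(
            np.vstack(nodes),
            np.concatenate(srcs) if srcs else np.empty(0, dtype=int),
            np.concatenate(dsts) if dsts else np.empty(0, dtype=int),
            np.vstack(feats) if feats else np.empty((0, 2)),
            np.concatenate(gids),
            len(indices),
            np.array(counts, dtype=float),
        )


@dataclass
class MultimodalData:
    parts: dict[str, object]  # branch name -> ArrayData / TokenData

    def __len__(self):
        return len(next(iter(self.parts.values())))

    def take(self, indices):
        return {name: part.take(indices) for name, part in self.parts.items()}


# ---------------------------------------------------------------------------
# architectures


class DNNClassifier(Module):
    """Fully connected stack with dropout; hidden widths are powers of 2."""

    def __init__(self, n_in: int, hidden: list[int] | None = None,
                 dropout_rate: float = 0.2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.body = MLP(n_in, hidden or [512, 256, 128], rng, dropout_rate)
        self.head = Dense(self.body.n_out, 1, rng, scale=0.05)

    @property
    def output_bias(self) -> Tensor:
        return self.head.b

    def forward(self, X: np.ndarray) -> Tensor:
        return self.head(self.body(Tensor(X)))


class _SequenceEncoder(Module):
    """Embedding -> LSTM -> GRU; returns the final GRU hidden state."""

    def __init__(self, vocab_size: int, embed_dim: int, lstm_hidden: int,
                 gru_hidden: int, rng: np.random.Generator):
        self.embedding = Embedding(vocab_size, embed_dim, rng)
        self.lstm = LSTM(embed_dim, lstm_hidden, rng)
        self.gru = GRU(lstm_hidden, gru_hidden, rng)
        self.n_out = gru_hidden

    def __call__(self, ids: np.ndarray) -> Tensor:
        xs = [self.embedding(ids[:, t]) for t in range(ids.shape[1])]
        hs = self.lstm(xs)
        return self.gru(hs)[-1]


class SequenceClassifier(Module):
    """Character-level SMILES model: embedding, LSTM and GRU layers, dense head."""

    def __init__(self, vocab_size: int, embed_dim: int = 64, lstm_hidden: int = 128,
                 gru_hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = _SequenceEncoder(vocab_size, embed_dim, lstm_hidden,
                                        gru_hidden, rng)
        self.head = Dense(self.encoder.n_out, 1, rng, scale=0.05)

    @property
    def output_bias(self) -> Tensor:
        return self.head.b

    def forward(self, ids: np.ndarray) -> Tensor:
        return self.head(self.encoder(ids))


class MPNNClassifier(Module):
    """Message passing on molecular graphs with gated state updates.

    For ``n_rounds`` iterations each atom aggregates messages from its
    bonded neighbors (conditioned on bond features), updates its state
    through a GRU-style gate, and the readout concatenates mean- and
    sum-pooled node states. ``n_rounds=0`` degenerates to a readout of the
    projected raw node features.
    """

    def __init__(self, hidden: int = 64, n_rounds: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_rounds = n_rounds
        self.project = Dense(4, hidden, rng)
        self.message = Dense(hidden + 2, hidden, rng)
        self.gate = Dense(2 * hidden, hidden, rng)
        self.candidate = Dense(2 * hidden, hidden, rng)
        self.head_mlp = MLP(2 * hidden, [64], rng, dropout_rate=0.1)
        self.head = Dense(self.head_mlp.n_out, 1, rng, scale=0.05)

    @property
    def output_bias(self) -> Tensor:
        return self.head.b

    def forward(self, batch: BatchedGraphs) -> Tensor:
        h = ad.tanh(self.project(Tensor(batch.node_x)))
        n_nodes = batch.node_x.shape[0]
        for _ in range(self.n_rounds):
            if len(batch.edge_src) == 0:
                break
            src_h = ad.gather_rows(h, batch.edge_src)
            msg_in = ad.concat([src_h, Tensor(batch.edge_feat)], axis=1)
            msg = ad.relu(self.message(msg_in))
            agg = ad.segment_sum(msg, batch.edge_dst, n_nodes)
            both = ad.concat([h, agg], axis=1)
            z = ad.sigmoid(self.gate(both))
            cand = ad.tanh(self.candidate(both))
            h = ad.add(ad.mul(z, cand), ad.mul(ad.add(1.0, ad.mul(z, -1.0)), h))
        summed = ad.segment_sum(h, batch.graph_ids, batch.n_graphs)
        mean = ad.mul(summed, Tensor(1.0 / batch.node_counts[:, None]))
        pooled = ad.concat([mean, summed], axis=1)
        return self.head(self.head_mlp(pooled))


class MultimodalClassifier(Module):
    """Five-branch fusion network merged by concatenation.

    One dense branch per tabular representation (MACCS keys, circular
    fingerprint, descriptors, latent codes) plus a character-sequence
    branch; the branch outputs are concatenated and passed through a dense
    head. All modules are trained jointly.
    """

    TABULAR_BRANCHES = ("maccs_fp", "circular_fp", "descriptors", "latent")
    SEQUENCE_BRANCH = "smiles"

    def __init__(
        self,
        branch_inputs: dict[str, int],  # tabular branch -> input width
        vocab_size: int,
        branch_hidden: dict[str, list[int]] | None = None,
        embed_dim: int = 64,
        lstm_hidden: int = 128,
        gru_hidden: int = 64,
        head_hidden: list[int] | None = None,
        dropout_rate: float = 0.2,
        seed: int = 0,
    ):
        missing = set(self.TABULAR_BRANCHES) - set(branch_inputs)
        if missing:
            raise ValueError(f"missing branch input widths: {sorted(missing)}")
        rng = np.random.default_rng(seed)
        defaults = {
            "maccs_fp": [128, 64],
            "circular_fp": [512, 128],
            "descriptors": [256, 128],
            "latent": [128, 64],
        }
        branch_hidden = {**defaults, **(branch_hidden or {})}
        self.branches: dict[str, MLP] = {
            name: MLP(branch_inputs[name], branch_hidden[name], rng, dropout_rate)
            for name in self.TABULAR_BRANCHES
        }
        self.sequence = _SequenceEncoder(vocab_size, embed_dim, lstm_hidden,
                                         gru_hidden, rng)
        merged = sum(m.n_out for m in self.branches.values()) + self.sequence.n_out
        self.head_mlp = MLP(merged, head_hidden or [256, 64], rng, dropout_rate)
        self.head = Dense(self.head_mlp.n_out, 1, rng, scale=0.05)

    @property
    def n_branches(self) -> int:
        return len(self.branches) + 1

    @property
    def output_bias(self) -> Tensor:
        return self.head.b

    def forward(self, batch: dict[str, np.ndarray]) -> Tensor:
        outs = [
            self.branches[name](Tensor(batch[name]))
            for name in self.TABULAR_BRANCHES
        ]
        outs.append(self.sequence(batch[self.SEQUENCE_BRANCH]))
        return self.head(self.head_mlp(ad.concat(outs, axis=1)))
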