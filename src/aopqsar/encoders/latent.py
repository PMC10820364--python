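"""Latent (learned) molecular representations behind a pluggable interface.

The downstream pipeline treats a latent encoder exactly like a descriptor
calculator: a fixed-width numeric vector per SMILES. Any object with an
``encode(list_of_smiles) -> matrix`` method and a ``width`` attribute can
be plugged in — including an externally pretrained sequence autoencoder
loaded by the user. Two encoders ship with the package:

``HashedNGramEncoder``
    Deterministic, training-free: character n-gram counts signed-hashed
    into a fixed-width vector and L2-normalized. Stable across processes
    (hashing is md5-based, not Python's salted ``hash``).

``NGramAutoencoder``
    A small dense autoencoder over the hashed n-gram counts, trainable on
    any SMILES corpus; the bottleneck activations are the latent code.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .tabular import FeatureBundle
from ..chem_curation import CuratedCompound


@runtime_checkable
class LatentEncoder(Protocol):
    width: int

    def encode(self, smiles: Sequence[str]) -> np.ndarray: ...


def _ngrams(s: str, n_min: int, n_max: int):
    for n in range(n_min, n_max + 1):
        for i in range(len(s) - n + 1):
            yield s[i : i + n]


def _hash_ngram(gram: str) -> tuple[int, int]:
    digest = hashlib.md5(gram.encode("utf-8")).digest()
    idx = int.from_bytes(digest[:8], "little")
    sign = 1 if digest[8] & 1 else -1
    return idx, sign


@dataclass
class HashedNGramEncoder:
    """Signed-hash character n-gram projection (deterministic, no training)."""

    width: int = 128
    n_min: int = 1
    n_max: int = 3

    def encode(self, smiles: Sequence[str]) -> np.ndarray:
        mat = np.zeros((len(smiles), self.width))
        for r, s in enumerate(smiles):
            for gram in _ngrams(s, self.n_min, self.n_max):
                idx, sign = _hash_ngram(gram)
                mat[r, idx % self.width] += sign
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        # scale so per-feature variances are order one (descriptor-like)
        return mat / norms * np.sqrt(self.width)


class NGramAutoencoder:
    """Dense autoencoder on hashed n-gram counts; bottleneck = latent code.

    A deliberately small architecture (input -> tanh bottleneck -> linear
    reconstruction) trained by full-batch gradient descent with momentum;
    on desk-scale corpora this converges in a few hundred epochs.
    """

    def __init__(self, width: int = 64, input_width: int = 256,
                 epochs: int = 300, lr: float = 0.05, seed: int = 0):
        self.width = width
        self.input_width = input_width
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self._base = HashedNGramEncoder(width=input_width)
        self._W1 = self._b1 = self._W2 = self._b2 = None

    def fit(self, corpus: Sequence[str]) -> "NGramAutoencoder":
        X = self._base.encode(corpus)
        rng = np.random.default_rng(self.seed)
        d, h = self.input_width, self.width
        W1 = rng.normal(0, 1.0 / np.sqrt(d), (d, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0, 1.0 / np.sqrt(h), (h, d))
        b2 = np.zeros(d)
        vel = [np.zeros_like(p) for p in (W1, b1, W2, b2)]
        n = X.shape[0]
        for _ in range(self.epochs):
            H = np.tanh(X @ W1 + b1)
            R = H @ W2 + b2
            err = (R - X) / n
            gW2 = H.T @ err
            gb2 = err.sum(0)
            dH = err @ W2.T * (1 - H**2)
            gW1 = X.T @ dH
            gb1 = dH.sum(0)
            for p, v, g in zip((W1, b1, W2, b2), vel, (gW1, gb1, gW2, gb2)):
                v *= 0.9
                v -= self.lr * g
                p += v
        self._W1, self._b1, self._W2, self._b2 = W1, b1, W2, b2
        return self

    def encode(self, smiles: Sequence[str]) -> np.ndarray:
        if self._W1 is None:
            raise RuntimeError("NGramAutoencoder not fitted; call fit(corpus) first")
        X = self._base.encode(smiles)
        return np.tanh(X @ self._W1 + self._b1)


def latent_encode(
    compounds: Sequence[CuratedCompound | str], encoder_handle: LatentEncoder | None
) -> FeatureBundle:
    """Encode compounds through a latent-encoder handle into a FeatureBundle."""
    if encoder_handle is None:
        raise ValueError(
            "no latent encoder provided; plug in a pretrained encoder or use the "
            "bundled surrogates HashedNGramEncoder / NGramAutoencoder"
        )
    smiles = [
        c.canonical_smiles if isinstance(c, CuratedCompound) else c for c in compounds
    ]
    mat = np.asarray(encoder_handle.encode(smiles), dtype=float)
    if mat.shape != (len(smiles), encoder_handle.width):
        raise ValueError("encoder output width does not match its declared width")
    return FeatureBundle(
        "latent", mat, [f"latent_{i}" for i in range(encoder_handle.width)]
    )
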