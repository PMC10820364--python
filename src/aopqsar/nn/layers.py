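"""Layers built on the autodiff Tensor: dense, embedding, LSTM, GRU."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]

        def collect(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        for v in vars(self).values():
            collect(v)
        return mods

    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        if scale is None:
            scale = np.sqrt(2.0 / n_in)  # He init for ReLU bodies
        self.W = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros((1, n_out)), requires_grad=True)

    def __call__(self, x) -> Tensor:
        return ad.add(ad.matmul(x, self.W), self.b)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self._rng = rng

    def __call__(self, x) -> Tensor:
        return ad.dropout(x, self.rate, self._rng, self.training)


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.table = Tensor(rng.normal(0.0, 0.1, (n_tokens, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return ad.gather_rows(self.table, ids)


class LSTM(Module):
    """Single-layer LSTM over a list of per-timestep (batch, n_in) tensors."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        scale = 1.0 / np.sqrt(n_in + n_hidden)
        self.Wx = Tensor(rng.normal(0, scale, (n_in, 4 * n_hidden)), requires_grad=True)
        self.Wh = Tensor(rng.normal(0, scale, (n_hidden, 4 * n_hidden)), requires_grad=True)
        b = np.zeros((1, 4 * n_hidden))
        b[0, n_hidden: 2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        batch = xs[0].shape[0]
        H = self.n_hidden
        h = Tensor(np.zeros((batch, H)))
        c = Tensor(np.zeros((batch, H)))
        outputs: list[Tensor] = []
        for x in xs:
            z = ad.add(ad.add(ad.matmul(x, self.Wx), ad.matmul(h, self.Wh)), self.b)
            i = ad.sigmoid(ad.slice_cols(z, 0, H))
            f = ad.sigmoid(ad.slice_cols(z, H, 2 * H))
            g = ad.tanh(ad.slice_cols(z, 2 * H, 3 * H))
            o = ad.sigmoid(ad.slice_cols(z, 3 * H, 4 * H))
            c = ad.add(ad.mul(f, c), ad.mul(i, g))
            h = ad.mul(o, ad.tanh(c))
            outputs.append(h)
        return outputs


class GRU(Module):
    """Single-layer GRU over a list of per-timestep (batch, n_in) tensors."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        scale = 1.0 / np.sqrt(n_in + n_hidden)
        self.Wx = Tensor(rng.normal(0, scale, (n_in, 3 * n_hidden)), requires_grad=True)
        self.Wh = Tensor(rng.normal(0, scale, (n_hidden, 3 * n_hidden)), requires_grad=True)
        self.b = Tensor(np.zeros((1, 3 * n_hidden)), requires_grad=True)

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        batch = xs[0].shape[0]
        H = self.n_hidden
        h = Tensor(np.zeros((batch, H)))
        outputs: list[Tensor] = []
        for x in xs:
            zx = ad.matmul(x, self.Wx)
            zh = ad.matmul(h, self.Wh)
            r = ad.sigmoid(
                ad.add(ad.add(ad.slice_cols(zx, 0, H), ad.slice_cols(zh, 0, H)),
                       ad.slice_cols(self.b, 0, H))
            )
            u = ad.sigmoid(
                ad.add(ad.add(ad.slice_cols(zx, H, 2 * H), ad.slice_cols(zh, H, 2 * H)),
                       ad.slice_cols(self.b, H, 2 * H))
            )
            n = ad.tanh(
                ad.add(
                    ad.add(ad.slice_cols(zx, 2 * H, 3 * H),
                           ad.mul(r, ad.slice_cols(zh, 2 * H, 3 * H))),
                    ad.slice_cols(self.b, 2 * H, 3 * H),
                )
            )
            h = ad.add(ad.mul(u, h), ad.mul(ad.add(1.0, ad.mul(u, -1.0)), n))
            outputs.append(h)
        return outputs


def is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


class MLP(Module):
    """Dense stack with ReLU + dropout; hidden widths must be powers of 2."""

    def __init__(
        self,
        n_in: int,
        hidden: list[int],
        rng: np.random.Generator,
        dropout_rate: float = 0.2,
        enforce_pow2: bool = True,
    ):
        if enforce_pow2:
            bad = [w for w in hidden if not is_power_of_two(w)]
            if bad:
                raise ValueError(f"hidden widths must be powers of 2, got {bad}")
        self.layers: list[Dense] = []
        self.dropouts: list[Dropout] = []
        prev = n_in
        for width in hidden:
            self.layers.append(Dense(prev, width, rng))
            self.dropouts.append(Dropout(dropout_rate, rng))
            prev = width
        self.n_out = prev
        self.hidden = list(hidden)

    def __call__(self, x) -> Tensor:
        for dense, drop in zip(self.layers, self.dropouts):
            x = drop(ad.relu(dense(x)))
        return x
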