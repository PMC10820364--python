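"""Character-level SMILES tokenization for sequence models.

SMILES are split into single characters (multi-character element symbols
like ``Cl`` are deliberately split, matching the character-embedding
formulation). The vocabulary collects every distinct character in the
training corpus plus special tokens (padding, unknown, and a sequence
start/end delimiter); the fixed output length is the nearest-rank
percentile (default 95th) of corpus string lengths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

PAD, UNK, SEQ = "<pad>", "<unk>", "<s>"
SPECIALS = [PAD, UNK, SEQ]


@dataclass
class Vocabulary:
    characters: list[str]  # ordered; specials first
    output_length: int

    def __post_init__(self):
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("characters must be unique")
        if self.output_length < 1:
            raise ValueError("output_length >= 1 required")
        self._index = {c: i for i, c in enumerate(self.characters)}

    @property
    def pad_id(self) -> int:
        return self._index[PAD]

    @property
    def unk_id(self) -> int:
        return self._index[UNK]

    def __len__(self):
        return len(self.characters)

    def id_of(self, char: str) -> int:
        return self._index.get(char, self.unk_id)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"characters": self.characters, "output_length": self.output_length},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["characters"], d["output_length"])


@dataclass
class TokenizedSMILES:
    token_ids: np.ndarray

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=int)


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    if not 0 < percentile <= 100:
        raise ValueError("percentile in (0, 100]")
    ordered = sorted(values)
    rank = max(1, math.ceil(percentile / 100.0 * len(ordered)))
    return ordered[rank - 1]


def build_vocabulary(
    smiles_corpus: Sequence[str], length_percentile: float = 95.0
) -> Vocabulary:
    if len(smiles_corpus) == 0:
        raise ValueError("empty corpus")
    chars = sorted({c for s in smiles_corpus for c in s})
    output_length = int(
        nearest_rank_percentile([len(s) for s in smiles_corpus], length_percentile)
    )
    return Vocabulary(SPECIALS + chars, max(1, output_length))


def vectorize_smiles(smiles: str, vocab: Vocabulary) -> TokenizedSMILES:
    """Per-character ids, truncated/padded to ``vocab.output_length``.

    Characters unseen at vocabulary-build time map to the unknown id.
    """
    ids = [vocab.id_of(c) for c in smiles[: vocab.output_length]]
    ids += [vocab.pad_id] * (vocab.output_length - len(ids))
    return TokenizedSMILES(np.array(ids, dtype=int))


def devectorize(tokens: TokenizedSMILES, vocab: Vocabulary) -> str:
    """Inverse mapping for known, non-special ids (prefix before padding)."""
    out = []
    for i in tokens.token_ids:
        ch = vocab.characters[int(i)]
        if ch == PAD:
            break
        out.append(ch)
    return "".join(out)


def vectorize_corpus(smiles_list: Sequence[str], vocab: Vocabulary) -> np.ndarray:
    return np.stack([vectorize_smiles(s, vocab).token_ids for s in smiles_list])
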