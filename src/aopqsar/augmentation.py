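"""SMILES-enumeration data augmentation for sequence models.

The same molecule admits many valid SMILES renderings; writing the
training structures several ways multiplies the sequence-model training
set without changing its chemistry. Enumeration permutes the atom
numbering with a seeded RNG and writes a non-canonical SMILES, retrying up
to a cap to collect distinct strings. Augmentation is restricted to the
training partition — variants of a held-out structure in the training set
would leak label information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .assay_labeling import EndpointDataset
from .chem_curation import SmilesParseError


class LeakageError(RuntimeError):
    """Raised when augmentation is attempted on a non-training partition."""


@dataclass
class AugmentedSet:
    """(variant, parent canonical SMILES, label) triples plus provenance."""

    entries: list[tuple[str, str, int]]
    seed: int
    requested_factor: int

    def __len__(self):
        return len(self.entries)

    @property
    def smiles(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def parents(self) -> list[str]:
        return [e[1] for e in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=int)


def enumerate_smiles(
    canonical_smiles: str, n_variants: int, seed: int, max_tries_per_variant: int = 20
) -> list[str]:
    """Up to ``n_variants`` distinct SMILES renderings of one molecule.

    Every output canonicalizes back to the input. Fewer strings are
    returned when the molecule admits fewer distinct renderings within the
    retry budget (e.g. single atoms).
    """
    if n_variants < 1:
        raise ValueError("n_variants >= 1")
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise SmilesParseError(canonical_smiles)
    canonical = Chem.MolToSmiles(mol)
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    n_atoms = mol.GetNumAtoms()
    for _ in range(n_variants * max_tries_per_variant):
        if len(out) >= n_variants:
            break
        perm = [int(i) for i in rng.permutation(n_atoms)]
        variant = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        if variant in seen:
            continue
        if Chem.CanonSmiles(variant) != canonical:  # paranoia; should not happen
            continue
        seen.add(variant)
        out.append(variant)
    return out


def augment_training_set(
    train: EndpointDataset, factor: int = 10, seed: int = 0
) -> AugmentedSet:
    """Each training compound contributes its canonical SMILES plus up to
    ``factor - 1`` enumerated variants, all inheriting the parent label."""
    if factor < 1:
        raise ValueError("factor >= 1")
    if train.partition == "test":
        raise LeakageError(
            "augmentation on a test partition would leak structures across folds"
        )
    ss = np.random.SeedSequence(seed)
    entries: list[tuple[str, str, int]] = []
    child_seeds = ss.generate_state(len(train)) >> 1  # keep below 2**31
    for i, (comp, label) in enumerate(zip(train.compounds, train.labels)):
        parent = comp.canonical_smiles
        entries.append((parent, parent, int(label)))
        if factor > 1:
            for v in enumerate_smiles(parent, factor - 1, int(child_seeds[i])):
                if v != parent:
                    entries.append((v, parent, int(label)))
    return AugmentedSet(entries, seed=seed, requested_factor=factor)
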