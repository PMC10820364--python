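"""Tabular encoders: physico-chemical descriptors and binary fingerprints.

Descriptors come from the RDKit 2D descriptor calculator (one column per
registered descriptor; per-cell failures become NaN for the preprocessing
stage to impute). Circular (Morgan/ECFP-style) and MACCS key fingerprints
use RDKit's generators; no preprocessing is applied to fingerprints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from ..chem_curation import CuratedCompound, SmilesParseError


@dataclass
class FeatureBundle:
    """A named compounds x features numeric matrix, row-aligned to compounds."""

    encoder_name: str
    matrix: np.ndarray
    feature_names: list[str]
    fitted_preprocess: object | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix/feature_names mismatch")

    @property
    def n_compounds(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.feature_names, index=index)

    def to_csv(self, path, index=None) -> None:
        self.to_frame(index).to_csv(path, index=index is not None)


def _as_mols(compounds: Sequence[CuratedCompound | str]) -> list[Chem.Mol]:
    mols = []
    for c in compounds:
        smi = c.canonical_smiles if isinstance(c, CuratedCompound) else c
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise SmilesParseError(smi)
        mols.append(mol)
    return mols


def descriptor_names() -> list[str]:
    return [name for name, _ in Descriptors.descList]


def compute_descriptors(compounds: Sequence[CuratedCompound | str]) -> FeatureBundle:
    """Full 1D/2D descriptor block; failed cells are NaN."""
    names = descriptor_names()
    funcs = dict(Descriptors.descList)
    rows = np.full((len(compounds), len(names)), np.nan)
    for i, mol in enumerate(_as_mols(compounds)):
        for j, name in enumerate(names):
            try:
                v = funcs[name](mol)
                rows[i, j] = v if (v is not None and math.isfinite(v)) else np.nan
            except Exception:
                pass  # recorded as NaN
    return FeatureBundle("descriptors", rows, list(names))


def compute_circular_fp(
    compounds: Sequence[CuratedCompound | str], radius: int = 2, n_bits: int = 2048
) -> FeatureBundle:
    """Hashed circular fingerprints (bit set iff an environment of radius
    <= ``radius`` occurs)."""
    if radius < 0 or n_bits < 8:
        raise ValueError("radius >= 0 and n_bits >= 8 required")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    mols = _as_mols(compounds)
    mat = np.zeros((len(mols), n_bits))
    for i, mol in enumerate(mols):
        mat[i, list(gen.GetFingerprint(mol).GetOnBits())] = 1.0
    return FeatureBundle(
        "circular_fp", mat, [f"morgan_r{radius}_{b}" for b in range(n_bits)]
    )


def compute_maccs_fp(compounds: Sequence[CuratedCompound | str]) -> FeatureBundle:
    """MACCS structural keys (167-bit public keyset; bit 0 unused)."""
    mols = _as_mols(compounds)
    n_bits = 167
    mat = np.zeros((len(mols), n_bits))
    for i, mol in enumerate(mols):
        mat[i, list(MACCSkeys.GenMACCSKeys(mol).GetOnBits())] = 1.0
    return FeatureBundle("maccs_fp", mat, [f"maccs_{b}" for b in range(n_bits)])
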