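"""Molecular graph featurization for message-passing networks.

Each heavy atom becomes a node with (atomic number, total valence, bonded
hydrogen count, hybridization code); each bond is stored once as an
``(i, j)`` pair with ``i < j`` together with (bond-type code, conjugated
flag). Message passing treats edges as undirected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from ..chem_curation import CuratedCompound, SmilesParseError

NODE_FEATURE_NAMES = ["atomic_num", "valence", "n_hydrogens", "hybridization"]
EDGE_FEATURE_NAMES = ["bond_type", "conjugated"]

_HYBRIDIZATION_CODES = {
    Chem.HybridizationType.S: 0,
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
    Chem.HybridizationType.SP3D: 4,
    Chem.HybridizationType.SP3D2: 5,
}
_BOND_CODES = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


@dataclass
class MolecularGraph:
    """Undirected molecular graph; each bond stored once with i < j."""

    node_features: np.ndarray  # (n_atoms, 4)
    edges: np.ndarray  # (n_bonds, 2) int
    edge_features: np.ndarray  # (n_bonds, 2)

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.edge_features = np.asarray(self.edge_features, dtype=float).reshape(
            -1, len(EDGE_FEATURE_NAMES)
        )
        n = self.node_features.shape[0]
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge references invalid node index")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def featurize_graph(compound: CuratedCompound | str) -> MolecularGraph:
    smi = compound.canonical_smiles if isinstance(compound, CuratedCompound) else compound
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise SmilesParseError(smi)
    nodes = np.array(
        [
            [
                a.GetAtomicNum(),
                a.GetTotalValence(),
                a.GetTotalNumHs(),
                _HYBRIDIZATION_CODES.get(a.GetHybridization(), 6),
            ]
            for a in mol.GetAtoms()
        ],
        dtype=float,
    ).reshape(-1, len(NODE_FEATURE_NAMES))
    edges, efeat = [], []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
        efeat.append((_BOND_CODES.get(b.GetBondType(), 0), float(b.GetIsConjugated())))
    return MolecularGraph(nodes, np.array(edges, dtype=int).reshape(-1, 2),
                          np.array(efeat, dtype=float).reshape(-1, 2))


def featurize_graphs(compounds: Sequence[CuratedCompound | str]) -> list[MolecularGraph]:
    return [featurize_graph(c) for c in compounds]


def graphs_to_jsonl(path, graphs: Sequence[MolecularGraph]) -> None:
    """Serialize graphs as JSON lines: node features, edge list, edge features."""
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(
                json.dumps(
                    {
                        "node_features": g.node_features.tolist(),
                        "edges": g.edges.tolist(),
                        "edge_features": g.edge_features.tolist(),
                    }
                )
                + "\n"
            )


def graphs_from_jsonl(path) -> list[MolecularGraph]:
    graphs = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            graphs.append(
                MolecularGraph(
                    np.array(d["node_features"]),
                    np.array(d["edges"], dtype=int),
                    np.array(d["edge_features"]),
                )
            )
    return graphs
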