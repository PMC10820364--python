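"""Endpoint labeling from assay hit-call matrices.

A compound is *active* for a molecular initiating event or key event if at
least one of the endpoint's assays called it active; it is *inactive* only
when every observed call is inactive. Compounds with no observed call among
the endpoint's assays carry no information and are excluded (and logged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_curation import CuratedCompound

ACTIVE, INACTIVE = 1.0, 0.0


@dataclass
class AssayMatrix:
    """Compounds x assays grid of hit calls.

    ``calls`` holds 1.0 (active), 0.0 (inactive) or NaN (missing), with one
    row per compound and one column per assay.
    """

    compounds: list[CuratedCompound]
    assays: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.compounds), len(self.assays)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.compounds)} compounds x {len(self.assays)} assays"
            )
        if len(set(self.assays)) != len(self.assays):
            raise ValueError("assay names must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls,
            index=[c.canonical_smiles for c in self.compounds],
            columns=self.assays,
        )


@dataclass
class EndpointDataset:
    """Binary activity labels for one MIE/KE endpoint."""

    endpoint_name: str
    compounds: list[CuratedCompound]
    labels: np.ndarray  # 1 = active, 0 = inactive
    n_assays_used: int
    partition: str | None = None  # "train" / "test" once split
    excluded: list[str] = field(default_factory=list)  # all-missing compounds

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.compounds):
            raise ValueError("labels and compounds must align")

    @property
    def smiles(self) -> list[str]:
        return [c.canonical_smiles for c in self.compounds]

    def __len__(self):
        return len(self.compounds)

    def subset(self, indices, partition: str | None = None) -> "EndpointDataset":
        indices = np.asarray(indices, dtype=int)
        return EndpointDataset(
            self.endpoint_name,
            [self.compounds[i] for i in indices],
            self.labels[indices],
            self.n_assays_used,
            partition=partition if partition is not None else self.partition,
        )


class ConfigurationError(ValueError):
    pass


def aggregate_hitcalls(matrix: AssayMatrix, assay_subset: Sequence[str],
                       endpoint_name: str = "endpoint") -> EndpointDataset:
    """Aggregate per-assay calls into one binary label per compound.

    active iff >= 1 active call among ``assay_subset``; inactive iff all
    observed calls inactive; all-missing compounds excluded and logged in
    ``EndpointDataset.excluded``.
    """
    if len(assay_subset) == 0:
        raise ConfigurationError("assay_subset must not be empty")
    missing_assays = set(assay_subset) - set(matrix.assays)
    if missing_assays:
        raise ConfigurationError(f"unknown assays: {sorted(missing_assays)}")
    cols = [matrix.assays.index(a) for a in assay_subset]
    sub = matrix.calls[:, cols]
    any_active = np.nansum(sub == ACTIVE, axis=1) > 0
    any_observed = (~np.isnan(sub)).sum(axis=1) > 0
    keep = any_observed
    labels = any_active[keep].astype(int)
    compounds = [c for c, k in zip(matrix.compounds, keep) if k]
    excluded = [c.canonical_smiles for c, k in zip(matrix.compounds, keep) if not k]
    return EndpointDataset(
        endpoint_name, compounds, labels, n_assays_used=len(assay_subset),
        excluded=excluded,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class DatasetSummary:
    endpoint_name: str
    n: int
    n_active: int
    n_inactive: int
    pct_active: int
    pct_inactive: int


def dataset_summary(ds: EndpointDataset) -> DatasetSummary:
    """Counts and integer percentages (round half away from zero)."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    n = len(ds)
    n_active = int(ds.labels.sum())
    n_inactive = n - n_active
    return DatasetSummary(
        ds.endpoint_name,
        n,
        n_active,
        n_inactive,
        _round_half_away(100.0 * n_active / n),
        _round_half_away(100.0 * n_inactive / n),
    )


# ---------------------------------------------------------------------------
# I/O

DEFAULT_ACTIVE_ALIASES = frozenset({"active", "1", "1.0", "true", "hit"})
DEFAULT_INACTIVE_ALIASES = frozenset({"inactive", "0", "0.0", "false", "nohit"})


def read_hitcall_csv(
    path,
    compounds: list[CuratedCompound],
    id_col: str = "id",
    active_aliases: frozenset[str] = DEFAULT_ACTIVE_ALIASES,
    inactive_aliases: frozenset[str] = DEFAULT_INACTIVE_ALIASES,
) -> AssayMatrix:
    """Read a wide hit-call CSV (one column per assay, blanks = missing).

    Rows are matched to ``compounds`` by the identifier column; unmatched
    rows are ignored, compounds without a row get all-missing calls.
    """
    df = pd.read_csv(path, dtype=str)
    if id_col not in df.columns:
        raise KeyError(f"column {id_col!r} not found")
    assays = [c for c in df.columns if c != id_col]
    by_id: dict[str, pd.Series] = {str(r[id_col]): r for _, r in df.iterrows()}

    def parse(v) -> float:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        s = str(v).strip().lower()
        if not s or s == "nan":
            return np.nan
        if s in active_aliases:
            return ACTIVE
        if s in inactive_aliases:
            return INACTIVE
        raise ValueError(f"unrecognized hit-call value {v!r}")

    calls = np.full((len(compounds), len(assays)), np.nan)
    for i, comp in enumerate(compounds):
        row = None
        for src in comp.source_ids:
            if src in by_id:
                row = by_id[src]
                break
        if row is None and comp.canonical_smiles in by_id:
            row = by_id[comp.canonical_smiles]
        if row is None:
            continue
        calls[i] = [parse(row[a]) for a in assays]
    return AssayMatrix(compounds, assays, calls)


def write_assay_matrix_csv(path, matrix: AssayMatrix, id_col: str = "id") -> None:
    df = matrix.to_frame().replace({ACTIVE: "active", INACTIVE: "inactive"})
    df.index.name = id_col
    df.to_csv(path, na_rep="")
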