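"""Structure curation: canonical parent structures from raw SMILES records.

The curation pipeline mirrors common QSAR practice: canonicalize every
SMILES, keep only the largest fragment (salt stripping), remove
stereochemistry, reject records that look chemically inconsistent, and
merge duplicate structures while keeping provenance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

#: Elements accepted by default; anything else marks a record inconsistent.
DEFAULT_ELEMENT_WHITELIST = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed/sanitized."""

    def __init__(self, smiles: str, detail: str = "unparsable SMILES"):
        self.smiles = smiles
        super().__init__(f"{detail}: {smiles!r}")


class CurationError(ValueError):
    """Raised when a structure collapses to nothing during curation."""


@dataclass(frozen=True)
class RawRecord:
    """One input row: free-text identifier plus raw SMILES."""

    identifier: str
    smiles: str

    def __post_init__(self):
        if not self.smiles:
            raise ValueError("smiles must be non-empty")


@dataclass
class CuratedCompound:
    """A canonical parent structure with provenance.

    ``canonical_smiles`` is the toolkit-canonical SMILES of the largest
    fragment with stereochemistry removed; ``source_ids`` lists every raw
    identifier merged into this structure.
    """

    canonical_smiles: str
    source_ids: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"CuratedCompound({self.canonical_smiles!r}, n_src={len(self.source_ids)})"


@dataclass(frozen=True)
class Rejection:
    identifier: str
    smiles: str
    reason: str


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles:
        raise SmilesParseError(str(smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Return the toolkit-canonical SMILES.

    Idempotent; chemically equal inputs map to the same output string.
    Raises :class:`SmilesParseError` on unparsable input.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def strip_to_parent(smiles: str) -> str:
    """Largest fragment, stereo removed, re-canonicalized.

    Fragment ties on heavy-atom count are broken by molecular weight and
    then by lexicographic canonical SMILES, so the choice is deterministic
    regardless of fragment order in the input string.
    """
    mol = _mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        raise CurationError(f"no fragments in {smiles!r}")

    best = max(
        frags,
        key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f), Chem.MolToSmiles(f)),
    )
    parent = Chem.Mol(best)
    Chem.RemoveStereochemistry(parent)
    if parent.GetNumHeavyAtoms() == 0:
        raise CurationError(f"empty parent after stripping {smiles!r}")
    return Chem.MolToSmiles(parent)


def _check_elements(mol: Chem.Mol, whitelist: frozenset[str]) -> str | None:
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in whitelist:
            return atom.GetSymbol()
    return None


def curate_record(
    record: RawRecord, element_whitelist: frozenset[str] = DEFAULT_ELEMENT_WHITELIST
) -> tuple[str, set[str]]:
    """Curate one record; returns (canonical parent SMILES, flags)."""
    canonical = canonicalize_smiles(record.smiles)
    flags: set[str] = set()
    had_fragments = "." in canonical
    mol = _mol_from_smiles(canonical)
    had_stereo = any(
        a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED for a in mol.GetAtoms()
    ) or any(
        b.GetStereo() != Chem.BondStereo.STEREONONE for b in mol.GetBonds()
    )
    parent = strip_to_parent(canonical)
    if had_fragments:
        flags.add("salt_stripped")
    if had_stereo:
        flags.add("stereo_removed")
    bad = _check_elements(_mol_from_smiles(parent), element_whitelist)
    if bad is not None:
        raise CurationError(f"element {bad} outside allowed set")
    return parent, flags


def curate_dataset(
    records: Iterable[RawRecord | tuple[str, str]],
    element_whitelist: frozenset[str] = DEFAULT_ELEMENT_WHITELIST,
) -> tuple[list[CuratedCompound], list[Rejection]]:
    """Curate a batch of records into unique canonical parents.

    Records failing parse/strip/whitelist checks go to the rejection log
    with a reason; duplicates (same canonical parent) are merged into one
    compound carrying all source identifiers. The output is sorted by
    canonical SMILES, so it is invariant to input record order.
    """
    compounds: dict[str, CuratedCompound] = {}
    rejections: list[Rejection] = []
    for rec in records:
        if not isinstance(rec, RawRecord):
            rec = RawRecord(*rec)
        try:
            parent, flags = curate_record(rec, element_whitelist)
        except (SmilesParseError, CurationError) as exc:
            rejections.append(Rejection(rec.identifier, rec.smiles, str(exc)))
            continue
        if parent in compounds:
            comp = compounds[parent]
            comp.source_ids.append(rec.identifier)
            comp.flags |= flags | {"merged_duplicate"}
        else:
            compounds[parent] = CuratedCompound(parent, [rec.identifier], flags)
    out = sorted(compounds.values(), key=lambda c: c.canonical_smiles)
    for comp in out:
        comp.source_ids.sort()
    return out, rejections


# ---------------------------------------------------------------------------
# I/O


def read_compounds_csv(
    path, id_col: str = "id", smiles_col: str = "smiles"
) -> list[RawRecord]:
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    if smiles_col not in df.columns:
        raise KeyError(f"column {smiles_col!r} not in {list(df.columns)}")
    ids = df[id_col] if id_col in df.columns else df.index.astype(str)
    return [
        RawRecord(str(i), str(s))
        for i, s in zip(ids, df[smiles_col])
        if isinstance(s, str) and s
    ]


def read_compounds_sdf(path) -> list[RawRecord]:
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), sanitize=True)):
        if mol is None:
            records.append(RawRecord(f"sdf_{i}", "*INVALID*"))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}"
        records.append(RawRecord(name or f"sdf_{i}", Chem.MolToSmiles(mol)))
    return records


def write_curated_csv(path, compounds: Sequence[CuratedCompound]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["canonical_smiles", "source_ids", "flags"])
        for c in compounds:
            writer.writerow(
                [c.canonical_smiles, ";".join(c.source_ids), ";".join(sorted(c.flags))]
            )


def write_rejection_log(path, rejections: Sequence[Rejection]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["identifier", "smiles", "reason"])
        for r in rejections:
            writer.writerow([r.identifier, r.smiles, r.reason])
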