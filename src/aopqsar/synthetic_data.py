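"""Synthetic compound libraries and assay matrices with planted ground truth.

The generator emulates the kind of data the pipeline consumes in practice —
a curated SMILES library plus a compounds x assays hit-call grid — while
keeping the ground truth known: *activity is defined by the presence of a
toxicophore substructure* (by default a nitroaromatic group). Molecules are
assembled from a small fragment grammar (aromatic/aliphatic scaffolds with
substitution slots, decorated by common substituents), which keeps them
chemically plausible, curation-stable, and flexible enough for SMILES
enumeration to yield many distinct renderings.

Assay read-outs are drawn with class-conditional hit probabilities and an
independent missingness rate, so the hit-call aggregation, labeling and
imbalance machinery can be exercised under controlled noise. Preset
benchmarks mirror the size and class imbalance of the three cardiotoxicity
endpoints used throughout the package (MIE1-like 232 @ 79% active,
KE1-like 636 @ 30%, KE2-like 5004 @ 23%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from rdkit import Chem

from .assay_labeling import AssayMatrix, EndpointDataset, aggregate_hitcalls
from .chem_curation import CuratedCompound, canonicalize_smiles

DEFAULT_TOXICOPHORE = "c[N+](=O)[O-]"  # nitro group on an aromatic carbon

# Scaffold templates: python format strings whose slots sit on carbons able
# to carry one extra single bond. Aromatic slots can host the toxicophore.
AROMATIC_SCAFFOLDS: list[str] = [
    "c1cc({0})ccc1{1}",
    "c1ccc({0})c({1})c1",
    "c1cc({0})cc({1})c1",
    "c1c({0})cc({1})cc1{2}",
    "c1c({0})c({1})cc({2})c1",
    "Cc1cc({0})ccc1{1}",
    "Cc1ccc({0})c({1})c1",
    "CCc1cc({0})ccc1{1}",
    "CC(C)c1cc({0})ccc1{1}",
    "c1c({0})cc2cc({1})ccc2c1",
    "c1cc({0})c2cccc({1})c2c1",
    "Cc1ccc2cc({0})c({1})cc2c1",
    "c1cc({0})ccc1-c1ccc({1})cc1",
    "c1cc({0})ccc1-c1ccc({1})cn1",
    "c1cnc({0})c({1})c1",
    "c1cc({0})ncc1{1}",
    "c1nc({0})cc({1})n1",
    "c1cc({0})c({1})s1",
    "c1cc({0})c({1})o1",
    "c1c({0})cc({1})[nH]1",
    "Cc1nc({0})c({1})s1",
    "c1cc({0})ccc1C({1})c1ccccc1",
    "c1cc({0})ccc1Oc1ccc({1})cc1",
    "c1cc({0})ccc1Cc1ccc({1})cc1",
    "O=C(c1ccc({0})cc1)c1ccc({1})cc1",
    "c1cc({0})ccc1S(=O)(=O)c1ccc({1})cc1",
]
ALIPHATIC_SCAFFOLDS: list[str] = [
    "CCC{0}",
    "CCCC{0}",
    "CCCCC{0}",
    "CCCCCC{0}",
    "CC(C)C{0}",
    "CC(C){0}",
    "CC({0})CC{1}",
    "C1CCC({0})CC1",
    "C1CC({0})CC1",
    "C1CCC({0})CC1{1}",
    "C1CCOC1{0}",
    "C1CCNC1{0}",
    "O1CCOC1{0}",
    "C1CCCCC1C{0}",
    "CC(C)(C)C{0}",
    "CCOC{0}",
]

#: Neutral decorating substituents (no charged atoms: the toxicophore is the
#: only charged motif in the grammar, so it stays uniquely identifiable in
#: both structure and SMILES character space).
DECORATIONS: list[str] = [
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "I", "C#N", "C(F)(F)F", "S", "SC", "SCC",
    "C(=O)O", "C(=O)OC", "C(=O)N", "C(=O)C", "OC(C)=O", "NC(C)=O", "C=C",
    "CCO", "CCN", "CO", "C(C)O", "OC(F)F", "N1CCCC1", "N1CCOCC1",
    "C1CC1",
]
LINKERS: list[str] = ["", "C", "CC", "CCC"]


class InfeasiblePatternError(RuntimeError):
    pass


@dataclass(frozen=True)
class AssaySpec:
    """Class-conditional read-out model for one assay."""

    name: str
    p_hit_active: float = 1.0
    p_hit_inactive: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        for p in (self.p_hit_active, self.p_hit_inactive, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticConfig:
    n_active: int
    n_inactive: int
    toxicophore: str = DEFAULT_TOXICOPHORE
    assay_specs: list[AssaySpec] = field(default_factory=list)
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_active + self.n_inactive < 10:
            raise ValueError("need at least 10 compounds")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise in [0, 1]")


def _fill(template: str, rng: np.random.Generator, fixed: dict[int, str]) -> str:
    n_slots = template.count("{")
    args = []
    for i in range(n_slots):
        if i in fixed:
            args.append(fixed[i])
        else:
            dec = DECORATIONS[rng.integers(len(DECORATIONS))]
            link = LINKERS[rng.integers(len(LINKERS))]
            args.append(link + dec)
    return template.format(*args)


def _sample_structure(rng: np.random.Generator, active: bool,
                      pattern: Chem.Mol) -> str | None:
    """One candidate canonical SMILES, or None if the draw was invalid."""
    if active:
        template = AROMATIC_SCAFFOLDS[rng.integers(len(AROMATIC_SCAFFOLDS))]
        n_slots = template.count("{")
        slot = int(rng.integers(n_slots))
        smi = _fill(template, rng, {slot: "[N+](=O)[O-]"})
    else:
        pool = AROMATIC_SCAFFOLDS + ALIPHATIC_SCAFFOLDS
        template = pool[rng.integers(len(pool))]
        smi = _fill(template, rng, {})
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return None
    has = mol.HasSubstructMatch(pattern)
    if has != active:
        return None
    return Chem.MolToSmiles(mol)


def generate_library(
    cfg: SyntheticConfig,
) -> tuple[list[CuratedCompound], np.ndarray]:
    """Generate ``n_active + n_inactive`` distinct curated compounds.

    Returns the compound list together with the *true* activity flags
    (after ``label_noise`` flips). Class counts are exact by construction.
    """
    pattern = Chem.MolFromSmarts(cfg.toxicophore)
    if pattern is None:
        raise InfeasiblePatternError(f"bad toxicophore SMARTS {cfg.toxicophore!r}")
    rng = np.random.default_rng(cfg.seed)
    seen: set[str] = set()
    actives: list[str] = []
    inactives: list[str] = []
    max_attempts = 500 * (cfg.n_active + cfg.n_inactive)
    attempts = 0
    while (len(actives) < cfg.n_active or len(inactives) < cfg.n_inactive):
        attempts += 1
        if attempts > max_attempts:
            raise InfeasiblePatternError(
                f"could not assemble {cfg.n_active}+{cfg.n_inactive} distinct "
                f"structures (got {len(actives)}+{len(inactives)})"
            )
        want_active = len(actives) < cfg.n_active and (
            len(inactives) >= cfg.n_inactive or rng.random() < 0.5
        )
        smi = _sample_structure(rng, want_active, pattern)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        (actives if want_active else inactives).append(smi)

    smiles = actives + inactives
    truth = np.array([1] * cfg.n_active + [0] * cfg.n_inactive)
    order = rng.permutation(len(smiles))
    smiles = [smiles[i] for i in order]
    truth = truth[order]
    if cfg.label_noise > 0:
        n_flip = int(round(cfg.label_noise * len(truth)))
        flip = rng.choice(len(truth), size=n_flip, replace=False)
        truth[flip] = 1 - truth[flip]
    compounds = [
        CuratedCompound(s, [f"syn{i:05d}"], set()) for i, s in enumerate(smiles)
    ]
    return compounds, truth


def generate_assay_matrix(
    compounds: list[CuratedCompound],
    truth: np.ndarray,
    cfg: SyntheticConfig,
) -> AssayMatrix:
    """Draw the hit-call grid with class-conditional probabilities."""
    if not cfg.assay_specs:
        raise ValueError("assay_specs must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    n = len(compounds)
    calls = np.empty((n, len(cfg.assay_specs)))
    truth = np.asarray(truth)
    for j, spec in enumerate(cfg.assay_specs):
        p = np.where(truth == 1, spec.p_hit_active, spec.p_hit_inactive)
        col = (rng.random(n) < p).astype(float)
        miss = rng.random(n) < spec.missing_rate
        col[miss] = np.nan
        calls[:, j] = col
    return AssayMatrix(compounds, [s.name for s in cfg.assay_specs], calls)


# ---------------------------------------------------------------------------
# Presets emulating the three endpoint datasets

PRESETS: dict[str, dict] = {
    "mie1_like": {"n_active": 184, "n_inactive": 48, "n_assays": 6,
                  "endpoint": "MIE1"},
    "ke1_like": {"n_active": 191, "n_inactive": 445, "n_assays": 7,
                 "endpoint": "KE1"},
    "ke2_like": {"n_active": 1147, "n_inactive": 3857, "n_assays": 12,
                 "endpoint": "KE2"},
}


def preset_config(
    name: str,
    seed: int = 0,
    p_hit_active: float = 1.0,
    p_hit_inactive: float = 0.0,
    missing_rate: float = 0.0,
    label_noise: float = 0.0,
) -> SyntheticConfig:
    """Config for a preset. Defaults are deterministic read-outs, so
    aggregated labels equal the planted truth and class proportions are
    exact; pass noise parameters to emulate messier assay panels."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    specs = [
        AssaySpec(f"{p['endpoint']}_assay_{j + 1}", p_hit_active, p_hit_inactive,
                  missing_rate)
        for j in range(p["n_assays"])
    ]
    return SyntheticConfig(
        n_active=p["n_active"], n_inactive=p["n_inactive"],
        assay_specs=specs, label_noise=label_noise, seed=seed,
    )


def generate_benchmark(
    name: str, seed: int = 0, out_dir: str | Path | None = None, **noise
) -> EndpointDataset:
    """Generate a preset benchmark; optionally write its CSV/YAML inputs.

    When ``out_dir`` is given, writes the compound table, the hit-call
    matrix and an endpoint configuration in the same dialects the pipeline
    readers consume.
    """
    cfg = preset_config(name, seed=seed, **noise)
    compounds, truth = generate_library(cfg)
    matrix = generate_assay_matrix(compounds, truth, cfg)
    endpoint = PRESETS[name]["endpoint"]
    ds = aggregate_hitcalls(matrix, matrix.assays, endpoint_name=endpoint)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(
            {"id": [c.source_ids[0] for c in compounds],
             "smiles": [c.canonical_smiles for c in compounds]}
        ).to_csv(out / f"{name}_compounds.csv", index=False)
        frame = matrix.to_frame().replace({1.0: "active", 0.0: "inactive"})
        frame.insert(0, "id", [c.source_ids[0] for c in compounds])
        frame.to_csv(out / f"{name}_hitcalls.csv", index=False, na_rep="")
        with open(out / f"{name}_endpoints.yaml", "w") as fh:
            yaml.safe_dump({"endpoints": {endpoint: matrix.assays}}, fh)
    return ds
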