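"""Configuration-driven orchestration of the full modeling workflow.

Stage order mirrors standard QSAR practice: curate -> label -> encode ->
split -> oversample -> train -> applicability domain -> evaluate. A run is
described by a :class:`RunConfig` (loadable from YAML), produces a tidy
metric table (one row per endpoint x split x model x encoder) plus a JSON
manifest with input/output hashes and the per-stage seeds, and is exactly
reproducible from the manifest.

One global seed expands into per-stage seeds through
``numpy.random.SeedSequence(global_seed, stage_ordinal)`` where the stage
ordinals are fixed (0 = library/curation, 1 = labeling, 2 = encoding,
3 = splitting, 4 = imbalance, 5 = model training), so any stage can be
re-run in isolation with the same stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .applicability_domain import AD_METHODS, assess_all
from .assay_labeling import aggregate_hitcalls, dataset_summary, read_hitcall_csv
from .chem_curation import curate_dataset, read_compounds_csv
from .encoders import (
    HashedNGramEncoder,
    compute_circular_fp,
    compute_descriptors,
    compute_maccs_fp,
    latent_encode,
    preprocess_features,
)
from .evaluation import SplitPlan, compute_metrics, stratified_split
from .imbalance import OversampleConfig, oversample
from .models.baselines import BaselineModel
from .synthetic_data import PRESETS, generate_benchmark

STAGE_ORDINALS = {
    "library": 0, "labeling": 1, "encoding": 2, "splitting": 3,
    "imbalance": 4, "training": 5,
}

TABULAR_ENCODERS = ("descriptors", "circular_fp", "maccs_fp", "latent")


class ConfigValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    # data source: either a synthetic preset or compound+hitcall CSVs
    preset: str | None = "ke2_like"
    compounds_csv: str | None = None
    hitcalls_csv: str | None = None
    endpoints: dict[str, list[str]] = field(default_factory=dict)
    encoders: list[str] = field(default_factory=lambda: ["circular_fp", "maccs_fp"])
    model_families: list[str] = field(default_factory=lambda: ["logreg", "rforest"])
    test_fractions: list[float] = field(default_factory=lambda: [0.10, 0.20, 0.30])
    imbalance: dict = field(default_factory=dict)  # OversampleConfig kwargs
    ad_methods: list[str] = field(default_factory=lambda: list(AD_METHODS))
    latent_width: int = 128
    seed: int = 0
    out_dir: str = "qsarpipe_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        bad = set(self.encoders) - set(TABULAR_ENCODERS)
        if bad:
            raise ConfigValidationError(f"unknown encoders: {sorted(bad)}")
        bad = set(self.ad_methods) - set(AD_METHODS)
        if bad:
            raise ConfigValidationError(f"unknown AD methods: {sorted(bad)}")
        if self.preset is None and not (self.compounds_csv and self.hitcalls_csv):
            raise ConfigValidationError(
                "either a preset or compounds_csv + hitcalls_csv is required"
            )
        if self.preset is not None and self.preset not in PRESETS:
            raise ConfigValidationError(f"unknown preset {self.preset!r}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Documented counter scheme: SeedSequence(global_seed, stage ordinal)."""
    ss = np.random.SeedSequence((global_seed, STAGE_ORDINALS[stage]))
    return int(ss.generate_state(1)[0] >> 1)  # < 2**31


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def _encode_all(compounds, encoders, latent_width, seed):
    features = {}
    for name in encoders:
        if name == "descriptors":
            features[name] = compute_descriptors(compounds)
        elif name == "circular_fp":
            features[name] = compute_circular_fp(compounds)
        elif name == "maccs_fp":
            features[name] = compute_maccs_fp(compounds)
        elif name == "latent":
            features[name] = latent_encode(
                compounds, HashedNGramEncoder(width=latent_width)
            )
    return features


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured workflow; returns the run manifest.

    Artifacts written under ``config.out_dir``: ``metrics.tsv`` (the tidy
    split-series table), ``summaries.tsv`` (per-endpoint class balance),
    ``ad_verdicts.tsv`` and ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {**vars(config)}, "stages": {}, "stage_seeds": {
        s: stage_seed(config.seed, s) for s in STAGE_ORDINALS
    }}

    # stage: library / curation + labeling
    if config.preset is not None:
        datasets = {
            PRESETS[config.preset]["endpoint"]: generate_benchmark(
                config.preset, seed=stage_seed(config.seed, "library")
            )
        }
    else:
        records = read_compounds_csv(config.compounds_csv, id_col="id",
                                     smiles_col="smiles")
        compounds, rejects = curate_dataset(records)
        matrix = read_hitcall_csv(config.hitcalls_csv, compounds)
        if not config.endpoints:
            raise ConfigValidationError("endpoints mapping is required for CSV input")
        for name, assays in config.endpoints.items():
            unknown = set(assays) - set(matrix.assays)
            if unknown:
                raise ConfigValidationError(
                    f"endpoint {name!r} references unknown assays {sorted(unknown)}"
                )
        datasets = {
            name: aggregate_hitcalls(matrix, assays, endpoint_name=name)
            for name, assays in config.endpoints.items()
        }
        manifest["stages"]["curation"] = {
            "n_curated": len(compounds), "n_rejected": len(rejects)
        }

    summaries = [vars(dataset_summary(ds)) for ds in datasets.values()]
    pd.DataFrame(summaries).to_csv(out / "summaries.tsv", sep="\t", index=False)

    rows = []
    ad_frames = []
    for endpoint, ds in datasets.items():
        features = _encode_all(
            ds.compounds, config.encoders, config.latent_width,
            stage_seed(config.seed, "encoding"),
        )
        for frac in config.test_fractions:
            plan = SplitPlan(frac, seed=stage_seed(config.seed, "splitting"))
            train_ds, test_ds = stratified_split(ds, plan)
            train_idx = [ds.smiles.index(s) for s in train_ds.smiles]
            test_idx = [ds.smiles.index(s) for s in test_ds.smiles]
            train_feats, test_feats = {}, {}
            for name, bundle in features.items():
                tr = bundle.matrix[train_idx]
                te = bundle.matrix[test_idx]
                if name in ("descriptors", "latent"):
                    from .encoders.tabular import FeatureBundle

                    tr_b, te_b = preprocess_features(
                        FeatureBundle(name, tr, bundle.feature_names),
                        FeatureBundle(name, te, bundle.feature_names),
                    )
                    tr, te = tr_b.matrix, te_b.matrix
                train_feats[name], test_feats[name] = tr, te

            verdict = assess_all(train_feats, test_feats,
                                 methods=tuple(config.ad_methods))
            discard_rate = float(1.0 - verdict.consensus_keep.mean())
            vframe = verdict.to_frame(test_ds.smiles)
            vframe.insert(0, "endpoint", endpoint)
            vframe.insert(1, "test_fraction", frac)
            ad_frames.append(vframe)

            os_cfg = (
                OversampleConfig(**config.imbalance) if config.imbalance else None
            )
            for family in config.model_families:
                for enc_name in config.encoders:
                    X_tr, y_tr = train_feats[enc_name], train_ds.labels
                    if os_cfg is not None:
                        X_tr, y_tr = oversample(X_tr, y_tr, os_cfg)
                    model = BaselineModel(
                        family, seed=stage_seed(config.seed, "training")
                    ).fit(X_tr, y_tr)
                    proba = model.predict_proba(test_feats[enc_name])
                    report = compute_metrics(
                        test_ds.labels, (proba >= 0.5).astype(int)
                    )
                    rows.append(
                        {
                            "endpoint": endpoint,
                            "test_fraction": frac,
                            "n_train": len(train_ds),
                            "n_test": len(test_ds),
                            "family": family,
                            "encoder": enc_name,
                            **report.as_dict(),
                            "ad_discard_rate": discard_rate,
                        }
                    )

    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    ad_table = pd.concat(ad_frames, ignore_index=True)
    ad_table.to_csv(out / "ad_verdicts.tsv", sep="\t", index=False)
    manifest["artifacts"] = {
        "metrics.tsv": _hash_frame(metrics),
        "ad_verdicts.tsv": _hash_frame(ad_table),
        "summaries.tsv": _hash_frame(pd.DataFrame(summaries)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
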