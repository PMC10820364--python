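"""Applicability-domain (AD) assessment and the all-methods consensus.

Five AD criteria are fitted on training features of the tabular encoders
(descriptors, fingerprints, latent codes):

- ``bounding_box``: inside every per-feature training [min, max] range;
- ``bounding_box_pca``: inside the score ranges of the principal
  components covering 95% of training variance;
- ``leverage``: hat value h = x (XᵀX)⁻¹ xᵀ at most 3p/n;
- ``centroid_distance``: Euclidean distance to the training centroid at
  most the maximum training distance;
- ``knn_variable_k``: within the neighborhood radius of at least one
  training point, where each training point's radius is the mean distance
  to its own k nearest training neighbors.

The consensus is deliberately permissive: a query compound is discarded
only when it falls out of domain under *every* method of *every* encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

AD_METHODS = (
    "bounding_box",
    "bounding_box_pca",
    "leverage",
    "centroid_distance",
    "knn_variable_k",
)


@dataclass
class ADModel:
    method: str
    encoder_name: str = "features"
    params: dict = field(default_factory=dict)
    n_train: int = 0
    n_features: int = 0


def fit_ad(
    X_train: np.ndarray,
    method: str,
    encoder_name: str = "features",
    pca_variance: float = 0.95,
    leverage_factor: float = 3.0,
    knn_k: int = 5,
    ridge: float = 1e-8,
) -> ADModel:
    """Fit one AD criterion on the training design matrix."""
    if method not in AD_METHODS:
        raise ValueError(f"method must be one of {AD_METHODS}")
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D training matrix with at least 3 rows")
    n, p = X.shape
    params: dict = {}
    if method == "bounding_box":
        params = {"mins": X.min(0), "maxs": X.max(0)}
    elif method == "bounding_box_pca":
        mean = X.mean(0)
        Xc = X - mean
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2
        total = var.sum()
        if total == 0:
            k = 1
        else:
            ratio = np.cumsum(var) / total
            k = int(np.searchsorted(ratio, pca_variance) + 1)
        basis = Vt[:k].T
        scores = Xc @ basis
        params = {"mean": mean, "basis": basis,
                  "mins": scores.min(0), "maxs": scores.max(0)}
    elif method == "leverage":
        gram = X.T @ X
        try:
            inv = np.linalg.inv(gram)
        except np.linalg.LinAlgError:
            inv = np.linalg.inv(gram + ridge * np.eye(p))
        params = {"inv_gram": inv, "threshold": leverage_factor * p / n}
    elif method == "centroid_distance":
        centroid = X.mean(0)
        dists = np.linalg.norm(X - centroid, axis=1)
        params = {"centroid": centroid, "threshold": dists.max()}
    elif method == "knn_variable_k":
        k = min(knn_k, n - 1)
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        d, _ = nn.kneighbors(X)
        radii = d[:, 1:].mean(axis=1)
        params = {"train": X.copy(), "radii": radii, "k": k}
    return ADModel(method, encoder_name, params, n_train=n, n_features=p)


def training_leverages(X_train: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Diagonal of the hat matrix for the training set (sums to rank(X))."""
    X = np.asarray(X_train, dtype=float)
    gram = X.T @ X
    try:
        inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        inv = np.linalg.inv(gram + ridge * np.eye(X.shape[1]))
    return np.einsum("ij,jk,ik->i", X, inv, X)


def assess(ad: ADModel, X_query: np.ndarray) -> np.ndarray:
    """Boolean in-domain flag per query row."""
    X = np.asarray(X_query, dtype=float)
    if X.ndim != 2 or X.shape[1] != ad.n_features:
        raise ValueError(
            f"query has {X.shape[-1]} features, model fitted on {ad.n_features}"
        )
    p = ad.params
    if ad.method == "bounding_box":
        return np.all((X >= p["mins"]) & (X <= p["maxs"]), axis=1)
    if ad.method == "bounding_box_pca":
        scores = (X - p["mean"]) @ p["basis"]
        return np.all((scores >= p["mins"]) & (scores <= p["maxs"]), axis=1)
    if ad.method == "leverage":
        h = np.einsum("ij,jk,ik->i", X, p["inv_gram"], X)
        return h <= p["threshold"]
    if ad.method == "centroid_distance":
        return np.linalg.norm(X - p["centroid"], axis=1) <= p["threshold"]
    if ad.method == "knn_variable_k":
        from scipy.spatial.distance import cdist

        d = cdist(X, p["train"])
        return (d <= p["radii"][None, :]).any(axis=1)
    raise ValueError(ad.method)  # pragma: no cover


@dataclass
class ADVerdict:
    """Per-compound, per-(method, encoder) in-domain flags plus consensus."""

    in_domain: dict[tuple[str, str], np.ndarray]  # (method, encoder) -> flags
    consensus_keep: np.ndarray

    def to_frame(self, compound_ids: list[str] | None = None) -> pd.DataFrame:
        n = len(self.consensus_keep)
        ids = compound_ids if compound_ids is not None else [str(i) for i in range(n)]
        rows = []
        for (method, encoder), flags in sorted(self.in_domain.items()):
            for cid, flag, keep in zip(ids, flags, self.consensus_keep):
                rows.append(
                    {"compound": cid, "method": method, "encoder": encoder,
                     "in_domain": bool(flag), "consensus_keep": bool(keep)}
                )
        return pd.DataFrame(rows)


def consensus(verdicts: Mapping[tuple[str, str], np.ndarray]) -> ADVerdict:
    """Keep a compound unless it is out of domain everywhere.

    ``verdicts`` maps (method, encoder) to a boolean in-domain array; a
    compound is discarded iff the flag is False for every entry.
    """
    if not verdicts:
        raise ValueError("at least one (method, encoder) verdict required")
    stack = np.stack([np.asarray(v, dtype=bool) for v in verdicts.values()])
    keep = stack.any(axis=0)
    return ADVerdict(dict(verdicts), keep)


def assess_all(
    train_features: Mapping[str, np.ndarray],
    query_features: Mapping[str, np.ndarray],
    methods: tuple[str, ...] = AD_METHODS,
    **fit_kwargs,
) -> ADVerdict:
    """Fit every method on every tabular encoder and form the consensus."""
    verdicts: dict[tuple[str, str], np.ndarray] = {}
    for encoder, X_train in train_features.items():
        for method in methods:
            ad = fit_ad(X_train, method, encoder_name=encoder, **fit_kwargs)
            verdicts[(method, encoder)] = assess(ad, query_features[encoder])
    return consensus(verdicts)
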