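"""Minority-class oversampling (SMOTE family) for tabular training folds.

Synthetic minority samples are interpolated between a minority point and
one of its minority nearest neighbors: ``x = x_i + u * (x_nn - x_i)`` with
``u ~ U[0, 1]``. The variants differ only in which minority points seed
the interpolation: Borderline-1/2 restrict to points near the class
boundary (Borderline-2 additionally interpolates part-way toward majority
neighbors), SVM-SMOTE seeds from minority support vectors of an SVM fitted
to the fold, and KMeans-SMOTE allocates synthesis to minority-dominated
clusters. Oversampling is only ever applied inside training folds; the
evaluation module enforces that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

VARIANTS = ("smote", "borderline1", "borderline2", "svm_smote", "kmeans_smote")


@dataclass
class OversampleConfig:
    variant: str = "smote"
    k_neighbors: int = 5
    seed: int = 0
    target_ratio: float = 1.0  # minority/majority after resampling

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("0 < target_ratio <= 1")


class OversampleError(ValueError):
    pass


def _interpolate(seeds_idx, X_min, nn_model, rng, n_new, u_max=1.0):
    """SMOTE interpolation from seed minority points toward minority NNs."""
    X_new = np.empty((n_new, X_min.shape[1]))
    _, neigh = nn_model.kneighbors(X_min[seeds_idx])
    for t in range(n_new):
        s = t % len(seeds_idx)
        i = seeds_idx[s]
        # first neighbor is the point itself
        nn_choices = neigh[s][1:]
        j = nn_choices[rng.integers(len(nn_choices))]
        u = rng.uniform(0.0, u_max)
        X_new[t] = X_min[i] + u * (X_min[j] - X_min[i])
    return X_new


def _danger_indices(X_min, X_all, y_all, minority_label, m_neighbors, rng):
    """Borderline 'danger' points: more than half (but not all) of the
    m nearest neighbors in the full fold belong to the majority class."""
    nn = NearestNeighbors(n_neighbors=m_neighbors + 1).fit(X_all)
    _, neigh = nn.kneighbors(X_min)
    danger = []
    for row, idxs in enumerate(neigh):
        labels = y_all[idxs[1:]]
        n_maj = int((labels != minority_label).sum())
        if m_neighbors / 2 <= n_maj < m_neighbors:
            danger.append(row)
    return np.array(danger, dtype=int)


def oversample(
    X: np.ndarray, y: np.ndarray, cfg: OversampleConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``(X, y)`` so minority/majority reaches ``target_ratio``.

    Original rows are preserved verbatim (synthetic rows are appended).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise OversampleError("both classes must be present")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_target = int(round(cfg.target_ratio * n_maj))
    n_new = n_target - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    if n_min <= cfg.k_neighbors:
        raise OversampleError(
            f"minority count {n_min} must exceed k_neighbors={cfg.k_neighbors} "
            f"for variant {cfg.variant!r}"
        )
    rng = np.random.default_rng(cfg.seed)
    min_idx = np.flatnonzero(y == minority)
    X_min = X[min_idx]
    nn_min = NearestNeighbors(n_neighbors=min(cfg.k_neighbors, n_min - 1) + 1).fit(X_min)

    if cfg.variant == "smote":
        seeds = np.arange(n_min)
        X_new = _interpolate(seeds, X_min, nn_min, rng, n_new)
    elif cfg.variant in ("borderline1", "borderline2"):
        seeds = _danger_indices(X_min, X, y, minority, cfg.k_neighbors, rng)
        if len(seeds) == 0:  # no boundary points: fall back to plain SMOTE seeds
            seeds = np.arange(n_min)
        if cfg.variant == "borderline1":
            X_new = _interpolate(seeds, X_min, nn_min, rng, n_new)
        else:
            n_toward_min = n_new - n_new // 2
            X_new_min = _interpolate(seeds, X_min, nn_min, rng, n_toward_min)
            X_maj = X[y == majority]
            nn_maj = NearestNeighbors(
                n_neighbors=min(cfg.k_neighbors, len(X_maj))
            ).fit(X_maj)
            X_new_maj = np.empty((n_new // 2, X.shape[1]))
            _, neigh = nn_maj.kneighbors(X_min[seeds])
            for t in range(n_new // 2):
                s = t % len(seeds)
                j = neigh[s][rng.integers(neigh.shape[1])]
                u = rng.uniform(0.0, 0.5)  # stay closer to the minority point
                X_new_maj[t] = X_min[seeds[s]] + u * (X_maj[j] - X_min[seeds[s]])
            X_new = np.vstack([X_new_min, X_new_maj])
    elif cfg.variant == "svm_smote":
        svm = SVC(kernel="rbf", gamma="scale", random_state=cfg.seed).fit(X, y)
        sv = svm.support_[y[svm.support_] == minority]
        pos = {g: p for p, g in enumerate(min_idx)}
        seeds = np.array([pos[g] for g in sv if g in pos], dtype=int)
        if len(seeds) == 0:
            seeds = np.arange(n_min)
        X_new = _interpolate(seeds, X_min, nn_min, rng, n_new)
    elif cfg.variant == "kmeans_smote":
        n_clusters = max(2, min(8, n_min // max(1, cfg.k_neighbors)))
        km = KMeans(n_clusters=n_clusters, random_state=cfg.seed, n_init=5).fit(X)
        assign = km.labels_
        cluster_pool = []
        for c in range(n_clusters):
            members = np.flatnonzero(assign == c)
            m_min = np.flatnonzero(y[members] == minority)
            if len(m_min) > cfg.k_neighbors and len(m_min) / len(members) >= 0.5:
                cluster_pool.append(members[m_min])
        if not cluster_pool:
            X_new = _interpolate(np.arange(n_min), X_min, nn_min, rng, n_new)
        else:
            sizes = np.array([len(c) for c in cluster_pool], dtype=float)
            alloc = np.floor(n_new * sizes / sizes.sum()).astype(int)
            alloc[: n_new - alloc.sum()] += 1
            parts = []
            for members, n_c in zip(cluster_pool, alloc):
                if n_c == 0:
                    continue
                Xc = X[members]
                nn_c = NearestNeighbors(
                    n_neighbors=min(cfg.k_neighbors, len(Xc) - 1) + 1
                ).fit(Xc)
                parts.append(_interpolate(np.arange(len(Xc)), Xc, nn_c, rng, n_c))
            X_new = np.vstack(parts)
    else:  # pragma: no cover
        raise OversampleError(cfg.variant)

    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(len(X_new), minority, dtype=y.dtype)])
    return X_out, y_out


def distribution_shift_report(
    X_orig: np.ndarray,
    X_resampled: np.ndarray,
    feature_names: list[str] | None = None,
    ks_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-feature mean/sd of both sets plus a two-sample KS statistic.

    The ``flagged`` column marks features whose KS statistic exceeds
    ``ks_threshold``; this is a report, never an automatic block.
    """
    X_orig = np.asarray(X_orig, dtype=float)
    X_resampled = np.asarray(X_resampled, dtype=float)
    if X_orig.shape[1] != X_resampled.shape[1]:
        raise ValueError("feature spaces differ")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X_orig.shape[1])]
    rows = []
    for j, name in enumerate(feature_names):
        ks = ks_2samp(X_orig[:, j], X_resampled[:, j], method="asymp").statistic
        rows.append(
            {
                "feature": name,
                "mean_orig": X_orig[:, j].mean(),
                "sd_orig": X_orig[:, j].std(),
                "mean_resampled": X_resampled[:, j].mean(),
                "sd_resampled": X_resampled[:, j].std(),
                "ks_statistic": ks,
                "flagged": bool(ks > ks_threshold),
            }
        )
    return pd.DataFrame(rows)
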