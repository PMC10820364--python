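"""Descriptor preprocessing: prune, impute, standardize — fit on training only.

Applied to descriptor and latent feature blocks (fingerprints, graphs and
token sequences are used raw). The fitted state records the kept-feature
mask, training medians for imputation and training mean/scale for
standardization, and is applied unchanged to held-out data so no held-out
statistic leaks into the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tabular import FeatureBundle


@dataclass
class FeaturePreprocessor:
    variance_threshold: float = 0.1
    correlation_threshold: float = 0.9
    kept_indices_: np.ndarray | None = field(default=None, repr=False)
    medians_: np.ndarray | None = field(default=None, repr=False)
    means_: np.ndarray | None = field(default=None, repr=False)
    scales_: np.ndarray | None = field(default=None, repr=False)
    feature_names_: list[str] | None = field(default=None, repr=False)

    def fit(self, bundle: FeatureBundle) -> "FeaturePreprocessor":
        X = np.asarray(bundle.matrix, dtype=float)
        if X.size == 0:
            raise ValueError("training matrix is empty")
        with np.errstate(all="ignore"):
            variances = np.nanvar(X, axis=0)
        variances = np.where(np.isfinite(variances), variances, 0.0)
        keep = np.flatnonzero(variances >= self.variance_threshold)
        if keep.size == 0:
            raise ValueError("all features dropped by the variance filter")

        # correlation pruning: scan features by descending training variance
        # and drop the later (lower-variance) member of any |r|>threshold pair
        order = keep[np.argsort(-variances[keep], kind="stable")]
        medians_all = np.nanmedian(X, axis=0)
        Ximp = np.where(np.isnan(X), medians_all[None, :], X)
        sub = Ximp[:, order]
        with np.errstate(all="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
        selected: list[int] = []
        for pos in range(len(order)):
            if all(abs(corr[pos, s]) <= self.correlation_threshold for s in selected):
                selected.append(pos)
        kept = np.sort(order[selected])
        if kept.size == 0:
            raise ValueError("all features dropped by the correlation filter")

        self.kept_indices_ = kept
        self.medians_ = medians_all[kept]
        Xk = Ximp[:, kept]
        self.means_ = Xk.mean(axis=0)
        scales = Xk.std(axis=0)
        scales[scales == 0] = 1.0
        self.scales_ = scales
        self.feature_names_ = [bundle.feature_names[i] for i in kept]
        return self

    def transform(self, bundle: FeatureBundle) -> FeatureBundle:
        if self.kept_indices_ is None:
            raise RuntimeError("preprocessor not fitted")
        X = np.asarray(bundle.matrix, dtype=float)[:, self.kept_indices_]
        X = np.where(np.isnan(X), self.medians_[None, :], X)
        X = (X - self.means_) / self.scales_
        return FeatureBundle(
            bundle.encoder_name, X, list(self.feature_names_), fitted_preprocess=self
        )


def preprocess_features(
    train_bundle: FeatureBundle,
    *other_bundles: FeatureBundle,
    variance_threshold: float = 0.1,
    correlation_threshold: float = 0.9,
) -> tuple[FeatureBundle, ...]:
    """Fit on the training bundle, apply the fitted transform everywhere.

    Returns ``(train_transformed, *others_transformed)``.
    """
    prep = FeaturePreprocessor(variance_threshold, correlation_threshold).fit(
        train_bundle
    )
    return tuple([prep.transform(train_bundle)] + [prep.transform(b) for b in other_bundles])
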