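# aopqsar

Multi-encoder QSAR modeling of cardiotoxicity endpoints defined by
Adverse Outcome Pathways (AOPs).

Cardiotoxic hazard is rarely a single mechanism: the AOP framework breaks
it into a molecular initiating event (MIE1, inhibition of mitochondrial
complexes) and downstream key events (KE1, increased oxidative stress;
KE2, mitochondrial dysfunction), each observable through panels of
high-throughput assays. `aopqsar` builds binary activity classifiers for
such endpoints from chemical structure alone, and is aimed at
computational toxicologists assembling first-tier in-silico screening
batteries.

The package covers the full workflow:

- **Curation** — SMILES canonicalization, salt stripping (largest
  fragment), stereo removal, duplicate merging, rejection logging.
- **Labeling** — a compound is *active* for an endpoint if at least one
  of the endpoint's assays called it active; inactive only if every
  observed call is inactive; all-missing compounds are excluded.
- **Five chemical encoders** — 2D physico-chemical descriptors, circular
  (Morgan/ECFP) fingerprints, MACCS keys, molecular graphs, character
  token sequences, plus pluggable latent (autoencoder-style) codes.
- **Models** — a baseline ML battery (logistic regression, decision tree,
  random forest, balanced random forest, gradient boosting, SVM, kNN,
  Gaussian naive Bayes) and neural architectures built on an in-package
  numpy autodiff stack: dense networks, a character-level LSTM/GRU
  sequence model, a message-passing graph network, and a five-branch
  multimodal network fusing MACCS, circular fingerprints, descriptors,
  latent codes and SMILES text by concatenation.
- **Imbalance handling** — SMOTE and its Borderline-1/2, SVM and KMeans
  variants for baseline models (training folds only, with a
  distribution-shift report); class-ratio output-bias initialization for
  the networks.
- **Data augmentation** — SMILES enumeration (random atom-order
  renderings) multiplying the sequence-model training set, guarded
  against test-set leakage.
- **Applicability domain** — bounding box, PCA bounding box, leverage
  (h ≤ 3p/n), centroid distance and variable-k nearest-neighbor criteria;
  a compound is discarded only when out of domain under *every* method of
  *every* encoder.
- **Evaluation** — stratified splits, repeated stratified k-fold CV, grid
  search on F1, the six-metric report (balanced accuracy, precision,
  sensitivity, specificity, MCC, F1), permutation importance and Shapley
  attributions.
- **Synthetic benchmarks** — generators that emulate the three endpoint
  datasets (232 @ 79 % active, 636 @ 30 %, 5004 @ 23 %) with a planted
  toxicophore (nitroaromatic) defining ground-truth activity, so the
  whole pipeline is testable without any external download.

## Worked example

```python
from aopqsar.assay_labeling import dataset_summary
from aopqsar.encoders import compute_circular_fp
from aopqsar.evaluation import SplitPlan, compute_metrics, stratified_split
from aopqsar.models.baselines import BaselineModel
from aopqsar.synthetic_data import generate_benchmark

ds = generate_benchmark("ke2_like", seed=1)        # 5004 compounds
s = dataset_summary(ds)
print(s.n, s.pct_active, s.pct_inactive)           # 5004 23 77

train, test = stratified_split(ds, SplitPlan(0.10, seed=2))
print(len(train), len(test))                       # 4504 500

model = BaselineModel("logreg", seed=0).fit(
    compute_circular_fp(train.compounds).matrix, train.labels
)
proba = model.predict_proba(compute_circular_fp(test.compounds).matrix)
report = compute_metrics(test.labels, (proba >= 0.5).astype(int))
print(round(report.balanced_accuracy, 3))          # 1.0
```

The benchmark plants a nitroaromatic toxicophore as the ground truth, so
a fingerprint model recovers the signal essentially perfectly (balanced
accuracy 1.0 on the 500-compound held-out split above); the figure to
watch on real assay data is lower and model-dependent. The same call
pattern drives the neural models through
`aopqsar.models.train(ModelSpec(...), EncodedDataset(...))`.

A YAML-configured end-to-end run (curate → label → encode → split →
oversample → train → AD → evaluate) is available from the shell:

```bash
qsarpipe generate --preset ke2_like --seed 1 --out-dir data/
qsarpipe run config.yaml
```

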