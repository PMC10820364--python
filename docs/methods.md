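# Methods

## Problem and data model

Each modeling endpoint is one event in the cardiotoxicity AOP chain:
MIE1 (inhibition of mitochondrial complexes), KE1 (increased oxidative
stress) or KE2 (mitochondrial dysfunction). The raw inputs are (a) a
compound table (identifier + SMILES) and (b) a compounds × assays grid of
hit calls taking values active / inactive / missing, together with a
configuration listing which assays define each endpoint. A compound is
labeled active for an endpoint when at least one of its assays called it
active. This "any-hit" rule is deliberately sensitive: it inflates the
false-positive side when individual assays are noisy, which is why the
evaluation leans on balanced accuracy, MCC and F1 rather than raw
accuracy.

Missingness is not part of the any-hit rule's usual statement, so the
package fixes a convention: *inactive* requires every **observed** call to
be inactive, and compounds whose calls are all missing are excluded from
the endpoint dataset (they carry no information) and logged.

## Curation

Structures are canonicalized with RDKit; the largest fragment is kept
(ties on heavy-atom count broken by molecular weight, then lexicographic
canonical SMILES), stereochemistry is removed, and duplicates (same
canonical parent) are merged with the union of their source identifiers.
"Chemical inconsistency" is operationalized as: parse/sanitization
failure, zero heavy atoms after stripping, or an element outside a
configurable organic whitelist (H, B, C, N, O, F, Si, P, S, Cl, Br, I).
Counter-ion-only records therefore survive as the ion if its element set
is allowed — a documented guess, exposed through the whitelist. Isotope
labels are kept; tautomer standardization and charge neutralization are
deliberately out of scope.

## Encoders

- **Descriptors**: the full RDKit 2D descriptor block (210 columns, one
  per registered descriptor). Per-cell calculation failures become NaN
  and are median-imputed by the preprocessing step.
- **Circular fingerprint**: hashed Morgan environments, radius 2, 2048
  bits (field-standard defaults).
- **MACCS keys**: the public 166/167-key set.
- **Graphs**: one node per heavy atom with (atomic number, total valence,
  bonded hydrogen count, hybridization code); one edge per bond (stored
  once, i < j; message passing expands to both directions) with
  (bond-type code, conjugated flag).
- **Token sequences**: SMILES split into single characters (multi-letter
  element symbols are split, matching the character-embedding
  formulation); the vocabulary is the training corpus's character set
  plus `<pad>`, `<unk>` and a sequence delimiter; the fixed output length
  is the nearest-rank 95th percentile of corpus string lengths. Unknown
  characters at inference map to `<unk>`.
- **Latent codes**: any object with `encode(smiles) -> matrix` and a
  `width` attribute plugs in, so an externally pretrained sequence
  autoencoder can be used directly. Two encoders ship: a deterministic
  signed-hash character-n-gram projection (md5-based, so stable across
  processes; L2-normalized and scaled by √width so feature variances are
  order one), and a small trainable dense autoencoder over those hashed
  n-gram counts whose bottleneck activations are the code. The dense
  variant was chosen over a sequence-to-sequence surrogate because it
  trains in seconds on one CPU while exercising the identical interface.

Preprocessing (descriptors and latent codes only; fingerprints, graphs
and token sequences are used raw): drop features with training variance
< 0.1; scan the survivors by descending training variance and drop the
later member of any pair with |Pearson r| > 0.9; median-impute missing
cells; standardize to zero mean / unit variance. All statistics come from
the training partition and are applied unchanged to held-out data.

## Imbalance

Baseline models train on SMOTE-resampled folds: synthetic minority rows
are `x_i + u (x_nn − x_i)`, `u ~ U[0,1]`, from a minority point toward one
of its `k = 5` minority nearest neighbors, until the minority/majority
ratio reaches 1.0. Borderline-1 restricts seeds to "danger" points (more
than half, but not all, of the m nearest fold neighbors are majority);
Borderline-2 additionally interpolates part-way (u ≤ 0.5) toward majority
neighbors; SVM-SMOTE seeds from minority support vectors of an RBF SVM
fitted to the fold; KMeans-SMOTE allocates synthesis to
minority-dominated clusters (falling back to plain SMOTE seeds when the
danger/support/cluster sets are empty, so small folds never fail). A
per-feature report (means, SDs, two-sample KS statistic, flag at
KS > 0.2 by default) quantifies the distribution shift of the resampled
fold; it informs, never blocks. Networks do not use SMOTE: their output
bias is initialized to `log(p/(1−p))` from the training class ratio.

## Applicability domain

Five criteria are fitted on training features of the tabular encoders
(the graph and token encoders have no natural feature-space AD here):
per-feature bounding box; bounding box on the principal components
covering 95 % of training variance; leverage `h = x (XᵀX)⁻¹ xᵀ ≤ 3p/n`
(ridge fallback on singular Gram matrices); Euclidean distance to the
training centroid, thresholded at the maximum training distance; and a
variable-k nearest-neighbor rule in which each training point gets a
radius equal to the mean distance to its k = 5 nearest training
neighbors and a query is in-domain if it lies within at least one such
radius. All thresholds are configurable. The consensus is maximally
permissive by design: a test compound is discarded only when *every*
method under *every* encoder calls it out of domain. On test sets drawn
from the training distribution this discards essentially nothing; on a
deliberately shifted query set the discard rate is large — both behaviors
are asserted in the test suite.

## Models and training

The baseline battery (logistic regression, decision tree, random forest,
balanced random forest, XGBoost, SVM, kNN, Gaussian NB) wraps
scikit-learn/xgboost behind one fit/predict-probability interface; the
balanced random forest is a random forest with per-bootstrap balanced
class weights.

The neural models run on an in-package numpy reverse-mode autodiff
(exact gradients, checked against numeric differentiation in the tests):

- **DNN**: dense stack with ReLU and dropout 0.2, default widths
  [512, 256, 128] — powers of two are enforced as an architecture
  constraint.
- **Sequence model**: character embedding (64) → LSTM(128) → GRU(64) →
  dense head, consuming the token sequences directly.
- **MPNN**: T = 3 message-passing rounds; each atom aggregates
  ReLU-transformed messages from bonded neighbors conditioned on bond
  features, updates through a GRU-style gate, and the readout
  concatenates mean- and sum-pooled node states. T = 0 is a legal
  degenerate baseline (readout of projected raw node features).
- **Multimodal**: five jointly trained branches — dense stacks for MACCS,
  circular fingerprints, descriptors and latent codes plus the sequence
  encoder — merged by concatenation into a dense head.

Training uses Adam at 1e-3, mini-batches of 32, a stratified 10 %
validation split, class-ratio output-bias initialization, and a plateau
schedule: no validation-loss improvement for `plateau_patience` (10)
epochs divides the learning rate by 10; a second plateau stops training;
an `early_stop_patience` (20) cap bounds the run. Output heads are
initialized with small weights (σ = 0.05) so the bias initialization,
not the random head, sets the starting operating point. Exact layer
sizes are config-exposed defaults, not fitted constants.

Data augmentation (sequence model only): each training compound
contributes its canonical SMILES plus up to factor−1 (default 9) distinct
random-atom-order renderings, generated by seeded atom renumbering with a
retry cap, each verified to canonicalize back to its parent. Augmentation
refuses to run on a test partition, and fold purity (no variant's parent
in a held-out fold) is asserted in the tests.

Hyperparameter search is an exhaustive grid evaluated by k-fold (default
5) CV mean F1 — F1 because it remains informative under class imbalance —
with ties broken by mean balanced accuracy, then grid order. Internal
validation is 10 repeats of stratified 10-fold CV; oversampling and
preprocessing are fitted inside each training fold only.

## Explainability

Permutation importance reports the mean ± SD drop of a chosen metric
(default F1) over seeded independent shuffles of one feature column;
constant columns are reported as exactly zero. Shapley attributions use
the exact closed form for linear readouts
(`φ_j = w_j (x_j − E[x_j])`, base = mean background prediction) and a
seeded permutation-sampling estimator of interventional Shapley values
for other probabilistic models; additivity (base + Σφ ≈ output) is the
correctness check.

## Synthetic benchmarks

The generator assembles molecules from a fragment grammar — 26 aromatic
scaffolds with 2–3 substitution slots, 16 aliphatic scaffolds, 35 neutral
decorating substituents with 4 linkers — large enough that independently
seeded libraries overlap by well under 5 %. Ground-truth activity is the
presence of a nitroaromatic toxicophore (`c[N+](=O)[O-]`): actives get
the nitro group planted on an aromatic slot, inactives are checked to be
free of the pattern. The nitro group is the grammar's only charged motif,
so the signal is recoverable by every encoder, including the character
models. Class counts are exact by construction. Assay read-outs are drawn
per assay with class-conditional hit probabilities and an independent
missing rate; an optional `label_noise` flips an exact fraction of truth
flags.

The three presets mirror the endpoint dataset shapes: `mie1_like` 232
compounds / 79 % active / 6 assays, `ke1_like` 636 / 30 % / 7,
`ke2_like` 5004 / 23 % / 12. Preset defaults use deterministic read-outs
(P(hit|active) = 1, P(hit|inactive) = 0, no missingness) so aggregated
labels equal the planted truth and the class percentages are exact;
noisy panels are available through the same config. What passing tests on
these benchmarks shows is that the pipeline recovers a clean planted
substructure signal end-to-end; they do not emulate the hardness of real
assay panels — the multi-mechanism chemistry, correlated assay noise and
activity cliffs of real data are explicitly not modeled.

## Benchmark problem sizes

The reference experiments in `aopqsar.benchmarks` (shared by the test
suite and `scripts/acceptance.py`) use: the full 5004-compound KE2-like
benchmark with a 90–10 split for the fingerprint baseline; a stratified
1200-compound subset for the single-branch-vs-multimodal comparison; a
400-compound subset (×10 enumeration) for the augmentation comparison —
with compact layer widths (DNN [128, 64]; multimodal branches down-scaled
alike; sequence models embed 32/LSTM 64/GRU 32 and embed 16/LSTM 32/
GRU 16 respectively) and a shortened schedule (20 epochs, plateau
patience 4, early stop 8). These sizes are the package's chosen study
conditions for a single-CPU workflow; the planted signal saturates well
below them, so the comparisons are insensitive to the exact values.

## Numerical conventions and edge cases

- Test-set size: round half away from zero; per-class counts by largest
  remainder; a class that would get zero test compounds is forced one.
- Zero-denominator metrics (precision, sensitivity, specificity, F1,
  MCC) are 0 by convention; the prediction threshold is `p ≥ 0.5` with
  ties going to active.
- Percentages in dataset summaries round half away from zero to integers.
- Leverage uses a ridge fallback (`1e-8` on the Gram diagonal) when XᵀX
  is singular; the hat-diagonal trace identity (Σh = p) holds to 1e-8 on
  full-rank designs.
- CV folds with a single truth class are re-drawn with a shifted seed and
  counted.
- One global seed expands into per-stage seeds via
  `SeedSequence(global_seed, stage_ordinal)` (ordinals fixed per stage),
  so pipeline stages can be re-run in isolation; all derived seeds stay
  below 2³¹.

## Known limitations

- The descriptor block is RDKit's 2D set (210 descriptors); descriptor
  counts and importance rankings are therefore not comparable with
  workflows built on other calculators (e.g. Mordred's 1613-column 1-2D
  block). No 3D/conformer descriptors.
- The latent encoders are desk-scale surrogates; they expose the
  interface of a large pretrained chemical autoencoder without its
  chemistry-wide representation power.
- The SVM- and KMeans-SMOTE variants implement the canonical seeding
  ideas (support-vector and cluster-restricted synthesis) without the
  extrapolation/density-weighting refinements of the original papers.
- The variable-k AD rule follows the per-point-radius coverage idea;
  published toolbox calibrations differ in their smoothing constants, so
  absolute discard rates are comparable only within this package.
- Multi-character element symbols are split by the character tokenizer;
  a `Cl` atom is the token pair `C`,`l`. This matches the character-
  embedding design but differs from atom-wise SMILES tokenizers.
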