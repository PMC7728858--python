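# Methods

## Problem and data model

The package evaluates binary classifiers of drug-induced liver injury (DILI)
trained on high-throughput transcriptomic treatment profiles. A profile is a
vector of moderated Z-scores over a fixed landmark-gene panel (978 genes in
the emulated assay), one per drug/dose/duration/cell-line combination; the
label is a drug-level annotation (DILI-positive/negative) joined onto every
profile of that drug. Because Level-5 moderated Z-scores are already a
variance-standardized differential statistic, features are used as-is: no
re-scaling or re-baselining is applied anywhere in the pipeline.

Drug ids are assumed pre-reconciled (one label per drug id). Synonym
resolution against chemical registries is out of scope; the readers raise on
conflicting or duplicate ids rather than guessing.

## Synthetic data generator

The generator emulates the study conditions end to end so that every
protocol is testable without external downloads. Defaults are the emulated
panel: 978 genes, 1279 drugs at a positive fraction of 768/1279 ≈ 0.60,
noise sd 1 (the Z-score scale). Where the emulated study pins no value, the
following were chosen once as realistic and are not data-tuned:

* `profiles_per_drug = 6` (2 cell lines × 3 doses), `dose_levels = (0.1, 1,
  10)` µM — a typical small dose series;
* `n_signal_genes = 50`, `effect_size = 2.0` — a moderate planted signal,
  50 of 978 genes shifted by up to two noise sds;
* `cell_line_sd = 0.5` — within-drug correlation of realistic magnitude.

Signal structure: a fixed subset of signal genes; each positive drug draws,
once, a ±1 direction per signal gene (its signature), and every profile of
that drug shifts those genes by `effect_size × dose_weight × direction`.
The dose weight is logistic in log-dose scaled to [0.5, 1] (any monotone
bounded map would do; this one keeps even the lowest dose informative).
Every (drug, cell line) pair additionally receives one scalar offset, sd
`cell_line_sd`, added to all genes of its profiles — the simplest structure
that makes profiles of the same drug correlated, as repeated assays of one
compound are. Offsets apply to positive and negative drugs alike, so the
null remains exactly label-free.

Two consequences worth knowing when reading test results:

* Because signature directions are drug-specific, the planted signal is
  *locally* recoverable (profiles of the same or similarly signed drugs
  cluster) but not linearly separable as a global mean shift. Neighborhood
  methods (KNN) therefore excel on the synthetic task, and small networks
  need either many epochs or larger samples to exploit it. This is
  deliberate: it gives signature extraction a recoverable ground truth and
  makes the profile-vs-drug-split leakage ordering visible.
* What the generator does **not** emulate: the Level 1→5 processing chain
  (bead deconvolution, replicate collapse), real cell-line biology (69
  heterogeneous lines), dose–duration interactions, and gene–gene
  correlation beyond the shared scalar offset. Passing tests demonstrate
  the correctness and calibration of the protocols, not real-data
  performance.

## Selection and splitting

**Variance-based selection** ("modified Kennard–Stone"): each profile is
scored by its Euclidean distance to the per-gene mean profile of the whole
collection; selection keeps the distance-extreme profiles. The classical
iterative max-min Kennard–Stone is intentionally not implemented. The
quantile rule published for this step (two-sided at q = 0.05) is internally
inconsistent with its reported yield (6000 of 23,791 ≈ 25%), so the package
exposes both a `quantile` mode and a `target_count` mode and makes
`target_count` the pipeline default. In target-count mode profiles are taken
alternately from the largest- and smallest-distance ends; all ties break by
lexical profile id for bit-reproducibility.

**Stratified splitting.** The train side receives round-half-up(total ×
fraction) profiles, apportioned to the classes by largest remainder of the
per-class quotas class_size × fraction, ties favouring the positive class.
This single rule reproduces every published split size this protocol family
reports (3568/2432 → 2854/1946 + 714/486; 2432/2432 balanced → 3891/973;
427/213 drugs → 342/170 + 85/43). A per-class round-half-up rule, by
contrast, cannot produce an odd train total from two equal classes (it
would give 3892, not 3891). Drug-stratified splits apply the same rule at
drug level and then move whole drugs; balanced downsampling subsamples the
majority class, without replacement, to the minority size. Splits are
functions of (ids, labels, seed) only — never of expression values — and a
property test enforces this.

## Classifiers

The deep model is a seven-hidden-layer fully connected network with a single
sigmoid output trained by mini-batch binary cross-entropy. It is implemented
in numpy with the four activations (tanh, ReLU, SELU, ELU) and four
optimizers (Adam, Adadelta, RMSProp, SGD) that form the 4 × 4 search grid;
initialisation is Glorot-uniform and, together with batch shuffling, draws
from a single seeded generator, so training is bit-reproducible. Default
architecture — widths (1000, 800, 600, 400, 200, 100, 50), 100 epochs,
batch 128, learning rate 1e-4, no dropout, no early stopping — is a package
default, chosen as a plain tapering funnel from the 978-gene input; every
element is overridable through `DnnConfig`.

KNN (Euclidean), SVM (polynomial/RBF) and RF delegate to scikit-learn behind
the shared contract. Scores are: sigmoid output (DNN), positive-neighbor
fraction (KNN), positive-vote fraction (RF), and for SVM the raw decision
value min-max mapped to [0, 1] within the prediction batch — AUC is
rank-invariant to this, and Platt scaling is deliberately avoided. The
decision threshold is 0.5 with the boundary classified negative. Every
fitted model records its training gene order and refuses inputs in any other
order. Grids: KNN k ∈ {3,5,7,9,11}; SVM kernels {polynomial, RBF} ×
C ∈ {0.01,0.1,1,10,100} × γ ∈ {0.1,0.01,0.001,0.0001}; RF trees
{100..500} × depth {8,10,12,∞} × min-split {2,5,10} × min-leaf {1,2,4}.
(The published optimum for the SVM is stated as C = 0.0001, γ = 10, which
lies outside both of its own grids; this package records it as the evident
transposition C = 10, γ = 0.0001.)

## Metrics and the V score

All confusion-based metrics follow their standard formulas; AUC is the
Mann–Whitney rank statistic (ties = 1/2), which equals the area under the
empirical ROC curve exactly and is monotone-invariant, so the SVM score
mapping cannot affect it. Any metric with a zero denominator (MCC with an
empty margin, kappa at P(e) = 1, a rate with an empty class) is defined as
0 — the conventional no-information value, needed because degenerate
predictors do arise during grid search.

The model-selection score is V = (MCC + c) × specificity with c = 0.05 by
default (configurable). The printed form of the constant in the source
protocol ("00.5") is ambiguous; 0.05 is used because it reproduces the
protocol's own reported best value exactly ((0.422 + 0.05) × 0.625 = 0.295),
while 0.5 does not. Multiplying by specificity steers selection away from
majority-class solutions on positive-heavy panels.

## Protocols

* **MCCV**: `n_iter` independent stratified 80/20 inner splits, fit and
  score per iteration, all metrics recorded. Iteration failures are logged
  and excluded with an explicit count; nothing is imputed.
* **Grid search**: MCCV per combination; selection by mean V, ties broken
  by mean AUC then lexical config label, invariant to row order.
* **Final evaluation**: one fit on the full training set, reports on both
  sets plus per-metric |train − validation| differences; overlapping sets
  are a hard error outside tests.
* **Y-scrambling**: labels permuted uniformly per scramble (features
  untouched), one inner fit-and-score per scramble (not a full MCCV —
  keeps cost linear), Welch two-sample *t* against the real MCCV
  distribution per metric, Benjamini–Hochberg adjustment across the eight
  metrics (the published description names only "adjusted p by Student's
  t-test"; both the raw and adjusted values are reported), and Cohen's
  d = (mean_real − mean_scrambled)/pooled sd. Defaults use 100 scrambles
  against 100 real iterations; both counts are configurable since the
  source protocol mentions 100 and 1000 in different places.
* **Robustness**: balanced-sampling (downsample → split → fit → validate,
  ×50) and drug-held-out splitting (×50) with a hard leakage check — any
  drug on both sides aborts the run.

Seeds fan out from one master seed through fixed offsets (documented in the
CLI module), so each stage is independently replayable and reruns are
byte-identical.

## Interpretation

Signatures are taken from correctly predicted validation profiles only: the
top-k (default 100) most up- and down-regulated genes by signed Z-score,
ties by lexical gene id. Each correctly predicted profile counts once — no
per-drug deduplication or weighting (documented choice; the protocol is
silent on it). Frequencies pool up and down occurrences (direction-resolved
counts are emitted alongside); the top-n (default 200) list breaks count
ties by larger mean |Z| across contributing profiles, then lexical id. ATC
stratification maps each drug to its first-level class(es); multi-class
drugs contribute to every class they map to, degenerate strata report only
their defined metrics, and unmapped drugs are counted, never silently
dropped.

## Test and verification sizes

The test suite exercises the statistical claims at sizes chosen to give
3-standard-error margins comfortably: null calibration of all four families
uses 200 drugs × 978 genes × 20 seeds; permutation testing uses 20 scrambles
against 20 real iterations on a 100-drug signal design; signal recovery uses
150 drugs with 50 planted genes; the leakage ordering uses 20 paired seeds.
Networks in tests use a small 7-layer architecture (widths 32…8) so the
whole suite stays fast; protocol behaviour, not network capacity, is what
those tests certify.

## Known limitations

* The headline real-data performance of the emulated study is not
  reproducible here by design: it requires the proprietary-scale public
  download and curated label mapping; this package certifies the machinery.
* The DNN is CPU-only numpy; at the default architecture it is adequate for
  thousands of profiles, not millions.
* The generator's within-drug correlation is a single shared scalar per
  (drug, cell line); real profile correlation is richer.
* SVM scores are ranking scores, not calibrated probabilities.
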