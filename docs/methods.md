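# Methods

## The prediction problem

Each patient is described by a vector of pharmacogenetic features: imputed
variant dosages in `[0, 2]` (expected alternate-allele counts; integers for
hard calls) and star-allele haplotype diplotype counts in `{0, 1, 2}`. The
targets are binary indicators of regular usage for a set of medications —
a multilabel problem, since patients commonly use several medications. The
scientific question is whether curated knowledge-graph structure linking
variants, haplotypes, genes, medications and diseases improves prediction
over models that see the genotypes alone.

## Graph construction

The graph is parsed from a relationships table in the PharmGKB TSV dialect
(entity id/name/type pairs plus an association status). Only rows whose
status is `associated` are kept; `ambiguous`, `not associated` and
unrecognized statuses are discarded (the latter with a warning). Status
matching is case-insensitive and whitespace-trimmed. Duplicate and reversed
rows collapse to a single undirected edge, and curated self-relations are
skipped because they carry no adjacency information (the normalization adds
a self-loop to every node anyway).

Genotype features that are absent from the curated table but whose gene is
present can be attached by ad-hoc feature–gene edges
(`adhoc-variant-gene` / `adhoc-haplotype-gene` provenance); when a curated
edge already exists it wins over the ad-hoc one. Features whose gene is not
in the graph are reported in a skipped list and excluded.

Node ordering is deterministic — sorted by `(type, id)` — so adjacency
matrices, embeddings and training runs are reproducible. The propagation
operator is `S = D̂^{-1/2}(A+I)D̂^{-1/2}`, stored sparse but contractually
equal to the dense closed form (tested to 1e−9).

### Randomized-graph control

The GCN-random ablation retrains the identical model on a rewired graph.
The default rewiring is a degree-preserving double-edge swap with
`10 × |E|` swap attempts, which destroys the specific wiring while keeping
every node's degree — so any performance drop is attributable to the loss
of meaningful structure, not to a change in degree distribution. A
`uniform-rewire` mode (same edge count, uniformly random pairs) is also
available. Both are seeded and reproducible.

## Feature and label filtering

* Features with fewer than 10 non-zero values are dropped (a column with
  exactly 10 survives). "Non-zero" is an exact comparison on stored values,
  so fractional imputed dosages count.
* Missing dosages are imputed with per-feature means computed on training
  rows only, avoiding information leak from validation/test patients.
* Medication codes are mapped to (ATC code, active-ingredient name) pairs;
  identity after mapping is the lowercased ingredient, so multiple codes for
  one ingredient share a label column. A medication is kept when its ATC
  code or its ingredient name (case-insensitive) matches a chemical node.
  Medications with fewer than 100 users are dropped (exactly 100 survives).
  Patients with no mapped medications remain as all-zero rows; they inform
  the negative class.

## Models and training

All predictors are scikit-learn-style estimators sharing one training loop:
minibatch Adam (learning rate 1e−3), at most 200 epochs, early stopping
after 20 epochs without validation-loss improvement, and selection of the
checkpoint with the minimum validation loss. The loss is the multilabel
binary cross-entropy, summed over medications and averaged over patients;
probabilities are clipped to `[1e−7, 1−1e−7]` inside the loss. A fixed
`random_state` makes the entire run (initialization, shuffling, rewiring)
bit-reproducible.

* **baseline** — unregularized multilabel logistic regression.
* **dnn** — feed-forward network with hidden widths (256, 64), ReLU.
* **gcn** — two graph-convolution layers of width 64 (ReLU), identity input
  features never materialized (layer 0 consumes `W^0` directly), dosage-
  weighted aggregation, then a head with one hidden layer of 64 (ReLU) and
  a linear-sigmoid output. GCN layers and head are updated jointly.
* **gcn-random** — identical, trained on the rewired graph.

The forward/backward passes are hand-written NumPy with analytic gradients
(verified against central finite differences in the test suite); the models
are small enough that this is fast on one CPU and keeps the dependency
surface minimal.

The default minibatch size is 4096. For desk-scale cohorts (thousands of
patients) that would collapse an epoch into a single optimizer step and
undertrain every model, so the pipeline's comparison runs use
`DESK_TRAIN = {batch_size: 256}`; the architecture, learning rate, epoch
budget and early-stopping rule are unchanged.

### Stratified splitting

`stratified_split` partitions patients 70/10/20 using iterative
stratification: labels are processed rarest first, and each patient carrying
the current label goes to the split with the greatest remaining demand for
it (ties broken by remaining capacity, then randomly), subject to exact
split sizes. Validation and test counts round up and training takes the
remainder; for a cohort of 485,754 this yields 340,027 / 48,576 / 97,151.
Labels with fewer users than splits trigger a warning and best-effort
placement.

## Evaluation and interpretation

Per-medication ROC AUC is computed on the held-out test split
(Mann–Whitney tie handling; single-class medications are reported as
missing). Models are compared with paired t-tests over per-medication AUC
differences; identical vectors give p = 1, and constant nonzero differences
raise rather than returning a degenerate infinite statistic. Mean AUCs are
unweighted across medications. Sample-size percentile binning uses
nearest-rank boundaries with boundary values assigned to the lower bin.

The ranking analysis standardizes each medication's predicted probabilities
to Z-scores (sample sd, ddof = 1; constant columns are zeroed and flagged),
ranks medications within each patient (rank 1 = highest Z, ties broken by
column index), and marks the top five. Per medication, a logistic
regression of actual usage on the top-five indicator gives an odds ratio
with a 95% Wald CI (`exp(slope ± 1.96·SE)`); with a single binary predictor
the slope equals the log cross-product ratio of the 2×2 table, which the
tests verify to 1e−6. Zero-cell tables are flagged degenerate with no
continuity correction. By default the analysis uses test-set predictions
only (leak-free) and medications with at least 5,000 users; desk-scale runs
lower that floor via configuration. No multiplicity adjustment is applied
across medications.

## Synthetic data generator

The generator emulates the structures the pipeline consumes. Defaults: 40
genes × 5 variants, 8 haplotypes, 12 drugs (3 target genes each), 8
diseases, 4,000 patients, allele frequencies uniform on (0.05, 0.5), target
prevalence 0.15, liability noise sd 1.0, 20% of variant–gene edges tagged
ad-hoc. Dosages are `Binomial(2, p_j)`. For drug *d* the liability is
`Σ_j β_dj·(G_ij − 2p_j) + ε`, with `β_dj` nonzero only for features whose
gene is graph-adjacent to the drug's chemical node; effects share a
gene-level mean of magnitude `beta_scale` with random sign (within-gene sd
`beta_scale/4`), inducing the effect sharing a GCN can exploit. Labels are
`Bernoulli(sigmoid(α_d + liability))` with `α_d` found by root-finding so
the empirical prevalence hits the target. `beta_scale = 0.4` is set so the
oracle linear scorer `Σ β_dj G_ij` attains mean AUC ≥ 0.70 at n = 10,000 —
a moderately predictive regime comparable to a genuinely informative but
noisy pharmacogenetic signal.

Because the signal is routed strictly through graph topology, the headline
contrast — informative graph beats randomized graph and non-graph
baselines — is reproducible in simulation at desk scale (minutes on one
CPU). What the simulations do **not** emulate: linkage disequilibrium,
population stratification, imputation error, label misclassification from
self-report, and the long-tailed medication frequency distribution of real
cohorts. Passing on synthetic data therefore demonstrates correctness of
the machinery and the graph-signal mechanism, not expected AUC levels on
real biobank data, where reported performance is far lower.

## Numerical choices and degenerate inputs

* Normalized adjacency validated square and symmetric; empty graphs are an
  error for adjacency construction and a warned-but-valid result for
  association filtering.
* Diverging training (NaN loss) raises with the epoch number.
* AUC of a single-class medication is missing, dropped from paired tests.
* The intercept search for label calibration brackets `[−30, 30]` and
  raises if the prevalence target is unreachable.
* Seeds below 2³¹ are drawn from a master generator wherever a component
  (graph rewiring, internal validation split) needs its own stream.

## Known limitations

* The NumPy training loop is single-threaded BLAS-bound; biobank-scale
  cohorts (10⁵–10⁶ patients, 10⁴ graph nodes) would need a GPU framework
  and sparse-dense hybrid optimizations out of scope here.
* Combination products map to a single ingredient row in the mapping table;
  multi-ingredient splitting is not modeled.
* Haplotype calling is consumed as a precomputed diplotype-count matrix;
  upstream genotype QC (HWE, call-rate filtering, liftover) is assumed done.
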