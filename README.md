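# pgxgraph

Graph-representation learning for predicting individual medication usage from
pharmacogenetic variants.

Pharmacogenomic knowledge bases curate associations between genetic variants,
star-allele haplotypes, genes, medications and diseases. `pgxgraph` turns such
a curated relationships table into an undirected knowledge graph, learns node
embeddings with a graph convolutional network (GCN), aggregates the embeddings
of each patient's variant and haplotype nodes weighted by genotype dosage, and
trains a multilabel classifier that predicts which medications the patient
uses. The package is aimed at researchers studying whether curated biomedical
graph structure improves genotype-based prediction of medication traits.

## Model

For a graph with adjacency `A` (N nodes), the GCN propagation rule is

    H^{l+1} = σ( D̂^{-1/2} Â D̂^{-1/2} H^l W^l ),   Â = A + I,

with `D̂` the diagonal degree matrix of `Â` and node input features fixed to
the identity matrix, so only graph *structure* informs the embeddings. The
pipeline has three steps:

1. **Node embedding** — stacked graph convolutions produce an `N × F`
   embedding matrix `H`.
2. **Patient aggregation** — for patient *i* with genotype dosages `G_i`
   (expected alternate-allele counts in `[0, 2]` plus haplotype diplotype
   counts), the patient embedding is the dosage-weighted sum
   `Z_i = Σ_j G_ij · H[feature_j]`.
3. **Classification** — a feed-forward head maps `Z_i` to `k` independent
   per-medication probabilities via terminal sigmoids.

All weights are trained end-to-end with minibatch Adam on the multilabel
binary cross-entropy `−(1/n) Σ_i Σ_j [y_ij log ŷ_ij + (1−y_ij) log(1−ŷ_ij)]`,
using a 70/10/20 stratified split and selecting the epoch with the lowest
validation loss. The GCN is compared against a logistic-regression baseline,
a dense feed-forward network, and the identical GCN trained on a
degree-preserving randomization of the graph (GCN-random) — the ablation that
tests whether the *specific* wiring of the graph carries signal. Per-medication
test-set ROC AUCs are compared with paired t-tests, and predictions are
interpreted by ranking: per-medication Z-scores, within-patient ranks, and the
odds ratio (with 95% Wald CI) of actually using a medication given that it
ranks in the patient's top five.

## Worked example

The built-in simulator generates a variant–gene–chemical–disease graph and a
cohort whose medication-usage signal flows strictly through graph topology
(a drug's causal variants are those whose gene is graph-linked to the drug):

```python
from pgxgraph import SimConfig, simulate
from pgxgraph.pipeline import compare_models
from pgxgraph.evaluate import paired_ttest

sg, X, Y, _ = simulate(SimConfig(seed=0))        # 4,000 patients, 12 drugs
res = compare_models(sg.graph, X, Y, seed=0)     # shared stratified split
for kind, m in res.mean_aucs.items():
    print(f"{kind:11s} mean test AUC = {m:.3f}")
t, p = paired_ttest(res.auc_tables["gcn"].values,
                    res.auc_tables["gcn-random"].values)
print(f"GCN vs GCN-random: t = {t:.2f}, p = {p:.4f}")
```

prints

```
baseline    mean test AUC = 0.658
dnn         mean test AUC = 0.638
gcn         mean test AUC = 0.695
gcn-random  mean test AUC = 0.633
GCN vs GCN-random: t = 6.57, p = 0.0000
```

The GCN outperforms every comparator, and randomizing the graph erases the
advantage — the mean AUC ordering that motivates the graph-based approach.
The t-test here pairs the 12 per-medication AUCs of the two models.

The same stages are available from the shell:

```bash
pgxgraph simulate --out data --seed 0
pgxgraph split --labels data/labels.tsv --seed 0 --out split.json
pgxgraph train --model gcn --nodes data/graph_nodes.tsv --edges data/graph_edges.tsv \
    --features data/dosages.tsv --labels data/labels.tsv --split split.json --out ckpt
pgxgraph evaluate --checkpoint ckpt --features data/dosages.tsv \
    --labels data/labels.tsv --split split.json --out auc.tsv
pgxgraph rank --checkpoint ckpt --features data/dosages.tsv \
    --labels data/labels.tsv --split split.json --min-n 50 --out or.tsv
```

or as a one-shot pipeline with a manifest of content-hashed outputs:
`pgxgraph run --out run1 --seed 0`.

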