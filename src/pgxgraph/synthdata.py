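"""Synthetic pharmacogenomic cohorts with graph-aligned planted signal.

The generator emulates the data shapes the pipeline consumes — a multipartite
variant/haplotype/gene/chemical/disease knowledge graph, dosage matrices in
[0, 2], and binary medication-usage labels — with a liability-threshold signal
routed strictly through graph topology: a drug's causal variants are exactly
those whose gene is graph-adjacent to the drug's chemical node, and effect
sizes share a gene-level mean. An informative graph therefore genuinely helps
prediction, and a degree-preserving rewiring of the graph destroys the
signal's alignment, which is what the randomized-graph control tests.

Per-drug liability: ``L_i = sum_j beta_dj * G_ij + eps``, ``eps ~ N(0, noise_sd)``;
usage labels are ``Bernoulli(sigmoid(alpha_d + L_i))`` with the intercept
``alpha_d`` calibrated so the empirical prevalence matches the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._nn import sigmoid
from .features import FeatureMatrix
from .kg import KGEdge, KGNode, KnowledgeGraph
from .labels import LabelMatrix


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_genes: int = 40
    variants_per_gene: int = 5
    n_haplotypes: int = 8          # one per gene, attached to the first genes
    n_drugs: int = 12
    n_diseases: int = 8
    genes_per_drug: int = 3
    n_patients: int = 4000
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_scale: float = 0.4        # gene-level effect magnitude on the liability
    prevalence: float = 0.15       # target per-drug usage prevalence
    noise_sd: float = 1.0          # non-genetic liability noise
    adhoc_fraction: float = 0.2    # variant-gene edges tagged ad-hoc
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "variants_per_gene", "n_drugs", "n_patients"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class SyntheticGraph:
    """Generated graph plus the feature and medication registries."""

    graph: KnowledgeGraph
    variant_gene: dict[str, str]
    haplotype_gene: dict[str, str]
    drug_ids: list[str]
    drug_names: list[str]
    feature_ids: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def generate_kg(config: SimConfig) -> SyntheticGraph:
    """Build a multipartite knowledge graph with registries for downstream steps.

    Every variant attaches to exactly one gene; every drug attaches to
    ``genes_per_drug`` genes; diseases connect to genes and drugs. A fraction
    of the variant-gene edges is tagged with ad-hoc provenance, mirroring
    features joined to the graph outside the curated table.
    """
    rng = np.random.default_rng(config.seed)
    g = KnowledgeGraph()

    genes = [f"G{i:03d}" for i in range(config.n_genes)]
    for gid in genes:
        g.add_node(KGNode(gid, f"gene_{gid}", "gene"))

    variant_gene: dict[str, str] = {}
    v = 0
    for gi, gid in enumerate(genes):
        for _ in range(config.variants_per_gene):
            vid = f"rs{v:06d}"
            variant_gene[vid] = gid
            v += 1

    haplotype_gene: dict[str, str] = {}
    for h in range(min(config.n_haplotypes, config.n_genes)):
        hid = f"{genes[h]}*{h + 2}"
        haplotype_gene[hid] = genes[h]

    drug_ids = [f"PA{d:04d}" for d in range(config.n_drugs)]
    drug_names = [f"drug{d:02d}" for d in range(config.n_drugs)]
    for did, name in zip(drug_ids, drug_names):
        g.add_node(KGNode(did, name, "chemical", atc=f"A{did[2:]}"))
        targets = rng.choice(config.n_genes, size=min(config.genes_per_drug,
                                                      config.n_genes),
                             replace=False)
        for t in targets:
            g.add_edge(KGEdge(did, genes[int(t)], "associated", "curated"))

    for s in range(config.n_diseases):
        did = f"D{s:03d}"
        g.add_node(KGNode(did, f"disease_{s}", "disease"))
        gi = int(rng.integers(config.n_genes))
        g.add_edge(KGEdge(did, genes[gi], "associated", "curated"))
        ci = int(rng.integers(config.n_drugs))
        g.add_edge(KGEdge(did, drug_ids[ci], "associated", "curated"))

    adhoc = rng.random(len(variant_gene)) < config.adhoc_fraction
    for is_adhoc, (vid, gid) in zip(adhoc, variant_gene.items()):
        prov = "adhoc-variant-gene" if is_adhoc else "curated"
        g.add_node(KGNode(vid, vid, "variant"))
        g.add_edge(KGEdge(vid, gid, "associated", prov))
    for hid, gid in haplotype_gene.items():
        g.add_node(KGNode(hid, hid, "haplotype"))
        g.add_edge(KGEdge(hid, gid, "associated", "adhoc-haplotype-gene"))

    feature_ids = list(variant_gene) + list(haplotype_gene)
    return SyntheticGraph(g, variant_gene, haplotype_gene, drug_ids,
                          drug_names, feature_ids)


def _causal_mask(sg: SyntheticGraph) -> np.ndarray:
    """Drug x feature mask: feature's gene is graph-adjacent to the drug."""
    gene_of = {**sg.variant_gene, **sg.haplotype_gene}
    drug_genes = [set(sg.graph.neighbors(d)) for d in sg.drug_ids]
    mask = np.zeros((len(sg.drug_ids), len(sg.feature_ids)), dtype=bool)
    for j, f in enumerate(sg.feature_ids):
        for d, genes in enumerate(drug_genes):
            if gene_of[f] in genes:
                mask[d, j] = True
    return mask


def generate_cohort(
    sg: SyntheticGraph, config: SimConfig
) -> tuple[FeatureMatrix, LabelMatrix, np.ndarray]:
    """Sample dosages, liabilities and usage labels for a patient cohort.

    Returns (features, labels, beta) where ``beta[d, j]`` is the true effect
    of feature j on drug d's liability — nonzero only where the feature's
    gene is graph-connected to the drug.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, p = config.n_patients, sg.n_features
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=p)
    G = rng.binomial(2, freqs, size=(n, p)).astype(np.float64)

    mask = _causal_mask(sg)
    beta = np.zeros((len(sg.drug_ids), p))
    gene_of = {**sg.variant_gene, **sg.haplotype_gene}
    genes = sorted({g for g in gene_of.values()})
    for d in range(len(sg.drug_ids)):
        gene_mean = {
            g: rng.choice([-1.0, 1.0]) * config.beta_scale for g in genes
        }
        for j in np.flatnonzero(mask[d]):
            mu = gene_mean[gene_of[sg.feature_ids[j]]]
            beta[d, j] = rng.normal(mu, 0.25 * config.beta_scale)

    sample_ids = [f"S{i:06d}" for i in range(n)]
    Gc = G - 2.0 * freqs  # centered for a stable intercept search
    Y = np.zeros((n, len(sg.drug_ids)))
    for d in range(len(sg.drug_ids)):
        liability = Gc @ beta[d] + rng.normal(0.0, config.noise_sd, size=n)

        def gap(alpha, L=liability):
            return float(sigmoid(alpha + L).mean() - config.prevalence)

        try:
            alpha = brentq(gap, -30.0, 30.0)
        except ValueError as err:
            raise ValueError("prevalence target unreachable given effects") from err
        Y[:, d] = rng.random(n) < sigmoid(alpha + liability)

    features = FeatureMatrix(G, sample_ids, list(sg.feature_ids),
                             ["variant"] * len(sg.variant_gene)
                             + ["haplotype"] * len(sg.haplotype_gene))
    labels = LabelMatrix(Y, sample_ids, list(sg.drug_names))
    return features, labels, beta


def simulate(config: SimConfig) -> tuple[SyntheticGraph, FeatureMatrix, LabelMatrix, np.ndarray]:
    """Graph + cohort in one call."""
    sg = generate_kg(config)
    features, labels, beta = generate_cohort(sg, config)
    return sg, features, labels, beta


# ---------------------------------------------------------------------------
# fixture writing


def write_fixtures(sg: SyntheticGraph, features: FeatureMatrix,
                   labels: LabelMatrix, directory) -> dict[str, Path]:
    """Write every input dialect the pipeline readers consume.

    Emits the relationships TSV (the curated subgraph rows), node/edge graph
    TSVs, dosage and label TSVs, per-patient code lists with a code->ATC/
    ingredient mapping, and a toy VCF of the first variants. All files
    round-trip through the module readers; same inputs give identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rel_rows = []
    for e in sg.graph.edges:
        if e.provenance != "curated":
            continue
        n1, n2 = sg.graph.node(e.source), sg.graph.node(e.target)
        rel_rows.append((n1.id, n1.name, n1.type, n2.id, n2.name, n2.type,
                         e.association))
    rel = pd.DataFrame(rel_rows, columns=[
        "Entity1_id", "Entity1_name", "Entity1_type",
        "Entity2_id", "Entity2_name", "Entity2_type", "Association"])
    paths["relationships"] = directory / "relationships.tsv"
    rel.to_csv(paths["relationships"], sep="\t", index=False)

    paths["nodes"] = directory / "graph_nodes.tsv"
    paths["edges"] = directory / "graph_edges.tsv"
    sg.graph.to_files(paths["nodes"], paths["edges"])

    paths["dosages"] = directory / "dosages.tsv"
    features.to_tsv(paths["dosages"])
    paths["labels"] = directory / "labels.tsv"
    labels.to_tsv(paths["labels"])

    mapping = pd.DataFrame({
        "code": [f"C{d:03d}" for d in range(len(sg.drug_ids))],
        "atc_code": [f"A{d[2:]}" for d in sg.drug_ids],
        "ingredient": sg.drug_names,
    })
    paths["mapping"] = directory / "medication_mapping.tsv"
    mapping.to_csv(paths["mapping"], sep="\t", index=False)

    name_to_code = dict(zip(sg.drug_names, mapping["code"]))
    codes = ["|".join(name_to_code[m]
                      for m in np.array(labels.medication_ids)[row == 1.0])
             for row in labels.values]
    paths["code_lists"] = directory / "medication_codes.tsv"
    pd.DataFrame({"sample_id": labels.sample_ids, "codes": codes}).to_csv(
        paths["code_lists"], sep="\t", index=False)

    paths["vcf"] = directory / "variants.vcf"
    _write_toy_vcf(paths["vcf"], features, max_variants=10)
    return paths


def _write_toy_vcf(path, features: FeatureMatrix, max_variants: int = 10) -> None:
    variant_cols = [j for j, k in enumerate(features.feature_kinds)
                    if k == "variant"][:max_variants]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(features.sample_ids),
    ]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for rank, j in enumerate(variant_cols):
        calls = "\t".join(gt_map.get(v, "./.")
                          for v in np.round(features.values[:, j]))
        lines.append(f"1\t{1000 + rank}\t{features.feature_ids[j]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t{calls}")
    Path(path).write_text("\n".join(lines) + "\n")
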