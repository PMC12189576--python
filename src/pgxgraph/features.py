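"""Patient-by-feature dosage matrices aligned to knowledge-graph nodes.

Features are variant dosages (expected alternate-allele counts in [0, 2],
integer for hard calls, fractional for imputed genotypes) and haplotype
diplotype counts in {0, 1, 2}. Columns are matched by id against variant and
haplotype nodes of the companion graph, and columns with fewer than
``min_nonzero`` non-zero values are dropped as uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kg import KnowledgeGraph

FEATURE_KINDS = ("variant", "haplotype")


@dataclass
class FeatureMatrix:
    """Patients x features dosage matrix with stable row/column identity."""

    values: np.ndarray  # float64, missing as NaN until imputation
    sample_ids: list[str]
    feature_ids: list[str]
    feature_kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (patients x features)")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError("shape does not match sample_ids/feature_ids")
        if not self.feature_kinds:
            self.feature_kinds = ["variant"] * p
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosage values must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def select_features(self, keep: np.ndarray | list[int]) -> "FeatureMatrix":
        keep = np.asarray(keep)
        return FeatureMatrix(
            self.values[:, keep],
            list(self.sample_ids),
            [self.feature_ids[int(i)] for i in keep],
            [self.feature_kinds[int(i)] for i in keep],
        )

    def impute_train_means(self, train_index: np.ndarray | None = None) -> "FeatureMatrix":
        """Replace missing cells with per-feature means from the training rows only."""
        out = self.values.copy()
        mask = ~np.isfinite(out)
        if mask.any():
            ref = out if train_index is None else out[np.asarray(train_index)]
            with np.errstate(invalid="ignore"):
                means = np.nanmean(ref, axis=0)
            means = np.where(np.isfinite(means), means, 0.0)
            out[mask] = np.broadcast_to(means, out.shape)[mask]
        return FeatureMatrix(out, list(self.sample_ids), list(self.feature_ids),
                             list(self.feature_kinds))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_dosage_tsv(path, feature_kind: str = "variant") -> FeatureMatrix:
    """Read the dosage TSV dialect (sample_id column + one numeric column per feature).

    "NA" cells are recorded as missing (NaN) pending train-mean imputation.
    A value outside [0, 2] raises with its (sample, feature) coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    if "sample_id" not in df.columns:
        raise ValueError("dosage TSV must have a 'sample_id' column")
    sample_ids = df["sample_id"].astype(str).tolist()
    feature_ids = [c for c in df.columns if c != "sample_id"]
    values = df[feature_ids].to_numpy(dtype=np.float64)
    bad = np.argwhere(np.isfinite(values) & ((values < 0) | (values > 2)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"dosage out of [0, 2] at sample {sample_ids[i]!r},"
            f" feature {feature_ids[j]!r}: {values[i, j]}"
        )
    return FeatureMatrix(values, sample_ids, feature_ids,
                         [feature_kind] * len(feature_ids))


def read_vcf_dosages(path, sample_subset: list[str] | None = None) -> FeatureMatrix:
    """Extract per-variant dosages from a VCF (DS if present, else GT allele count).

    Variant ids are taken from the ID column (rsID). Missing genotype calls
    become NaN; a record carrying neither GT nor DS raises, naming the variant.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=sample_subset)
    samples = list(vcf.samples)
    ids: list[str] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=np.float64).ravel()
            col[col < 0] = np.nan  # cyvcf2 missing sentinel
        else:
            gts = rec.genotype.array() if rec.genotype is not None else None
            if gts is None:
                raise ValueError(f"variant {vid!r} has neither GT nor DS")
            alleles = np.asarray(gts)[:, :2].astype(np.float64)
            alleles[alleles < 0] = np.nan
            col = np.clip(alleles, 0, 1).sum(axis=1)
            col[np.isnan(alleles).any(axis=1)] = np.nan
        ids.append(vid)
        cols.append(col)
    values = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return FeatureMatrix(values, samples, ids, ["variant"] * len(ids))


def match_features_to_graph(
    feature_ids: list[str], graph: KnowledgeGraph
) -> tuple[list[str], list[str]]:
    """Partition feature ids into (graph-matched, unmatched).

    A feature matches when its id equals the id of a variant or haplotype
    node; the partition is exhaustive and disjoint, preserving input order.
    """
    node_ids = {
        n.id for n in graph.nodes if n.type in FEATURE_KINDS
    }
    kept = [f for f in feature_ids if f in node_ids]
    unmatched = [f for f in feature_ids if f not in node_ids]
    return kept, unmatched


def filter_low_count_features(matrix: FeatureMatrix, min_nonzero: int = 10) -> FeatureMatrix:
    """Drop features with fewer than ``min_nonzero`` non-zero values.

    "Non-zero" is exact comparison against 0.0 on stored values, so fractional
    imputed dosages count as non-zero; missing cells do not count. A column
    with exactly ``min_nonzero`` non-zeros is kept.
    """
    vals = matrix.values
    nonzero = np.sum(np.isfinite(vals) & (vals != 0.0), axis=0)
    keep = np.flatnonzero(nonzero >= min_nonzero)
    if keep.size == 0:
        raise ValueError("no features survive the low-count filter")
    return matrix.select_features(keep)


def concat_features(*parts: FeatureMatrix) -> FeatureMatrix:
    """Column-concatenate fragments sharing the same sample order."""
    first = parts[0]
    for p in parts[1:]:
        if p.sample_ids != first.sample_ids:
            raise ValueError("sample order mismatch between feature fragments")
    return FeatureMatrix(
        np.hstack([p.values for p in parts]),
        list(first.sample_ids),
        [f for p in parts for f in p.feature_ids],
        [k for p in parts for k in p.feature_kinds],
    )
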