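"""End-to-end orchestration: simulate/load, split, train, evaluate, rank.

This module glues the pipeline stages together for the command-line interface
and for reproducible model-comparison experiments. Desk-scale runs (thousands
of patients, hundreds of graph nodes) use a smaller minibatch than the
large-cohort default so the optimizer takes enough steps per epoch; this is
the ``DESK_TRAIN`` configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, ranking
from .features import FeatureMatrix, filter_low_count_features
from .kg import KnowledgeGraph
from .labels import LabelMatrix, filter_min_users
from .model import build_model, stratified_split, train
from .synthdata import SimConfig, simulate, write_fixtures

#: training overrides for desk-scale cohorts (n in the thousands)
DESK_TRAIN = {"batch_size": 256}

ALL_KINDS = ("baseline", "dnn", "gcn", "gcn-random")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "pgxgraph_run"
    model_kinds: tuple[str, ...] = ALL_KINDS
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    min_nonzero: int = 10
    min_users: int = 100
    min_n_rank: int = 5000
    k_top: int = 5
    n_bins: int = 5
    seed: int = 0
    sim: SimConfig | None = None
    train_overrides: dict = field(default_factory=lambda: dict(DESK_TRAIN))


@dataclass
class ComparisonResult:
    """Per-seed outcome of the model comparison."""

    auc_tables: dict[str, evaluate.AUCTable]
    mean_aucs: dict[str, float]
    histories: dict[str, dict]
    test_index: np.ndarray
    test_probs: dict[str, np.ndarray]


def compare_models(
    graph: KnowledgeGraph,
    features: FeatureMatrix,
    labels: LabelMatrix,
    seed: int = 0,
    kinds: tuple[str, ...] = ALL_KINDS,
    train_overrides: dict | None = None,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
) -> ComparisonResult:
    """Train each model kind on a shared stratified split and score the test set."""
    overrides = dict(DESK_TRAIN if train_overrides is None else train_overrides)
    splits = stratified_split(labels, fractions, seed=seed)
    te = splits[2]
    tables, means, hists, probs_by = {}, {}, {}, {}
    for kind in kinds:
        extra = ({"graph": graph, "feature_ids": features.feature_ids}
                 if kind.startswith("gcn") else {})
        model = build_model(kind, random_state=seed, **extra, **overrides)
        model, hist = train(model, features.values, labels.values, splits)
        probs = model.predict_proba(features.values[te])
        tab = evaluate.auc_table(labels.values[te], probs, labels.medication_ids)
        tables[kind] = tab
        means[kind] = tab.mean()
        hists[kind] = hist
        probs_by[kind] = probs
    return ComparisonResult(tables, means, hists, te, probs_by)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Full run: simulate (or load), filter, split, train, evaluate, rank.

    Writes graph/matrix fixtures, the four-model AUC report, paired-test
    JSON, percentile-bin means, the odds-ratio report, and a manifest with a
    content hash per output. Re-running with the same configuration
    reproduces the manifest hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim or SimConfig(seed=config.seed)
    sg, features, labels, _ = simulate(sim)
    paths = write_fixtures(sg, features, labels, out / "inputs")

    features = filter_low_count_features(features, config.min_nonzero)
    min_users = min(config.min_users, int(labels.user_counts.max()))
    labels = filter_min_users(labels, min_users)

    result = compare_models(
        sg.graph, features, labels, seed=config.seed,
        kinds=config.model_kinds, train_overrides=config.train_overrides,
        fractions=config.fractions,
    )

    report = evaluate.auc_report(result.auc_tables)
    paths["auc_report"] = out / "auc_report.tsv"
    report.to_csv(paths["auc_report"], sep="\t", index=False,
                  float_format="%.6f")

    comparisons = {}
    if "gcn" in result.auc_tables:
        for other in result.auc_tables:
            if other == "gcn":
                continue
            t, p = evaluate.paired_ttest(result.auc_tables["gcn"].values,
                                         result.auc_tables[other].values)
            comparisons[f"gcn_vs_{other.replace('-', '_')}"] = {"t": t, "p": p}
    paths["comparisons"] = out / "comparisons.json"
    paths["comparisons"].write_text(json.dumps({
        "mean_auc": result.mean_aucs, "paired_t": comparisons}, indent=2))

    bins = {kind: evaluate.percentile_bin_means(tab, config.n_bins)
            for kind, tab in result.auc_tables.items()}
    paths["bin_means"] = out / "auc_bin_means.tsv"
    pd.concat(bins, names=["model"]).reset_index(level=0).to_csv(
        paths["bin_means"], sep="\t", index=False, float_format="%.6f")

    best = max(result.mean_aucs, key=result.mean_aucs.get)
    te = result.test_index
    min_n = min(config.min_n_rank,
                int(labels.values[te].sum(axis=0).max()))
    or_report = ranking.rank_report(result.test_probs[best],
                                    labels.values[te],
                                    labels.medication_ids,
                                    k_top=min(config.k_top, labels.n_medications),
                                    min_n=min_n)
    paths["or_report"] = out / "or_report.tsv"
    or_report.to_csv(paths["or_report"], sep="\t", index=False,
                     float_format="%.6f")

    manifest = {
        "seed": config.seed,
        "model_kinds": list(config.model_kinds),
        "outputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                    for name, p in sorted(paths.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
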