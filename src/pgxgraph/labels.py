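"""Binary multilabel medication-usage matrices.

Per-patient medication-code lists are mapped to ATC codes and active
ingredient names, matched against the chemical nodes of the knowledge graph
(either the ATC code or the lowercase ingredient name may match), and
medications with fewer than ``min_users`` users are dropped. Medication
identity after mapping is the lowercased ingredient name, so multiple source
codes for one ingredient collapse to a single label column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kg import KnowledgeGraph


@dataclass
class MedicationMapping:
    """Source medication code -> (ATC code or None, lowercase ingredient name)."""

    codes: dict[str, tuple[str | None, str]]

    @classmethod
    def from_tsv(cls, path) -> "MedicationMapping":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("code", "atc_code", "ingredient"):
            if col not in df.columns:
                raise ValueError(f"mapping TSV missing column {col!r}")
        if df["code"].duplicated().any():
            dup = df.loc[df["code"].duplicated(), "code"].iloc[0]
            raise ValueError(f"duplicate medication code {dup!r} in mapping")
        codes = {
            r.code: (r.atc_code or None, r.ingredient.strip().lower())
            for r in df.itertuples(index=False)
        }
        return cls(codes)


@dataclass
class LabelMatrix:
    """Patients x medications binary usage indicators."""

    values: np.ndarray
    sample_ids: list[str]
    medication_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("label values must be 2-D")
        if self.values.shape != (len(self.sample_ids), len(self.medication_ids)):
            raise ValueError("label shape does not match ids")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("label values must be binary")

    @property
    def user_counts(self) -> np.ndarray:
        return self.values.sum(axis=0).astype(int)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_medications(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values.astype(int), columns=self.medication_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LabelMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        meds = [c for c in df.columns if c != "sample_id"]
        return cls(df[meds].to_numpy(dtype=np.float64),
                   df["sample_id"].astype(str).tolist(), meds)


def read_code_lists(path) -> dict[str, list[str]]:
    """Read the code-list TSV dialect: sample_id, pipe-separated medication codes."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "codes"):
        if col not in df.columns:
            raise ValueError(f"code-list TSV missing column {col!r}")
    return {
        r.sample_id: [c for c in r.codes.split("|") if c]
        for r in df.itertuples(index=False)
    }


def map_codes_to_medications(
    code_lists: dict[str, list[str]], mapping: MedicationMapping
) -> tuple[dict[str, set[str]], set[str]]:
    """Map each patient's codes to a deduplicated set of ingredient names.

    Returns (per-patient medication sets, set of codes that had no mapping).
    Unmapped codes are expected and reported, never fatal.
    """
    per_patient: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for sample, codes in code_lists.items():
        meds: set[str] = set()
        for code in codes:
            entry = mapping.codes.get(code)
            if entry is None:
                unmapped.add(code)
            else:
                meds.add(entry[1])
        per_patient[sample] = meds
    return per_patient, unmapped


def match_medications_to_graph(
    medications: list[str], graph: KnowledgeGraph,
    mapping: MedicationMapping | None = None,
) -> list[str]:
    """Keep medications present in the graph's chemical nodes.

    A medication is kept iff its ATC code (looked up through the mapping, when
    provided) equals a chemical node's ATC annotation, OR its lowercase
    ingredient name equals a chemical node's lowercase display name. Either
    criterion suffices.
    """
    chems = graph.nodes_of_type("chemical")
    names = {c.name.strip().lower() for c in chems}
    atcs = {c.atc for c in chems if c.atc}
    med_atc: dict[str, set[str]] = {}
    if mapping is not None:
        for atc, ingredient in mapping.codes.values():
            if atc:
                med_atc.setdefault(ingredient, set()).add(atc)
    kept = []
    for med in medications:
        key = med.strip().lower()
        if key in names or (med_atc.get(key, set()) & atcs):
            kept.append(med)
    return kept


def build_label_matrix(
    per_patient: dict[str, set[str]],
    medication_ids: list[str],
    sample_order: list[str],
) -> LabelMatrix:
    """Binary matrix with row i, column j = 1 iff patient i uses medication j.

    ``sample_order`` must cover every patient and fixes row order to match the
    companion feature matrix; patients with no mapped medications become
    all-zero rows.
    """
    missing = set(sample_order) - set(per_patient)
    extra = set(per_patient) - set(sample_order)
    if missing or extra:
        raise ValueError(
            f"sample order mismatch: {len(missing)} samples without code lists,"
            f" {len(extra)} code lists without samples"
        )
    values = np.zeros((len(sample_order), len(medication_ids)))
    med_index = {m: j for j, m in enumerate(medication_ids)}
    for i, sample in enumerate(sample_order):
        for med in per_patient[sample]:
            j = med_index.get(med)
            if j is not None:
                values[i, j] = 1.0
    return LabelMatrix(values, list(sample_order), list(medication_ids))


def filter_min_users(matrix: LabelMatrix, min_users: int = 100) -> LabelMatrix:
    """Drop medications with fewer than ``min_users`` users (boundary kept)."""
    counts = matrix.values.sum(axis=0)
    keep = np.flatnonzero(counts >= min_users)
    if keep.size == 0:
        raise ValueError("no medications survive the minimum-user filter")
    return LabelMatrix(
        matrix.values[:, keep],
        list(matrix.sample_ids),
        [matrix.medication_ids[int(j)] for j in keep],
    )
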