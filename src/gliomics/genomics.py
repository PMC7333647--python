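"""Mutation, arm-level deletion, and histology calls from variant/segment tables.

Variant classifications use a closed vocabulary; a gene is called mutated for
a patient iff at least one record carries a protein-altering classification
(missense, frameshift, nonsense).  Arm-level deletion is called from
copy-number segments by a length-weighted majority of bases whose segment
mean lies strictly below a threshold (default -0.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "CNVSegment",
    "HistologyClass",
    "VocabularyError",
    "MissingDataError",
    "QUALIFYING_CLASSES",
    "VARIANT_VOCABULARY",
    "call_mutation",
    "call_arm_deletion",
    "call_1p19q_codeletion",
    "classify_2016",
    "mutation_frequency_screen",
    "read_variant_table",
    "read_segment_table",
    "write_status_table",
]

#: Classifications that trigger a mutation call.
QUALIFYING_CLASSES = frozenset({"missense", "frameshift", "nonsense"})

#: Closed vocabulary of accepted variant classifications.
VARIANT_VOCABULARY = QUALIFYING_CLASSES | {"silent", "other"}


class VocabularyError(ValueError):
    """A variant classification outside the closed vocabulary."""


class MissingDataError(ValueError):
    """An arm status cannot be determined (no covering segments)."""


class HistologyClass(str, Enum):
    OLIGODENDROGLIOMA = "Oligodendroglioma"
    DIFFUSE_ASTROCYTOMA = "DiffuseAstrocytoma"


@dataclass(frozen=True)
class VariantRecord:
    patient_id: str
    gene: str
    variant_classification: str

    def __post_init__(self) -> None:
        if self.variant_classification not in VARIANT_VOCABULARY:
            raise VocabularyError(
                f"unknown variant classification {self.variant_classification!r}; "
                f"expected one of {sorted(VARIANT_VOCABULARY)}"
            )


@dataclass(frozen=True)
class CNVSegment:
    """A copy-number segment with 1-based inclusive coordinates."""

    patient_id: str
    chrom: str
    arm: str
    start: int
    end: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def start0(self) -> int:
        """Half-open 0-based start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """Half-open 0-based end (exclusive)."""
        return self.end

    @property
    def length(self) -> int:
        return self.end0 - self.start0


def call_mutation(
    variants: Iterable[VariantRecord], patient: str, gene: str
) -> int:
    """Return 1 iff any record for (patient, gene) has a qualifying class.

    Idempotent and order-independent; silent/other records never trigger.
    """
    for rec in variants:
        if (
            rec.patient_id == patient
            and rec.gene == gene
            and rec.variant_classification in QUALIFYING_CLASSES
        ):
            return 1
    return 0


def call_arm_deletion(
    segments: Sequence[CNVSegment],
    arm: str,
    threshold: float = -0.2,
    majority_fraction: float = 0.5,
) -> int:
    """Call an arm deleted iff the length-weighted deleted fraction > 1/2.

    A base is "deleted" when its segment mean is strictly below ``threshold``.
    The fraction is taken over covered bases only.  Raises
    :class:`MissingDataError` when no segment covers the arm.
    """
    covered = 0
    deleted = 0
    for seg in segments:
        if seg.arm != arm:
            continue
        covered += seg.length
        if seg.seg_mean < threshold:
            deleted += seg.length
    if covered == 0:
        raise MissingDataError(f"no copy-number coverage on arm {arm!r}")
    return int(deleted / covered > majority_fraction)


def call_1p19q_codeletion(
    segments: Sequence[CNVSegment],
    threshold: float = -0.2,
) -> int:
    """Codeletion iff both 1p and 19q are deleted."""
    del_1p = call_arm_deletion(segments, "1p", threshold=threshold)
    del_19q = call_arm_deletion(segments, "19q", threshold=threshold)
    return int(del_1p == 1 and del_19q == 1)


def classify_2016(idh: int, codel: int) -> HistologyClass:
    """WHO-2016 style reclassification from IDH and 1p/19q codeletion status."""
    if idh == 1 and codel == 1:
        return HistologyClass.OLIGODENDROGLIOMA
    return HistologyClass.DIFFUSE_ASTROCYTOMA


def mutation_frequency_screen(
    variants: Sequence[VariantRecord],
    patients: Sequence[str],
    min_fraction: float,
) -> list[tuple[str, float]]:
    """Genes mutated in at least ``min_fraction`` of the cohort.

    Returns (gene, rate) pairs sorted by rate descending, ties by gene symbol.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    if len(patients) == 0:
        raise ValueError("empty cohort")
    patient_set = set(patients)
    mutated: dict[str, set[str]] = {}
    for rec in variants:
        if rec.patient_id not in patient_set:
            continue
        if rec.variant_classification in QUALIFYING_CLASSES:
            mutated.setdefault(rec.gene, set()).add(rec.patient_id)
    n = len(patient_set)
    rates = {gene: len(pids) / n for gene, pids in mutated.items()}
    hits = [(g, r) for g, r in rates.items() if r >= min_fraction]
    hits.sort(key=lambda gr: (-gr[1], gr[0]))
    return hits


# ---------------------------------------------------------------------------
# Table I/O (MAF-like / SEG-like TSV)
# ---------------------------------------------------------------------------

_ARM_BY_CHROM = {"1": "1p", "19": "19q"}


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "gene", "variant_classification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return [
        VariantRecord(row.patient_id, row.gene, row.variant_classification)
        for row in df.itertuples(index=False)
    ]


def read_segment_table(path: str | Path) -> list[CNVSegment]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"patient_id", "chrom", "arm", "start", "end", "seg_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return [
        CNVSegment(
            str(row.patient_id),
            str(row.chrom),
            str(row.arm),
            int(row.start),
            int(row.end),
            float(row.seg_mean),
        )
        for row in df.itertuples(index=False)
    ]


def per_patient_status(
    variants: Sequence[VariantRecord],
    segments: Sequence[CNVSegment],
    patients: Sequence[str],
    genes: Sequence[str] = ("CIC", "IDH1", "FUBP1"),
    threshold: float = -0.2,
) -> pd.DataFrame:
    """Mutation + codeletion + histology status table, one row per patient."""
    by_patient_var: dict[str, list[VariantRecord]] = {p: [] for p in patients}
    for rec in variants:
        if rec.patient_id in by_patient_var:
            by_patient_var[rec.patient_id].append(rec)
    by_patient_seg: dict[str, list[CNVSegment]] = {p: [] for p in patients}
    for seg in segments:
        if seg.patient_id in by_patient_seg:
            by_patient_seg[seg.patient_id].append(seg)

    rows = []
    for pid in patients:
        row: dict[str, object] = {"patient_id": pid}
        for gene in genes:
            row[f"{gene}_mutant"] = call_mutation(by_patient_var[pid], pid, gene)
        try:
            codel = call_1p19q_codeletion(by_patient_seg[pid], threshold=threshold)
        except MissingDataError:
            codel = None
        row["codeletion_1p19q"] = codel
        idh = row.get("IDH1_mutant", 0)
        row["histology_2016"] = (
            classify_2016(int(idh), codel).value if codel is not None else None
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_status_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
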