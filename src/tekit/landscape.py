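"""Repeat landscape summaries: percent of dataset and Gb of genome per label.

Annotations are per-read intervals (0-based, half-open) tagged with a
superfamily label and a coarse category.  Overlaps are resolved by category
precedence before summarization, so per-label base counts partition the
dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CATEGORIES = ("known_TE", "unknown_repeat", "simple_repeat")
_PRECEDENCE = {cat: i for i, cat in enumerate(CATEGORIES)}
NONREPETITIVE = "nonrepetitive"


@dataclass(frozen=True)
class Annotation:
    """One annotated interval on a read (0-based, half-open)."""

    read_id: str
    start: int
    end: int
    label: str
    category: str

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(
                f"annotation on {self.read_id!r}: bad interval [{self.start}, {self.end})"
            )
        if self.category not in _PRECEDENCE:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _subtract(start: int, end: int, claimed: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Fragments of [start, end) not covered by the (disjoint) claimed list."""
    fragments = []
    cursor = start
    for cs, ce in sorted(claimed):
        if ce <= cursor or cs >= end:
            continue
        if cs > cursor:
            fragments.append((cursor, min(cs, end)))
        cursor = max(cursor, ce)
        if cursor >= end:
            break
    if cursor < end:
        fragments.append((cursor, end))
    return fragments


def resolve_overlaps(records: Iterable[Annotation]) -> list[Annotation]:
    """Make per-read annotations disjoint.

    Precedence: known_TE > unknown_repeat > simple_repeat; ties broken by
    longer annotation, then lexicographic label.  Lower-precedence
    annotations are trimmed (possibly split) around higher-precedence ones;
    exact duplicates collapse to one record.
    """
    by_read: dict[str, list[Annotation]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)

    resolved: list[Annotation] = []
    for read_id in sorted(by_read):
        claimed: list[tuple[int, int]] = []
        ordered = sorted(
            by_read[read_id],
            key=lambda r: (_PRECEDENCE[r.category], -r.length, r.label, r.start),
        )
        for rec in ordered:
            for s, e in _subtract(rec.start, rec.end, claimed):
                resolved.append(
                    Annotation(read_id=rec.read_id, start=s, end=e,
                               label=rec.label, category=rec.category)
                )
                claimed.append((s, e))
    resolved.sort(key=lambda r: (r.read_id, r.start))
    return resolved


@dataclass(frozen=True)
class LandscapeSummary:
    """Per-label bp totals with percent-of-dataset and Gb-of-genome views."""

    bp_by_label: dict[str, int]
    category_by_label: dict[str, str]
    dataset_bp: int
    genome_size_gb: float

    @property
    def annotated_bp(self) -> int:
        return sum(self.bp_by_label.values())

    @property
    def nonrepetitive_bp(self) -> int:
        return self.dataset_bp - self.annotated_bp

    def percent(self, label: str) -> float:
        bp = self.nonrepetitive_bp if label == NONREPETITIVE else self.bp_by_label[label]
        return 100.0 * bp / self.dataset_bp

    def gb(self, label: str) -> float:
        return self.percent(label) / 100.0 * self.genome_size_gb

    @property
    def coverage_pct(self) -> float:
        """Dataset size as a percentage of the genome."""
        return 100.0 * self.dataset_bp / (self.genome_size_gb * 1e9)

    def category_percent(self, category: str) -> float:
        if category == NONREPETITIVE:
            return self.percent(NONREPETITIVE)
        bp = sum(
            v for k, v in self.bp_by_label.items()
            if self.category_by_label[k] == category
        )
        return 100.0 * bp / self.dataset_bp

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "label": label,
                "category": self.category_by_label[label],
                "bp": bp,
                "percent": self.percent(label),
                "gb": self.gb(label),
            }
            for label, bp in self.bp_by_label.items()
        ]
        rows.append(
            {
                "label": NONREPETITIVE,
                "category": NONREPETITIVE,
                "bp": self.nonrepetitive_bp,
                "percent": self.percent(NONREPETITIVE),
                "gb": self.gb(NONREPETITIVE),
            }
        )
        df = pd.DataFrame(rows)
        return df.sort_values(["bp", "label"], ascending=[False, True]).reset_index(drop=True)


def summarize(
    records: Sequence[Annotation], genome_size_gb: float, dataset_bp: int
) -> LandscapeSummary:
    """Summarize disjoint annotations into a :class:`LandscapeSummary`.

    ``dataset_bp`` is the total size of the (filtered) read dataset; the
    unannotated remainder is reported as nonrepetitive.
    """
    if dataset_bp <= 0:
        raise ValueError("dataset_bp must be positive")
    if genome_size_gb <= 0:
        raise ValueError("genome_size_gb must be positive")
    bp_by_label: dict[str, int] = {}
    category_by_label: dict[str, str] = {}
    for rec in records:
        bp_by_label[rec.label] = bp_by_label.get(rec.label, 0) + rec.length
        category_by_label.setdefault(rec.label, rec.category)
    annotated = sum(bp_by_label.values())
    if annotated > dataset_bp:
        raise ValueError(
            f"annotated bp ({annotated}) exceeds dataset_bp ({dataset_bp}); "
            "resolve overlaps first"
        )
    return LandscapeSummary(
        bp_by_label=bp_by_label,
        category_by_label=category_by_label,
        dataset_bp=dataset_bp,
        genome_size_gb=genome_size_gb,
    )


def rank_superfamilies(summary: LandscapeSummary, k: int | None = None) -> list[str]:
    """Known-TE labels ranked by bp descending; ties break lexicographically."""
    labels = [
        label
        for label in summary.bp_by_label
        if summary.category_by_label[label] == "known_TE"
    ]
    labels.sort(key=lambda lb: (-summary.bp_by_label[lb], lb))
    return labels if k is None else labels[:k]


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read a BED-like TSV: read_id, start, end, label, category."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(
                    f"{path}: line {lineno}: need read_id, start, end, label, category"
                )
            records.append(
                Annotation(
                    read_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    label=parts[3],
                    category=parts[4],
                )
            )
    return records


def write_annotations(records: Iterable[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.read_id}\t{rec.start}\t{rec.end}\t{rec.label}\t{rec.category}\n")
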