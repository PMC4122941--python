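"""Copy-vs-consensus divergence and age (divergence) distributions.

The consensus of a repeat family is treated as the ancestral ("master")
sequence.  Each copy's observed mismatch proportion is refined by excluding
substitutions inferred to have occurred on active master-element lineages --
identical base changes shared between copies -- and then corrected for
multiple hits with the Jukes-Cantor model.  Corrected divergences, binned
at 1% resolution and weighted by bp (or read count), form the family's age
distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import PairwiseAlignment, RepeatFamily

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")

#: substitution key: (consensus position, derived base)
SubKey = tuple[int, str]


@dataclass(frozen=True)
class Substitution:
    """A single base difference between a copy and its consensus."""

    copy_id: str
    consensus_pos: int
    ancestral_base: str
    derived_base: str

    def __post_init__(self) -> None:
        if self.ancestral_base == self.derived_base:
            raise ValueError("substitution with identical ancestral and derived base")

    @property
    def key(self) -> SubKey:
        return (self.consensus_pos, self.derived_base)


@dataclass(frozen=True)
class DivergenceRecord:
    """Raw and refined divergence estimates for one copy."""

    copy_id: str
    aligned_sites: int
    raw_sub_count: int
    excluded_sub_count: int
    p_raw: float
    p_refined: float
    d_raw: float
    d_refined: float
    copy_len_bp: int

    @property
    def identity(self) -> float:
        """Pre-refinement identity to consensus, ``1 - p_raw``."""
        return 1.0 - self.p_raw


def extract_substitutions(aln: PairwiseAlignment) -> list[Substitution]:
    """List every column where both rows carry differing A/C/G/T bases.

    Gap columns and columns containing N contribute nothing.  Positions are
    reported in consensus coordinates.
    """
    subs = []
    for pos, copy_char, cons_char in aln.columns():
        if copy_char in BASES and cons_char in BASES and copy_char != cons_char:
            subs.append(
                Substitution(
                    copy_id=aln.copy_id,
                    consensus_pos=pos,
                    ancestral_base=cons_char,
                    derived_base=copy_char,
                )
            )
    return subs


def substitution_keys(aln: PairwiseAlignment) -> set[SubKey]:
    return {s.key for s in extract_substitutions(aln)}


def aligned_sites(aln: PairwiseAlignment) -> int:
    """Number of columns with A/C/G/T in both rows."""
    return sum(
        1
        for c, k in zip(aln.gapped_copy, aln.gapped_consensus)
        if c in BASES and k in BASES
    )


def detect_master_substitutions(
    family: RepeatFamily,
    min_shared_subs: int = 2,
    min_copies: int = 2,
) -> set[SubKey]:
    """Flag substitution keys attributable to active master-element lineages.

    Pairwise rule: for every pair of copies, collect the substitution keys
    (position, derived base) present in both; whenever a pair shares at
    least ``min_shared_subs`` keys, the entire shared set is flagged.  The
    result is the union over all pairs, restricted to keys carried by at
    least ``min_copies`` copies.  Families with fewer than two copies yield
    an empty set.
    """
    if family.n_copies < 2:
        return set()
    keysets = [substitution_keys(aln) for aln in family.alignments]
    flagged: set[SubKey] = set()
    for a, b in combinations(keysets, 2):
        shared = a & b
        if len(shared) >= min_shared_subs:
            flagged |= shared
    if min_copies > 2 and flagged:
        counts: dict[SubKey, int] = {}
        for keys in keysets:
            for key in keys:
                counts[key] = counts.get(key, 0) + 1
        flagged = {key for key in flagged if counts[key] >= min_copies}
    return flagged


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance ``d = -(3/4) ln(1 - 4p/3)``.

    Valid for ``0 <= p < 0.75``; at or beyond 0.75 the correction saturates
    and a ``ValueError`` is raised.
    """
    if not 0.0 <= p < 0.75:
        raise ValueError(f"proportion {p} outside the Jukes-Cantor domain [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def divergence_records(
    family: RepeatFamily, flagged: set[SubKey]
) -> list[DivergenceRecord]:
    """Per-copy raw and refined divergence given flagged master keys.

    Copies with zero aligned sites (or mismatch proportions at Jukes-Cantor
    saturation) are skipped with a logged count.
    """
    records = []
    skipped = 0
    for aln in family.alignments:
        sites = aligned_sites(aln)
        if sites == 0:
            skipped += 1
            continue
        subs = extract_substitutions(aln)
        raw = len(subs)
        excluded = sum(1 for s in subs if s.key in flagged)
        p_raw = raw / sites
        p_ref = (raw - excluded) / sites
        if p_raw >= 0.75:
            skipped += 1
            continue
        records.append(
            DivergenceRecord(
                copy_id=aln.copy_id,
                aligned_sites=sites,
                raw_sub_count=raw,
                excluded_sub_count=excluded,
                p_raw=p_raw,
                p_refined=p_ref,
                d_raw=jukes_cantor(p_raw),
                d_refined=jukes_cantor(p_ref),
                copy_len_bp=aln.copy_len_bp,
            )
        )
    if skipped:
        logger.info(
            "family %s: skipped %d cop(ies) with no usable aligned sites",
            family.family_id, skipped,
        )
    return records


def filter_copies(
    records: Iterable[DivergenceRecord],
    min_len_bp: int = 100,
    min_identity: float = 0.80,
) -> list[DivergenceRecord]:
    """Keep copies strictly longer than ``min_len_bp`` and at least
    ``min_identity`` identical (pre-refinement) to the consensus.

    Boundary readings are deliberate: strict ``>`` for length, ``>=`` for
    identity.
    """
    return [
        r
        for r in records
        if r.copy_len_bp > min_len_bp and r.identity >= min_identity - 1e-12
    ]


@dataclass(frozen=True)
class AgeHistogram:
    """Percent-of-data per divergence bin (half-open bins ``[k*w, (k+1)*w)``)."""

    bin_width_pct: float
    bin_edges: tuple[float, ...]  # length n_bins + 1
    values: tuple[float, ...]  # percent of total_data per bin
    weighting: str  # "bp" or "read_count"
    total_data: float

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def mode_bin(self) -> int:
        """Index of the highest bin (first on ties)."""
        return int(np.argmax(self.values))

    def to_rows(self) -> list[tuple[float, float, float]]:
        return [
            (self.bin_edges[i], self.bin_edges[i + 1], self.values[i])
            for i in range(self.n_bins)
        ]


def age_histogram(
    records: Sequence[DivergenceRecord],
    bin_width_pct: float = 1.0,
    weighting: str = "bp",
    total_data: float | None = None,
    min_range_pct: float = 20.0,
) -> AgeHistogram:
    """Bin refined divergences (as percent) into an :class:`AgeHistogram`.

    Each copy contributes its weight -- ``copy_len_bp`` for ``bp``
    weighting, 1 for ``read_count`` -- to the half-open bin containing
    ``100 * d_refined``.  Values are percent of ``total_data``; when
    ``total_data`` is None the summed weight of *records* is used, so the
    histogram sums to 100.
    """
    if weighting not in ("bp", "read_count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if bin_width_pct <= 0:
        raise ValueError("bin width must be positive")
    weights = [r.copy_len_bp if weighting == "bp" else 1 for r in records]
    if total_data is None:
        total_data = float(sum(weights))
    if total_data <= 0:
        raise ValueError("total_data must be positive")
    d_pct = [100.0 * r.d_refined for r in records]
    top = max([min_range_pct] + d_pct)
    n_bins = max(1, int(math.floor(top / bin_width_pct)) + 1)
    values = np.zeros(n_bins)
    for d, w in zip(d_pct, weights):
        values[int(d // bin_width_pct)] += w
    values = 100.0 * values / total_data
    edges = tuple(round(i * bin_width_pct, 10) for i in range(n_bins + 1))
    return AgeHistogram(
        bin_width_pct=bin_width_pct,
        bin_edges=edges,
        values=tuple(float(v) for v in values),
        weighting=weighting,
        total_data=total_data,
    )


def local_maxima(values: Sequence[float], min_height: float = 0.0) -> int:
    """Count local maxima after flooring small bins and merging equal runs.

    Bins below ``min_height`` are treated as zero; adjacent equal bins are
    merged before counting, so a flat-topped peak counts once.  Edge bins
    count as maxima when they exceed their single neighbor.
    """
    floored = [v if v >= min_height else 0.0 for v in values]
    merged: list[float] = []
    for v in floored:
        if not merged or v != merged[-1]:
            merged.append(v)
    n = len(merged)
    count = 0
    for i, v in enumerate(merged):
        if v <= 0:
            continue
        left_ok = i == 0 or merged[i - 1] < v
        right_ok = i == n - 1 or merged[i + 1] < v
        if left_ok and right_ok:
            count += 1
    return count


def plot_histogram(hist: AgeHistogram, path: str) -> None:
    """Render an age histogram as a bar chart (divergence % vs % of data)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    lefts = hist.bin_edges[:-1]
    ax.bar(lefts, hist.values, width=hist.bin_width_pct, align="edge",
           edgecolor="black", linewidth=0.4)
    ax.set_xlabel("sequence divergence from consensus (%)")
    unit = "bp" if hist.weighting == "bp" else "reads"
    ax.set_ylabel(f"% of total data ({unit})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
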