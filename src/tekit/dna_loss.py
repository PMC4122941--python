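"""DNA loss rate through small indels in non-LTR retrotransspon copies.

Copies of decaying non-LTR retrotransposons are aligned against their
family consensus (trimmed to a protein-coding region).  Families whose
substitutions are nonrandomly distributed across codon positions are
excluded (chi-square, P < alpha) -- such patterns betray substitutions that
accumulated on still-active master lineages rather than neutral decay.
Small (<= 30 bp) insertion and deletion events, and Jukes-Cantor-corrected
substitution totals, are then pooled over the retained copies; the loss
rate is (bp deleted - bp inserted) per substitution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .alignment_io import GAP, PairwiseAlignment, RepeatFamily
from .te_age import BASES, aligned_sites, extract_substitutions, jukes_cantor

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class IndelEvent:
    """One maximal gap run in a pairwise alignment.

    ``consensus_pos`` is the 1-based consensus coordinate of the column
    preceding the event (0 when the event opens the aligned region).
    """

    copy_id: str
    kind: str  # "insertion" | "deletion"
    consensus_pos: int
    length_bp: int
    seq: str
    in_homopolymer: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.length_bp != len(self.seq):
            raise ValueError("indel length does not match its sequence")
        if self.length_bp < 1:
            raise ValueError("indel length must be >= 1")


@dataclass(frozen=True)
class CodonTestResult:
    """Chi-square test of substitution counts against uniform codon positions."""

    family_id: str
    counts: tuple[int, int, int]
    chi2_stat: float
    p_value: float
    excluded: bool
    tested: bool = True  # False when no substitutions were available

    @property
    def n_total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class ConsensusAcceptance:
    """Whether a family's consensus meets the length/support thresholds."""

    family_id: str
    consensus_len: int
    n_qualifying_copies: int
    accepted: bool


@dataclass(frozen=True)
class LossRateResult:
    """Pooled indel/substitution tallies and derived loss-rate statistics.

    ``loss_rate`` is (bp_deleted - bp_inserted) / n_substitutions_jc;
    ratio and mean-size fields are NaN when their denominator is zero.
    """

    n_insertions: int
    n_deletions: int
    n_substitutions_jc: float
    bp_inserted: int
    bp_deleted: int
    loss_rate: float
    mean_del_size: float
    mean_ins_size: float
    del_ins_ratio: float
    n_copies: int

    @classmethod
    def from_tallies(
        cls,
        *,
        n_insertions: int,
        n_deletions: int,
        bp_inserted: int,
        bp_deleted: int,
        n_substitutions_jc: float,
        n_copies: int,
    ) -> "LossRateResult":
        if n_substitutions_jc > 0:
            loss = (bp_deleted - bp_inserted) / n_substitutions_jc
        elif bp_deleted == bp_inserted == 0:
            loss = 0.0
        else:
            loss = math.nan  # undefined: indels but no substitutions
        return cls(
            n_insertions=n_insertions,
            n_deletions=n_deletions,
            n_substitutions_jc=n_substitutions_jc,
            bp_inserted=bp_inserted,
            bp_deleted=bp_deleted,
            loss_rate=loss,
            mean_del_size=bp_deleted / n_deletions if n_deletions else math.nan,
            mean_ins_size=bp_inserted / n_insertions if n_insertions else math.nan,
            del_ins_ratio=n_deletions / n_insertions if n_insertions else math.nan,
            n_copies=n_copies,
        )


# ---------------------------------------------------------------------------
# consensus acceptance and the codon-position filter


def accept_consensus(
    family: RepeatFamily,
    min_consensus_len: int = 330,
    min_copies: int = 5,
    min_copy_len: int = 300,
    min_identity: float = 0.80,
) -> ConsensusAcceptance:
    """Apply the consensus-acceptance thresholds.

    Accepted iff the consensus is strictly longer than ``min_consensus_len``
    and at least ``min_copies`` member copies each exceed ``min_copy_len``
    bp and are at least ``min_identity`` identical to the consensus.
    """
    qualifying = 0
    for aln in family.alignments:
        sites = aligned_sites(aln)
        if sites == 0 or aln.copy_len_bp <= min_copy_len:
            continue
        identity = 1.0 - len(extract_substitutions(aln)) / sites
        if identity >= min_identity - 1e-12:
            qualifying += 1
    accepted = family.consensus_len > min_consensus_len and qualifying >= min_copies
    return ConsensusAcceptance(
        family_id=family.family_id,
        consensus_len=family.consensus_len,
        n_qualifying_copies=qualifying,
        accepted=accepted,
    )


def longest_orf_frame(consensus: str) -> int:
    """Frame offset (0/1/2) with the longest stop-codon-free codon run."""
    best_run, best_offset = -1, 0
    for offset in (0, 1, 2):
        run = longest = 0
        for i in range(offset, len(consensus) - 2, 3):
            if consensus[i : i + 3] in STOP_CODONS:
                run = 0
            else:
                run += 1
                longest = max(longest, run)
        if longest > best_run:
            best_run, best_offset = longest, offset
    return best_offset


def codon_substitution_counts(
    family: RepeatFamily, orf_frame_offset: int = 0
) -> tuple[int, int, int]:
    """Substitution counts per codon position, pooled over the family's copies.

    A substitution at consensus position ``p`` lands at codon position
    ``((p - 1 - offset) mod 3) + 1``; substitutions upstream of the frame
    start are excluded.
    """
    if orf_frame_offset not in (0, 1, 2):
        raise ValueError("frame offset must be 0, 1 or 2")
    counts = [0, 0, 0]
    for aln in family.alignments:
        for sub in extract_substitutions(aln):
            if sub.consensus_pos <= orf_frame_offset:
                continue
            counts[(sub.consensus_pos - 1 - orf_frame_offset) % 3] += 1
    return (counts[0], counts[1], counts[2])


def chi_square_uniform(
    counts: tuple[int, int, int], alpha: float = 0.05, family_id: str = ""
) -> CodonTestResult:
    """Chi-square test of *counts* against a uniform expectation (df = 2).

    With zero substitutions the test is not applicable; the family is
    retained and flagged via ``tested=False``.
    """
    n_total = sum(counts)
    if n_total == 0:
        return CodonTestResult(
            family_id=family_id,
            counts=tuple(counts),
            chi2_stat=0.0,
            p_value=math.nan,
            excluded=False,
            tested=False,
        )
    stat, p = stats.chisquare(list(counts))
    return CodonTestResult(
        family_id=family_id,
        counts=tuple(counts),
        chi2_stat=float(stat),
        p_value=float(p),
        excluded=bool(p < alpha),
    )


# ---------------------------------------------------------------------------
# indel events


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' in *row* as (start_col, length), 0-based columns."""
    runs = []
    start = None
    for i, ch in enumerate(row):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(row) - start))
    return runs


def count_indels(aln: PairwiseAlignment, cap: int = 30) -> list[IndelEvent]:
    """Extract small indel events from one alignment.

    Each maximal gap run in the copy row is one deletion (of consensus
    sequence); each maximal gap run in the consensus row is one insertion
    (of copy sequence).  Events longer than *cap* bp are discarded with a
    logged count.
    """
    # consensus coordinate of each column's preceding consensus base
    prev_pos = []
    pos = aln.consensus_start - 1
    for k in aln.gapped_consensus:
        prev_pos.append(pos)
        if k != GAP:
            pos += 1

    events: list[IndelEvent] = []
    capped = 0
    for start, length in _gap_runs(aln.gapped_copy):
        if length > cap:
            capped += 1
            continue
        events.append(
            IndelEvent(
                copy_id=aln.copy_id,
                kind="deletion",
                consensus_pos=prev_pos[start],
                length_bp=length,
                seq=aln.gapped_consensus[start : start + length],
            )
        )
    for start, length in _gap_runs(aln.gapped_consensus):
        if length > cap:
            capped += 1
            continue
        events.append(
            IndelEvent(
                copy_id=aln.copy_id,
                kind="insertion",
                consensus_pos=prev_pos[start],
                length_bp=length,
                seq=aln.gapped_copy[start : start + length],
            )
        )
    if capped:
        logger.info("%s: discarded %d indel(s) above the %d bp cap", aln.copy_id, capped, cap)
    events.sort(key=lambda e: (e.consensus_pos, e.kind))
    return events


def flag_homopolymer_indels(
    aln: PairwiseAlignment, events: Iterable[IndelEvent], min_run: int = 5
) -> list[IndelEvent]:
    """Set ``in_homopolymer`` on mononucleotide indels inside long base runs.

    An event is flagged iff its sequence is a single repeated base and that
    base's run -- the event plus adjacent identical consensus bases -- spans
    at least ``min_run`` bp.  Flagged events should be excluded from all
    tallies (454-style sequencing miscalls homopolymer lengths).
    """
    cons = aln.ungapped_consensus()
    offset = aln.consensus_start  # consensus coordinate of cons[0]
    flagged = []
    for ev in events:
        bases = set(ev.seq)
        if len(bases) != 1 or next(iter(bases)) not in BASES:
            flagged.append(ev)
            continue
        base = ev.seq[0]
        run = ev.length_bp
        # walk left from the column preceding the event
        i = ev.consensus_pos - offset
        while i >= 0 and i < len(cons) and cons[i] == base:
            run += 1
            i -= 1
        # walk right past the event's own consensus footprint
        skip = ev.length_bp if ev.kind == "deletion" else 0
        j = ev.consensus_pos - offset + 1 + skip
        while 0 <= j < len(cons) and cons[j] == base:
            run += 1
            j += 1
        if run >= min_run:
            flagged.append(
                IndelEvent(
                    copy_id=ev.copy_id,
                    kind=ev.kind,
                    consensus_pos=ev.consensus_pos,
                    length_bp=ev.length_bp,
                    seq=ev.seq,
                    in_homopolymer=True,
                )
            )
        else:
            flagged.append(ev)
    return flagged


# ---------------------------------------------------------------------------
# screening and the pooled loss rate


def screen_families(
    families: Sequence[RepeatFamily],
    alpha: float = 0.05,
    frame_offsets: dict[str, int] | None = None,
    min_consensus_len: int = 330,
    min_copies: int = 5,
    min_copy_len: int = 300,
    min_identity: float = 0.80,
) -> tuple[list[RepeatFamily], list[ConsensusAcceptance], list[CodonTestResult]]:
    """Apply consensus acceptance then the codon-position chi-square filter.

    Frame offsets default to :func:`longest_orf_frame` of each consensus.
    Returns the retained families along with both per-family reports.
    """
    frame_offsets = frame_offsets or {}
    acceptances = []
    codon_tests = []
    retained = []
    for family in families:
        acc = accept_consensus(
            family,
            min_consensus_len=min_consensus_len,
            min_copies=min_copies,
            min_copy_len=min_copy_len,
            min_identity=min_identity,
        )
        acceptances.append(acc)
        if not acc.accepted:
            continue
        offset = frame_offsets.get(family.family_id)
        if offset is None:
            offset = longest_orf_frame(family.consensus)
        test = chi_square_uniform(
            codon_substitution_counts(family, offset), alpha=alpha,
            family_id=family.family_id,
        )
        codon_tests.append(test)
        if not test.excluded:
            retained.append(family)
    n_excluded = sum(1 for t in codon_tests if t.excluded)
    logger.info(
        "screening: %d/%d families pass consensus acceptance, %d excluded by chi-square",
        len(codon_tests), len(families), n_excluded,
    )
    return retained, acceptances, codon_tests


def loss_rate(
    families: Sequence[RepeatFamily],
    alpha: float = 0.05,
    min_run: int = 5,
    indel_cap: int = 30,
    frame_offsets: dict[str, int] | None = None,
    screen: bool = True,
    exclude_homopolymer: bool = True,
) -> LossRateResult:
    """Pooled DNA loss rate over all copies of the given families.

    With ``screen=True`` (default) the consensus-acceptance and chi-square
    filters are applied first; pass ``screen=False`` when the input is
    already screened.  Per-copy substitution proportions are Jukes-Cantor
    corrected individually (the correction is nonlinear) and summed as
    ``aligned_sites * d``.
    """
    if screen:
        families, _, _ = screen_families(families, alpha=alpha, frame_offsets=frame_offsets)
    n_ins = n_del = bp_ins = bp_del = 0
    n_sub_jc = 0.0
    n_copies = 0
    n_homopolymer = 0
    for family in families:
        for aln in family.alignments:
            sites = aligned_sites(aln)
            if sites == 0:
                logger.info("%s: no aligned sites; copy skipped", aln.copy_id)
                continue
            p = len(extract_substitutions(aln)) / sites
            if p >= 0.75:
                logger.info("%s: divergence at Jukes-Cantor saturation; copy skipped",
                            aln.copy_id)
                continue
            n_copies += 1
            n_sub_jc += sites * jukes_cantor(p)
            events = count_indels(aln, cap=indel_cap)
            if exclude_homopolymer:
                events = flag_homopolymer_indels(aln, events, min_run=min_run)
                n_homopolymer += sum(1 for e in events if e.in_homopolymer)
                events = [e for e in events if not e.in_homopolymer]
            for ev in events:
                if ev.kind == "deletion":
                    n_del += 1
                    bp_del += ev.length_bp
                else:
                    n_ins += 1
                    bp_ins += ev.length_bp
    if n_homopolymer:
        logger.info("excluded %d homopolymer-associated indel(s)", n_homopolymer)
    return LossRateResult.from_tallies(
        n_insertions=n_ins,
        n_deletions=n_del,
        bp_inserted=bp_ins,
        bp_deleted=bp_del,
        n_substitutions_jc=n_sub_jc,
        n_copies=n_copies,
    )
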