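"""Sequence and pairwise-alignment I/O.

Two on-disk alignment formats are supported:

* a canonical, bit-exact text format: records separated by blank lines,
  line 1 ``#aln <copy_id> <family_id> <consensus_start> <consensus_end>
  <strand> <source_read_id>`` (space-delimited), line 2 the gapped copy row,
  line 3 the gapped consensus row;
* RepeatMasker ``.align`` block output, parsed best-effort (dialects drift
  across RepeatMasker versions, so unparseable blocks are skipped and
  counted rather than fatal).

All alignments are stored in consensus (+) orientation: complemented hits
are reverse-complemented on input so downstream arithmetic runs on a single
coordinate system.  Consensus coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

GAP = "-"
ALIGNMENT_ALPHABET = frozenset("ACGTN-")
_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")
_NON_BASE = re.compile(r"[^ACGTN]")
_NON_BASE_GAPPED = re.compile(r"[^ACGTN-]")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed at all."""


class ValidationError(ValueError):
    """Raised when a parsed record violates an alignment invariant."""


def sanitize_sequence(seq: str) -> str:
    """Uppercase *seq* and map any character outside {A,C,G,T,N} to N."""
    return _NON_BASE.sub("N", seq.upper())


def sanitize_gapped(seq: str) -> str:
    """Like :func:`sanitize_sequence` but preserves ``-`` gap characters."""
    return _NON_BASE_GAPPED.sub("N", seq.upper())


def reverse_complement(seq: str) -> str:
    """Reverse-complement a (possibly gapped) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PairwiseAlignment:
    """One gapped copy-vs-consensus alignment in consensus (+) orientation.

    Invariants (enforced at construction):

    * both rows have equal length;
    * no column is gapped in both rows;
    * ``consensus_end - consensus_start + 1`` equals the number of non-gap
      characters in the consensus row.
    """

    copy_id: str
    family_id: str
    gapped_copy: str
    gapped_consensus: str
    consensus_start: int
    consensus_end: int
    strand: str = "+"
    source_read_id: str = ""

    def __post_init__(self) -> None:
        if len(self.gapped_copy) != len(self.gapped_consensus):
            raise ValidationError(
                f"alignment {self.copy_id!r}: row length mismatch "
                f"({len(self.gapped_copy)} vs {len(self.gapped_consensus)})"
            )
        bad = (set(self.gapped_copy) | set(self.gapped_consensus)) - ALIGNMENT_ALPHABET
        if bad:
            raise ValidationError(
                f"alignment {self.copy_id!r}: illegal characters {sorted(bad)}"
            )
        for i, (c, k) in enumerate(zip(self.gapped_copy, self.gapped_consensus)):
            if c == GAP and k == GAP:
                raise ValidationError(
                    f"alignment {self.copy_id!r}: column {i + 1} gapped in both rows"
                )
        span = self.consensus_end - self.consensus_start + 1
        n_cons = len(self.gapped_consensus) - self.gapped_consensus.count(GAP)
        if span != n_cons:
            raise ValidationError(
                f"alignment {self.copy_id!r}: consensus span {span} != "
                f"{n_cons} non-gap consensus characters"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"alignment {self.copy_id!r}: bad strand {self.strand!r}")

    @property
    def copy_len_bp(self) -> int:
        """Ungapped length of the copy row."""
        return len(self.gapped_copy) - self.gapped_copy.count(GAP)

    @property
    def consensus_span(self) -> int:
        return self.consensus_end - self.consensus_start + 1

    def ungapped_copy(self) -> str:
        return self.gapped_copy.replace(GAP, "")

    def ungapped_consensus(self) -> str:
        return self.gapped_consensus.replace(GAP, "")

    def columns(self) -> Iterable[tuple[int, str, str]]:
        """Yield ``(consensus_pos, copy_char, consensus_char)`` per column.

        ``consensus_pos`` is the 1-based consensus coordinate of the column;
        for insertion columns (consensus gap) it is the coordinate of the
        preceding consensus base (possibly ``consensus_start - 1``).
        """
        pos = self.consensus_start - 1
        for c, k in zip(self.gapped_copy, self.gapped_consensus):
            if k != GAP:
                pos += 1
            yield pos, c, k


TE_CLASSES = ("LTR", "non-LTR", "DNA", "unknown", "simple")


def classify_superfamily(label: str) -> str:
    """Map a superfamily label (e.g. ``"LTR/Gypsy"``) to a coarse TE class."""
    u = label.upper()
    if u.startswith("LTR"):
        return "LTR"
    if u.startswith(("LINE", "SINE", "PENELOPE", "NONLTR", "NON-LTR", "RETROPOSON")):
        return "non-LTR"
    if u.startswith(("DNA", "RC/")):
        return "DNA"
    if u.startswith(("SIMPLE", "SATELLITE", "LOW_COMPLEXITY", "TANDEM")):
        return "simple"
    return "unknown"


@dataclass
class RepeatFamily:
    """A consensus sequence plus its classification and member alignments."""

    family_id: str
    consensus: str
    superfamily: str = "Unknown"
    te_class: str | None = None
    alignments: list[PairwiseAlignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if GAP in self.consensus:
            raise ValidationError(f"family {self.family_id!r}: consensus contains gaps")
        self.consensus = sanitize_sequence(self.consensus)
        if self.te_class is None:
            self.te_class = classify_superfamily(self.superfamily)
        if self.te_class not in TE_CLASSES:
            raise ValidationError(
                f"family {self.family_id!r}: unknown te_class {self.te_class!r}"
            )
        for aln in self.alignments:
            if aln.family_id != self.family_id:
                raise ValidationError(
                    f"family {self.family_id!r}: member {aln.copy_id!r} "
                    f"belongs to {aln.family_id!r}"
                )

    @property
    def consensus_len(self) -> int:
        return len(self.consensus)

    @property
    def n_copies(self) -> int:
        return len(self.alignments)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    Sequences are uppercased and characters outside {A,C,G,T,N} are mapped
    to N.  Record order is preserved.  A sequence line appearing before any
    header is a format error naming the offending line.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, sanitize_sequence("".join(chunks))))
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
    if header is not None:
        records.append((header, sanitize_sequence("".join(chunks))))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# canonical alignment format


def write_canonical_alignments(
    alignments: Iterable[PairwiseAlignment], path: str | Path
) -> None:
    """Write alignments in the canonical three-line record format."""
    with open(path, "w") as fh:
        for aln in alignments:
            src = aln.source_read_id or "."
            fh.write(
                f"#aln {aln.copy_id} {aln.family_id} {aln.consensus_start} "
                f"{aln.consensus_end} {aln.strand} {src}\n"
            )
            fh.write(aln.gapped_copy + "\n")
            fh.write(aln.gapped_consensus + "\n\n")


def read_canonical_alignments(path: str | Path) -> list[PairwiseAlignment]:
    """Read alignments written by :func:`write_canonical_alignments`."""
    alignments: list[PairwiseAlignment] = []
    with open(path) as fh:
        block: list[str] = []
        lineno_of_block = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.strip():
                if not block:
                    lineno_of_block = lineno
                block.append(line.strip())
            elif block:
                alignments.append(_parse_canonical_block(block, lineno_of_block, path))
                block = []
        if block:
            alignments.append(_parse_canonical_block(block, lineno_of_block, path))
    return alignments


def _parse_canonical_block(
    block: list[str], lineno: int, path: str | Path
) -> PairwiseAlignment:
    if len(block) != 3 or not block[0].startswith("#aln"):
        raise FormatError(
            f"{path}: line {lineno}: expected a 3-line '#aln' record, got {len(block)} lines"
        )
    fields = block[0].split()
    if len(fields) != 7:
        raise FormatError(
            f"{path}: line {lineno}: '#aln' header needs 6 fields, got {len(fields) - 1}"
        )
    _, copy_id, family_id, start, end, strand, source = fields
    return PairwiseAlignment(
        copy_id=copy_id,
        family_id=family_id,
        gapped_copy=sanitize_gapped(block[1]),
        gapped_consensus=sanitize_gapped(block[2]),
        consensus_start=int(start),
        consensus_end=int(end),
        strand=strand,
        source_read_id="" if source == "." else source,
    )


# ---------------------------------------------------------------------------
# RepeatMasker .align (read-only, best-effort)

_RM_SEQ_LINE = re.compile(r"^\s*(C\s+)?(\S+)\s+(\d+)\s+([A-Za-z*-]+)\s+(\d+)\s*$")
_RM_NOISE_PREFIXES = ("Matrix", "Transitions", "Gap_init", "Kimura", "Assumed", "RepeatMasker")


def _is_rm_header(tokens: list[str]) -> bool:
    if len(tokens) < 12:
        return False
    try:
        int(tokens[0])
        float(tokens[1]), float(tokens[2]), float(tokens[3])
        int(tokens[5]), int(tokens[6])
    except ValueError:
        return False
    return True


def read_repeatmasker_align(path: str | Path) -> list[PairwiseAlignment]:
    """Parse a RepeatMasker ``.align`` file into pairwise alignments.

    Complemented ("C") hits are reverse-complemented so the stored consensus
    row runs 5'->3' with ascending coordinates; such records carry strand
    ``-``.  Unparseable blocks are skipped with a logged count; a file that
    yields zero parseable blocks is a format error.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    blocks: list[tuple[list[str], list[str]]] = []
    current: tuple[list[str], list[str]] | None = None
    for line in lines:
        tokens = line.split()
        if tokens and _is_rm_header(tokens):
            current = (tokens, [])
            blocks.append(current)
        elif current is not None:
            current[1].append(line)
    if not blocks:
        raise FormatError(f"{path}: no RepeatMasker alignment blocks found")

    alignments: list[PairwiseAlignment] = []
    skipped = 0
    for header, body in blocks:
        try:
            alignments.append(_parse_rm_block(header, body))
        except (ValueError, IndexError) as exc:
            skipped += 1
            logger.debug("skipping unparseable block (%s): %s", header[:7], exc)
    if skipped:
        logger.warning("%s: skipped %d unparseable alignment block(s)", path, skipped)
    if not alignments:
        raise FormatError(f"{path}: no parseable RepeatMasker alignment blocks")
    return alignments


def _names_match(a: str, b: str) -> bool:
    a = a.split("#")[0]
    b = b.split("#")[0]
    return a == b or a.startswith(b) or b.startswith(a)


def _parse_rm_block(header: list[str], body: list[str]) -> PairwiseAlignment:
    qname = header[4]
    qstart, qend = int(header[5]), int(header[6])
    if header[8] == "C":
        strand = "-"
        cname = header[9]
        # complemented layout: (left) end start
        coords = [t for t in header[10:13] if not t.startswith("(")]
        cend, cstart = int(coords[0]), int(coords[1])
    else:
        strand = "+"
        cname = header[8]
        cstart, cend = int(header[9]), int(header[10])

    qparts: list[str] = []
    cparts: list[str] = []
    expect_query = True
    for line in body:
        stripped = line.strip()
        if not stripped or stripped.startswith(_RM_NOISE_PREFIXES):
            continue
        m = _RM_SEQ_LINE.match(line)
        if not m:
            continue
        comp_prefix, name, _, seq, _ = m.groups()
        if comp_prefix or _names_match(name, cname) and not _names_match(name, qname):
            cparts.append(seq)
            expect_query = True
        elif _names_match(name, qname):
            qparts.append(seq)
            expect_query = False
        elif expect_query:
            qparts.append(seq)
            expect_query = False
        else:
            cparts.append(seq)
            expect_query = True

    gapped_copy = sanitize_gapped("".join(qparts))
    gapped_cons = sanitize_gapped("".join(cparts))
    if not gapped_copy or len(gapped_copy) != len(gapped_cons):
        raise ValueError(
            f"row lengths differ ({len(gapped_copy)} vs {len(gapped_cons)})"
        )
    if strand == "-":
        # RepeatMasker prints the read forward and the consensus complemented
        # with descending coordinates; flip both rows into + orientation.
        gapped_copy = reverse_complement(gapped_copy)
        gapped_cons = reverse_complement(gapped_cons)
    return PairwiseAlignment(
        copy_id=f"{qname}:{qstart}-{qend}",
        family_id=cname.split("#")[0],
        gapped_copy=gapped_copy,
        gapped_consensus=gapped_cons,
        consensus_start=min(cstart, cend),
        consensus_end=max(cstart, cend),
        strand=strand,
        source_read_id=qname,
    )


# ---------------------------------------------------------------------------
# grouping helpers


def build_families(
    alignments: Sequence[PairwiseAlignment],
    consensus_by_id: dict[str, str] | None = None,
    superfamily_by_id: dict[str, str] | None = None,
) -> list[RepeatFamily]:
    """Group alignments by family_id into :class:`RepeatFamily` objects.

    When no consensus sequence is supplied for a family, one is
    reconstructed from the member alignment with the widest consensus span
    (this only covers the aligned region; supply real consensus sequences
    when absolute lengths matter, e.g. consensus-acceptance thresholds).
    """
    consensus_by_id = consensus_by_id or {}
    superfamily_by_id = superfamily_by_id or {}
    grouped: dict[str, list[PairwiseAlignment]] = {}
    for aln in alignments:
        grouped.setdefault(aln.family_id, []).append(aln)
    families = []
    for family_id, members in grouped.items():
        consensus = consensus_by_id.get(family_id)
        if consensus is None:
            widest = max(members, key=lambda a: a.consensus_span)
            consensus = widest.ungapped_consensus()
            logger.info(
                "family %s: no consensus supplied; reconstructed %d bp from %s",
                family_id, len(consensus), widest.copy_id,
            )
        families.append(
            RepeatFamily(
                family_id=family_id,
                consensus=consensus,
                superfamily=superfamily_by_id.get(family_id, "Unknown"),
                alignments=members,
            )
        )
    return families


def read_family_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping family_id -> superfamily label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: need family_id<TAB>superfamily")
            mapping[parts[0]] = parts[1]
    return mapping
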