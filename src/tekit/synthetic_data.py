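"""Master-gene TE family simulator with exact ground truth.

A family consists of copies spawned by an active master lineage.  The
ancestral master sequence plays the role of the estimated consensus.  The
active lineage accrues its own substitutions through time (optionally
biased toward third codon positions); a copy born at a drawn age inherits
every master substitution older than its birth, then decays neutrally:
private substitutions (Poisson in rate x length x age, positions uniform,
derived base uniform over the three alternatives, applied sequentially so
multiple hits behave as Jukes-Cantor assumes) plus small insertions and
deletions with geometric sizes.  Gapped copy-vs-consensus alignments are
emitted exactly, by construction -- no aligner is involved -- and every
event is recorded in a :class:`SimTruth`.

Ages are parameterized directly in expected-divergence units (divergence is
the age proxy throughout); with ``neutral_sub_rate = 1`` an age of 0.05
means 5% expected substitutions per site.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .alignment_io import PairwiseAlignment, RepeatFamily

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# age models


@dataclass(frozen=True)
class BurstAge:
    """Normal burst of copy ages, truncated at zero."""

    mean: float
    sd: float

    @property
    def mean_age(self) -> float:
        return self.mean

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, n), 0.0, None)


@dataclass(frozen=True)
class ExponentialAge:
    """Exponentially distributed copy ages (ongoing proliferation)."""

    mean: float

    @property
    def mean_age(self) -> float:
        return self.mean

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.exponential(self.mean, n)


@dataclass(frozen=True)
class TwoBurstAge:
    """Mixture of two truncated-normal bursts (``mix`` = weight of burst 1)."""

    mean1: float
    mean2: float
    sd: float
    mix: float = 0.5

    @property
    def mean_age(self) -> float:
        return self.mix * self.mean1 + (1.0 - self.mix) * self.mean2

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        pick1 = rng.random(n) < self.mix
        means = np.where(pick1, self.mean1, self.mean2)
        return np.clip(rng.normal(means, self.sd), 0.0, None)


AgeModel = BurstAge | ExponentialAge | TwoBurstAge


# ---------------------------------------------------------------------------
# scenario / truth containers


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated family.

    Rates are per site per unit age; indel sizes are geometric with the
    given success probabilities (mean size 1/p).  ``master_sub_count`` is
    the expected number of substitutions on the active lineage over the
    simulated time span.  ``codon_bias`` > 1 favors third codon positions
    for master-lineage substitutions.
    """

    master_len: int = 2000
    n_copies: int = 100
    age_model: AgeModel = BurstAge(0.05, 0.01)
    neutral_sub_rate: float = 1.0
    master_sub_count: float = 0.0
    del_rate: float = 0.0
    ins_rate: float = 0.0
    del_size_p: float = 0.5
    ins_size_p: float = 0.5
    codon_bias: float = 1.0
    read_len_mean: float = 400.0
    read_len_sd: float = 100.0
    homopolymer_error_rate: float = 0.0
    family_id: str = "fam1"
    superfamily: str = "LTR/Gypsy"
    seed: int = 0

    def validate(self) -> None:
        if self.master_len < 1 or self.n_copies < 1:
            raise ValueError("master_len and n_copies must be >= 1")
        for name in ("neutral_sub_rate", "master_sub_count", "del_rate", "ins_rate",
                     "homopolymer_error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("del_size_p", "ins_size_p"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.codon_bias <= 0:
            raise ValueError("codon_bias must be positive")
        if self.master_sub_count > self.master_len:
            raise ValueError("expected master substitutions exceed available sites")
        if self.neutral_sub_rate * self.age_model.mean_age >= 0.75:
            raise ValueError(
                "expected divergence at or beyond Jukes-Cantor saturation; "
                "lower the age mean or the substitution rate"
            )


@dataclass(frozen=True)
class TrueIndel:
    kind: str  # "insertion" | "deletion"
    consensus_pos: int  # 1-based position of the preceding consensus base
    length_bp: int
    seq: str


@dataclass(frozen=True)
class CopyTruth:
    """Ground truth for one simulated copy."""

    copy_id: str
    age: float
    inherited_keys: frozenset[tuple[int, str]]
    private_events: tuple[tuple[int, str], ...]
    visible_subs: frozenset[tuple[int, str]]
    indels: tuple[TrueIndel, ...]

    @property
    def bp_deleted(self) -> int:
        return sum(i.length_bp for i in self.indels if i.kind == "deletion")

    @property
    def bp_inserted(self) -> int:
        return sum(i.length_bp for i in self.indels if i.kind == "insertion")


@dataclass(frozen=True)
class SimTruth:
    """Per-copy ground truth plus the master-lineage event log."""

    family_id: str
    scenario: SimScenario
    master_events: tuple[tuple[float, int, str], ...]  # (age, pos, derived base)
    copies: dict[str, CopyTruth]

    @property
    def mean_true_divergence(self) -> float:
        """Expected neutral substitutions/site, averaged over realized ages."""
        ages = [c.age for c in self.copies.values()]
        return self.scenario.neutral_sub_rate * float(np.mean(ages))

    def true_divergence(self, copy_id: str) -> float:
        return self.scenario.neutral_sub_rate * self.copies[copy_id].age

    @property
    def true_loss_rate(self) -> float:
        """Model (bp deleted - bp inserted) per substitution."""
        s = self.scenario
        del_bp = s.del_rate / s.del_size_p
        ins_bp = s.ins_rate / s.ins_size_p
        return (del_bp - ins_bp) / s.neutral_sub_rate


# ---------------------------------------------------------------------------
# simulation


def _random_other_base(rng: np.random.Generator, current: int) -> int:
    return (current + 1 + int(rng.integers(3))) % 4


def _master_position_weights(scenario: SimScenario) -> np.ndarray | None:
    if scenario.codon_bias == 1.0:
        return None
    w = np.ones(scenario.master_len)
    w[2::3] = scenario.codon_bias  # third positions in frame 0
    return w / w.sum()


def simulate_family(scenario: SimScenario) -> tuple[RepeatFamily, SimTruth]:
    """Simulate one family; fully reproducible from ``scenario.seed``."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    L = scenario.master_len
    master = rng.integers(0, 4, L)

    ages = scenario.age_model.draw(rng, scenario.n_copies)
    span = float(ages.max()) if float(ages.max()) > 0 else 1.0

    # master-lineage substitutions, oldest first, applied along the lineage
    n_master = int(rng.poisson(scenario.master_sub_count))
    event_ages = np.sort(rng.uniform(0.0, span, n_master))[::-1]
    weights = _master_position_weights(scenario)
    lineage = master.copy()
    master_events: list[tuple[float, int, str]] = []
    for e_age in event_ages:
        if weights is None:
            pos = int(rng.integers(L))
        else:
            pos = int(rng.choice(L, p=weights))
        new = _random_other_base(rng, int(lineage[pos]))
        lineage[pos] = new
        master_events.append((float(e_age), pos + 1, str(_BASES[new])))

    alignments: list[PairwiseAlignment] = []
    copies: dict[str, CopyTruth] = {}
    for i, age in enumerate(map(float, ages)):
        copy_id = f"{scenario.family_id}.c{i:04d}"
        seq = master.copy()
        for e_age, pos1, base in master_events:
            if e_age > age:
                seq[pos1 - 1] = np.flatnonzero(_BASES == base)[0]
        inherited = frozenset(
            (int(p) + 1, str(_BASES[seq[p]]))
            for p in np.flatnonzero(seq != master)
        )

        n_private = int(rng.poisson(scenario.neutral_sub_rate * L * age))
        private_events = []
        for _ in range(n_private):
            pos = int(rng.integers(L))
            new = _random_other_base(rng, int(seq[pos]))
            seq[pos] = new
            private_events.append((pos + 1, str(_BASES[new])))

        deleted = np.zeros(L, dtype=bool)
        indels: list[TrueIndel] = []
        n_del = int(rng.poisson(scenario.del_rate * L * age))
        for _ in range(n_del):
            size = int(rng.geometric(scenario.del_size_p))
            if size > L:
                continue
            start = int(rng.integers(0, L - size + 1))
            if deleted[start : start + size].any():
                continue  # overlapping deletions are redrawn as no-ops
            deleted[start : start + size] = True
            indels.append(
                TrueIndel(
                    kind="deletion",
                    consensus_pos=start,
                    length_bp=size,
                    seq="".join(_BASES[master[start : start + size]]),
                )
            )

        ins_by_anchor: dict[int, str] = defaultdict(str)
        n_ins = int(rng.poisson(scenario.ins_rate * L * age))
        for _ in range(n_ins):
            size = int(rng.geometric(scenario.ins_size_p))
            anchor = int(rng.integers(1, L + 1))
            ins_seq = "".join(_BASES[rng.integers(0, 4, size)])
            ins_by_anchor[anchor] += ins_seq
            indels.append(
                TrueIndel(kind="insertion", consensus_pos=anchor,
                          length_bp=size, seq=ins_seq)
            )

        if scenario.homopolymer_error_rate > 0:
            _inject_homopolymer_errors(rng, master, ins_by_anchor, deleted, scenario)

        if deleted.all():
            continue  # degenerate: nothing left of the copy

        copy_chars = np.where(deleted, "-", _BASES[seq])
        cons_chars = _BASES[master]
        if ins_by_anchor:
            cp, kp = [], []
            prev = 0
            for anchor in sorted(ins_by_anchor):
                cp.append("".join(copy_chars[prev:anchor]))
                kp.append("".join(cons_chars[prev:anchor]))
                ins_seq = ins_by_anchor[anchor]
                cp.append(ins_seq)
                kp.append("-" * len(ins_seq))
                prev = anchor
            cp.append("".join(copy_chars[prev:]))
            kp.append("".join(cons_chars[prev:]))
            gapped_copy, gapped_cons = "".join(cp), "".join(kp)
        else:
            gapped_copy, gapped_cons = "".join(copy_chars), "".join(cons_chars)

        visible = frozenset(
            (int(p) + 1, str(_BASES[seq[p]]))
            for p in np.flatnonzero((seq != master) & ~deleted)
        )
        alignments.append(
            PairwiseAlignment(
                copy_id=copy_id,
                family_id=scenario.family_id,
                gapped_copy=gapped_copy,
                gapped_consensus=gapped_cons,
                consensus_start=1,
                consensus_end=L,
                strand="+",
                source_read_id=copy_id,
            )
        )
        copies[copy_id] = CopyTruth(
            copy_id=copy_id,
            age=age,
            inherited_keys=inherited,
            private_events=tuple(private_events),
            visible_subs=visible,
            indels=tuple(indels),
        )

    family = RepeatFamily(
        family_id=scenario.family_id,
        consensus="".join(_BASES[master]),
        superfamily=scenario.superfamily,
        alignments=alignments,
    )
    truth = SimTruth(
        family_id=scenario.family_id,
        scenario=scenario,
        master_events=tuple(master_events),
        copies=copies,
    )
    return family, truth


def _inject_homopolymer_errors(
    rng: np.random.Generator,
    master: np.ndarray,
    ins_by_anchor: dict[int, str],
    deleted: np.ndarray,
    scenario: SimScenario,
) -> None:
    """Add spurious 1-bp insertions inside consensus homopolymer runs >= 5.

    Emulates pyrosequencing length miscalls; these are errors, not true
    indels, so they are *not* recorded in the truth ledger.
    """
    L = len(master)
    i = 0
    while i < L:
        j = i
        while j < L and master[j] == master[i]:
            j += 1
        if j - i >= 5 and rng.random() < scenario.homopolymer_error_rate:
            anchor = int(rng.integers(i + 1, j + 1))  # inside the run, 1-based
            ins_by_anchor[anchor] += str(_BASES[master[i]])
        i = j


# ---------------------------------------------------------------------------
# read shredding


def shred_to_reads(
    family: RepeatFamily, scenario: SimScenario
) -> tuple[list[tuple[str, str]], list[PairwiseAlignment]]:
    """Cut each copy into read-length fragments with consistent sub-alignments.

    Fragment lengths are drawn from normal(read_len_mean, read_len_sd)
    truncated at 50 bp; a short tail is merged into the final fragment so
    the concatenated ungapped fragments reproduce each copy exactly.
    Returns ``(reads, fragment_alignments)``.
    """
    rng = np.random.default_rng(scenario.seed + 7919)
    reads: list[tuple[str, str]] = []
    fragments: list[PairwiseAlignment] = []
    for aln in family.alignments:
        n_bp = aln.copy_len_bp
        if n_bp == 0:
            continue
        pieces: list[int] = []
        remaining = n_bp
        while remaining > 0:
            ln = max(50, int(round(rng.normal(scenario.read_len_mean, scenario.read_len_sd))))
            ln = min(ln, remaining)
            if remaining - ln < 50:
                ln = remaining
            pieces.append(ln)
            remaining -= ln

        # column index at which each piece ends (just after its last copy base)
        cuts = []
        target = 0
        seen = 0
        piece_iter = iter(pieces)
        want = next(piece_iter)
        for col, ch in enumerate(aln.gapped_copy):
            if ch != "-":
                seen += 1
                if seen == want + target:
                    cuts.append(col + 1)
                    target += want
                    want = next(piece_iter, None)
                    if want is None:
                        break
        cuts[-1] = len(aln.gapped_copy)  # absorb trailing gap columns

        start_col = 0
        cons_pos = aln.consensus_start - 1  # last consensus coord before fragment
        for k, end_col in enumerate(cuts):
            sub_copy = aln.gapped_copy[start_col:end_col]
            sub_cons = aln.gapped_consensus[start_col:end_col]
            n_cons = len(sub_cons) - sub_cons.count("-")
            read_id = f"{aln.copy_id}.r{k}"
            if n_cons > 0:
                fragments.append(
                    PairwiseAlignment(
                        copy_id=read_id,
                        family_id=aln.family_id,
                        gapped_copy=sub_copy,
                        gapped_consensus=sub_cons,
                        consensus_start=cons_pos + 1,
                        consensus_end=cons_pos + n_cons,
                        strand=aln.strand,
                        source_read_id=read_id,
                    )
                )
            reads.append((read_id, sub_copy.replace("-", "")))
            cons_pos += n_cons
            start_col = end_col
    return reads, fragments


# ---------------------------------------------------------------------------
# presets


def preset_scenarios(seed: int = 0) -> dict[str, SimScenario]:
    """Named scenarios contrasting proliferation histories.

    * ``ongoing``  -- age peak near the present (mode below 1% divergence);
    * ``old_burst`` -- a past proliferation peak well above 1% divergence;
    * ``two_burst`` -- bimodal control resembling two transfer/activity waves.
    """
    common = dict(master_len=2000, n_copies=500, neutral_sub_rate=1.0, seed=seed)
    return {
        "ongoing": SimScenario(
            age_model=ExponentialAge(0.004), family_id="ongoing", **common
        ),
        "old_burst": SimScenario(
            age_model=BurstAge(0.05, 0.012), family_id="old_burst", **common
        ),
        "two_burst": SimScenario(
            age_model=TwoBurstAge(0.015, 0.08, 0.006, 0.5),
            family_id="two_burst", **common
        ),
    }


# ---------------------------------------------------------------------------
# truth serialization (plain text, for the CLI)


def truth_to_rows(truth: SimTruth) -> list[dict[str, object]]:
    rows = []
    for copy in truth.copies.values():
        rows.append(
            {
                "copy_id": copy.copy_id,
                "true_age": copy.age,
                "n_inherited": len(copy.inherited_keys),
                "n_private": len(copy.private_events),
                "n_visible_subs": len(copy.visible_subs),
                "n_deletions": sum(1 for i in copy.indels if i.kind == "deletion"),
                "n_insertions": sum(1 for i in copy.indels if i.kind == "insertion"),
                "bp_deleted": copy.bp_deleted,
                "bp_inserted": copy.bp_inserted,
            }
        )
    return rows
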