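import math

import numpy as np
import pytest

from tekit import synthetic_data as sd
from tekit.alignment_io import RepeatFamily
from tekit.dna_loss import (
    IndelEvent,
    LossRateResult,
    accept_consensus,
    chi_square_uniform,
    codon_substitution_counts,
    count_indels,
    flag_homopolymer_indels,
    longest_orf_frame,
    loss_rate,
    screen_families,
)
from .conftest import family_from_rows, make_aln


def _copy_row(consensus, n_subs):
    """Copy differing from consensus at the first n_subs positions."""
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    row = list(consensus)
    for i in range(n_subs):
        row[i] = swap[row[i]]
    return "".join(row)


class TestAcceptConsensus:
    def _family(self, consensus_len, copy_len, n_copies, identity=0.85):
        consensus = ("ACGT" * ((consensus_len + 3) // 4))[:consensus_len]
        copy_cons = consensus[:copy_len]
        n_subs = int(round((1 - identity) * copy_len))
        rows = [_copy_row(copy_cons, n_subs)] * n_copies
        alns = [
            make_aln(row, copy_cons, copy_id=f"f1.c{i}", family_id="f1")
            for i, row in enumerate(rows)
        ]
        return RepeatFamily(family_id="f1", consensus=consensus,
                            superfamily="LINE/L1", alignments=alns)

    def test_thresholds_satisfied(self):
        acc = accept_consensus(self._family(400, 350, 6, identity=0.85))
        assert acc.accepted and acc.n_qualifying_copies == 6

    def test_consensus_length_boundary_is_strict(self):
        assert not accept_consensus(self._family(330, 350, 6)).accepted
        assert accept_consensus(self._family(331, 350, 6)).accepted

    def test_too_few_qualifying_copies(self):
        assert not accept_consensus(self._family(400, 350, 4)).accepted

    def test_copy_length_boundary_is_strict(self):
        assert not accept_consensus(self._family(400, 300, 6)).accepted
        assert accept_consensus(self._family(400, 301, 6)).accepted

    def test_copy_identity_boundary_is_inclusive(self):
        assert accept_consensus(self._family(400, 400, 5, identity=0.80)).accepted
        assert not accept_consensus(self._family(400, 400, 5, identity=0.78)).accepted


class TestCodonCounts:
    def _family_with_sub_positions(self, positions, length=12):
        consensus = "A" * length
        rows = []
        for pos in positions:
            row = list(consensus)
            row[pos - 1] = "C"
            rows.append("".join(row))
        return family_from_rows(consensus, rows, superfamily="LINE/L1")

    def test_positions_one_two_three(self):
        family = self._family_with_sub_positions([1, 2, 3])
        assert codon_substitution_counts(family, 0) == (1, 1, 1)

    def test_third_positions(self):
        family = self._family_with_sub_positions([3, 6, 9])
        assert codon_substitution_counts(family, 0) == (0, 0, 3)

    def test_no_substitutions(self):
        family = self._family_with_sub_positions([])
        assert codon_substitution_counts(family, 0) == (0, 0, 0)

    def test_offset_shifts_frame_and_drops_upstream(self):
        family = self._family_with_sub_positions([1, 2, 3])
        # position 1 is upstream of the frame; 2 -> codon pos 1, 3 -> codon pos 2
        assert codon_substitution_counts(family, 1) == (1, 1, 0)

    def test_bad_offset(self):
        with pytest.raises(ValueError):
            codon_substitution_counts(self._family_with_sub_positions([]), 3)


class TestChiSquareUniform:
    def test_uniform_counts_retained(self):
        res = chi_square_uniform((10, 10, 10))
        assert res.chi2_stat == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert not res.excluded

    def test_heavy_bias_excluded(self):
        res = chi_square_uniform((5, 5, 50))
        assert res.chi2_stat == pytest.approx(67.5)
        assert res.excluded

    def test_tiny_sample_retained(self):
        res = chi_square_uniform((0, 0, 1))
        assert res.chi2_stat == pytest.approx(2.0)
        assert res.p_value == pytest.approx(math.exp(-1.0), rel=1e-6)
        assert not res.excluded

    def test_zero_counts_not_applicable(self):
        res = chi_square_uniform((0, 0, 0))
        assert not res.tested and not res.excluded


class TestLongestOrfFrame:
    def test_picks_stop_free_frame(self):
        # frame 0 is wall-to-wall stops; frames 1/2 are open (tie -> lowest)
        consensus = "TAATAATAATAA"
        assert longest_orf_frame(consensus) == 1

    def test_all_frames_open_prefers_lowest(self):
        assert longest_orf_frame("ACGACGACGACG") == 0


class TestCountIndels:
    def test_single_deletion(self):
        (ev,) = count_indels(make_aln("ACG--CGT", "ACGTACGT"))
        assert ev.kind == "deletion"
        assert ev.length_bp == 2
        assert ev.seq == "TA"
        assert ev.consensus_pos == 3

    def test_single_insertion(self):
        (ev,) = count_indels(make_aln("ACGTAACGT", "ACGT-ACGT"))
        assert ev.kind == "insertion"
        assert ev.length_bp == 1
        assert ev.seq == "A"
        assert ev.consensus_pos == 4

    def test_cap_discards_long_runs(self):
        cons = "ACGT" * 10
        copy = "A" + "-" * 31 + cons[32:]
        events = count_indels(make_aln(copy, cons))
        assert events == []
        # a 30 bp run is exactly at the cap and kept
        copy30 = "AC" + "-" * 30 + cons[32:]
        (ev,) = count_indels(make_aln(copy30, cons))
        assert ev.length_bp == 30

    def test_maximal_runs_not_split(self):
        events = count_indels(make_aln("A---T", "ACGCT"))
        assert len(events) == 1 and events[0].length_bp == 3

    def test_leading_gap_has_position_zero(self):
        (ev,) = count_indels(make_aln("--GT", "ACGT"))
        assert ev.consensus_pos == 0 and ev.kind == "deletion"


class TestIndelInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_row_swap_symmetry(self, seed):
        scenario = sd.SimScenario(
            master_len=600, n_copies=5, age_model=sd.BurstAge(0.05, 0.01),
            del_rate=0.02, ins_rate=0.02, seed=seed,
        )
        family, _ = sd.simulate_family(scenario)
        for aln in family.alignments:
            swapped = make_aln(
                aln.gapped_consensus, aln.gapped_copy, copy_id=aln.copy_id
            )
            fwd = count_indels(aln, cap=10**9)
            rev = count_indels(swapped, cap=10**9)
            fwd_tally = (
                sorted(e.length_bp for e in fwd if e.kind == "deletion"),
                sorted(e.length_bp for e in fwd if e.kind == "insertion"),
            )
            rev_tally = (
                sorted(e.length_bp for e in rev if e.kind == "insertion"),
                sorted(e.length_bp for e in rev if e.kind == "deletion"),
            )
            assert fwd_tally == rev_tally

    @pytest.mark.parametrize("seed", range(5))
    def test_deletion_bp_conservation(self, seed):
        scenario = sd.SimScenario(
            master_len=600, n_copies=5, age_model=sd.BurstAge(0.05, 0.01),
            del_rate=0.02, ins_rate=0.01, seed=seed,
        )
        family, _ = sd.simulate_family(scenario)
        for aln in family.alignments:
            events = count_indels(aln, cap=10**9)
            del_bp = sum(e.length_bp for e in events if e.kind == "deletion")
            assert del_bp == aln.gapped_copy.count("-")


class TestHomopolymerFlag:
    def test_insertion_extending_long_run_flagged(self):
        # consensus run AAAA; inserted A makes 5
        aln = make_aln("GAAAAACT", "GAAAA-CT")
        (ev,) = count_indels(aln)
        (flagged,) = flag_homopolymer_indels(aln, [ev])
        assert flagged.in_homopolymer

    def test_multibase_indel_never_flagged(self):
        aln = make_aln("G--AAAT", "GACAAAT")  # deletes "AC", not mononucleotide
        events = count_indels(aln)
        flagged = flag_homopolymer_indels(aln, events)
        assert not any(e.in_homopolymer for e in flagged)

    def test_short_run_not_flagged(self):
        aln = make_aln("GAAACT", "GAA-CT")
        (ev,) = count_indels(aln)
        (flagged,) = flag_homopolymer_indels(aln, [ev])
        assert not flagged.in_homopolymer

    def test_deletion_inside_run_counts_own_footprint(self):
        # deleting 2 of 5 As: run = 2 deleted + 3 flanking = 5 -> flagged
        aln = make_aln("G--AAACT", "GAAAAACT")
        (ev,) = count_indels(aln)
        (flagged,) = flag_homopolymer_indels(aln, [ev])
        assert flagged.in_homopolymer

    def test_injector_produces_flaggable_events(self):
        scenario = sd.SimScenario(
            master_len=2000, n_copies=10, age_model=sd.BurstAge(0.01, 0.002),
            homopolymer_error_rate=1.0, seed=4,
        )
        family, truth = sd.simulate_family(scenario)
        n_flagged = 0
        for aln in family.alignments:
            events = flag_homopolymer_indels(aln, count_indels(aln))
            n_flagged += sum(e.in_homopolymer for e in events)
            # injected errors are not part of the truth record
            assert not truth.copies[aln.copy_id].indels
        assert n_flagged > 0


class TestLossRateResult:
    def test_arithmetic(self):
        res = LossRateResult.from_tallies(
            n_insertions=10, n_deletions=20, bp_inserted=40, bp_deleted=120,
            n_substitutions_jc=1000.0, n_copies=5,
        )
        assert res.loss_rate == pytest.approx(0.08)
        assert res.mean_del_size == pytest.approx(6.0)
        assert res.mean_ins_size == pytest.approx(4.0)
        assert res.del_ins_ratio == pytest.approx(2.0)

    def test_reported_event_counts_reproduce_ratio(self):
        res = LossRateResult.from_tallies(
            n_insertions=39258, n_deletions=29755, bp_inserted=0, bp_deleted=0,
            n_substitutions_jc=0.0, n_copies=0,
        )
        assert round(res.del_ins_ratio, 2) == 0.76

    def test_no_indels_gives_zero_rate(self):
        res = LossRateResult.from_tallies(
            n_insertions=0, n_deletions=0, bp_inserted=0, bp_deleted=0,
            n_substitutions_jc=500.0, n_copies=3,
        )
        assert res.loss_rate == 0.0
        assert math.isnan(res.del_ins_ratio)

    def test_zero_substitutions_is_missing(self):
        res = LossRateResult.from_tallies(
            n_insertions=1, n_deletions=1, bp_inserted=2, bp_deleted=5,
            n_substitutions_jc=0.0, n_copies=1,
        )
        assert math.isnan(res.loss_rate)


class TestScreening:
    def _big_family(self, biased, family_id, seed=0):
        if biased:
            scenario = sd.SimScenario(
                master_len=600, n_copies=8, age_model=sd.ExponentialAge(0.02),
                neutral_sub_rate=0.0, master_sub_count=80.0, codon_bias=12.0,
                family_id=family_id, superfamily="LINE/L1", seed=seed,
            )
        else:
            scenario = sd.SimScenario(
                master_len=600, n_copies=8, age_model=sd.BurstAge(0.05, 0.01),
                family_id=family_id, superfamily="LINE/L1", seed=seed,
            )
        family, _ = sd.simulate_family(scenario)
        return family

    def test_biased_family_screened_out(self):
        neutral = self._big_family(False, "neutral", seed=1)
        biased = self._big_family(True, "biased", seed=2)
        retained, acceptances, tests = screen_families([neutral, biased])
        assert all(a.accepted for a in acceptances)
        retained_ids = {f.family_id for f in retained}
        assert "neutral" in retained_ids
        assert "biased" not in retained_ids

    def test_loss_rate_runs_end_to_end(self):
        family = self._big_family(False, "neutral", seed=3)
        res = loss_rate([family])
        assert res.n_copies == family.n_copies
        assert res.n_substitutions_jc > 0
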