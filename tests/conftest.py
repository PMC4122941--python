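import pytest

from tekit.alignment_io import PairwiseAlignment, RepeatFamily


def make_aln(copy_row, cons_row, copy_id="c1", family_id="f1", start=1, **kw):
    """Build a PairwiseAlignment, deriving consensus_end from the rows."""
    end = start + len(cons_row) - cons_row.count("-") - 1
    return PairwiseAlignment(
        copy_id=copy_id,
        family_id=family_id,
        gapped_copy=copy_row,
        gapped_consensus=cons_row,
        consensus_start=start,
        consensus_end=end,
        **kw,
    )


def family_from_rows(consensus, copy_rows, family_id="f1", superfamily="LTR/Gypsy"):
    """Family whose copies align gaplessly against the full consensus."""
    alignments = [
        make_aln(row, consensus, copy_id=f"{family_id}.c{i}", family_id=family_id)
        for i, row in enumerate(copy_rows)
    ]
    return RepeatFamily(
        family_id=family_id,
        consensus=consensus,
        superfamily=superfamily,
        alignments=alignments,
    )


@pytest.fixture
def aln_factory():
    return make_aln


@pytest.fixture
def family_factory():
    return family_from_rows
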