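"""Window alignment, coverage classes, 3' indel normalization, calling."""

import pytest
from Bio.Seq import reverse_complement

from hv1hap.alignment import (
    AlignmentParams,
    Coverage,
    CoverageError,
    InputError,
    Strand,
    align_to_window,
    call_profile,
    classify_coverage,
    normalize_indels,
    profile_query,
)
from hv1hap.mutation_model import ReferenceWindow, format_profile, parse_profile


def _call(query, ref, **kwargs):
    params = kwargs.pop("params", None)
    aln = normalize_indels(align_to_window(query, ref, params), ref, params)
    return call_profile(aln, ref, **kwargs)


def test_self_alignment_is_reference_haplotype(synthetic_ref):
    qp = profile_query(synthetic_ref.sequence, synthetic_ref)
    assert qp.coverage is Coverage.FULL
    assert qp.strand is Strand.FORWARD
    assert qp.profile is not None and len(qp.profile) == 0


def test_single_substitution_called(synthetic_ref):
    seq = list(synthetic_ref.sequence)
    pos = synthetic_ref.start + 100
    original = seq[100]
    seq[100] = {"A": "C", "C": "A", "G": "T", "T": "G"}[original]
    qp = profile_query("".join(seq), synthetic_ref)
    assert qp.coverage is Coverage.FULL
    assert format_profile(qp.profile) == f"{original}{pos}{seq[100]}"


def test_reverse_strand_detected(synthetic_ref):
    qp = profile_query(reverse_complement(synthetic_ref.sequence), synthetic_ref)
    assert qp.strand is Strand.REVERSE_COMPLEMENTED
    assert qp.coverage is Coverage.FULL
    assert len(qp.profile) == 0


def test_flanked_query_is_full_coverage(synthetic_ref):
    query = "AGTC" * 10 + synthetic_ref.sequence + "TTGACA" * 8
    aln = align_to_window(query, synthetic_ref)
    assert classify_coverage(aln, synthetic_ref) is Coverage.FULL


def test_fragment_is_partial_and_refused(synthetic_ref):
    fragment = synthetic_ref.sequence[: 400]
    aln = align_to_window(fragment, synthetic_ref)
    assert classify_coverage(aln, synthetic_ref) is Coverage.PARTIAL
    with pytest.raises(CoverageError):
        call_profile(aln, synthetic_ref)
    assert profile_query(fragment, synthetic_ref).profile is None


def test_unrelated_sequence_is_coverage_none(synthetic_ref):
    import random

    rng = random.Random(99)
    junk = "".join(rng.choice("ACGT") for _ in range(300))
    aln = align_to_window(junk, synthetic_ref)
    assert classify_coverage(aln, synthetic_ref) is Coverage.NONE


def test_rejects_non_nucleotide_query(synthetic_ref):
    with pytest.raises(InputError):
        align_to_window("ACGT!!", synthetic_ref)
    with pytest.raises(InputError):
        align_to_window("", synthetic_ref)


# 35 bp toy window with a C-run at coordinates 11..15; events sit mid-window
# so they cannot be absorbed into the free end gaps
_TOY = ReferenceWindow(sequence="ACGTAGTCATCCCCCGTTAGCATCGGATCGATGCA", start=1, end=35)


def test_deletion_shifts_to_3prime_end_of_homopolymer():
    # query misses one C of the run: every placement inside the run is
    # score-equivalent, the call must land on the run's last coordinate
    query = _TOY.sequence[:10] + _TOY.sequence[11:]  # drop the run's first C
    assert format_profile(_call(query, _TOY)) == "C15-"


def test_insertion_anchors_after_homopolymer_run():
    query = _TOY.sequence[:11] + "C" + _TOY.sequence[11:]  # extra C inside the run
    assert format_profile(_call(query, _TOY)) == "-15.1C"


def test_heteropolymeric_insertion_preserved():
    from hv1hap.mutation_model import apply_profile

    profile = parse_profile("-22.1C -22.2T -22.3C")
    assert format_profile(_call(apply_profile(_TOY, profile), _TOY)) == str(profile)


def test_normalize_is_idempotent_and_sequence_preserving(synthetic_ref):
    from hv1hap.mutation_model import apply_profile

    query = apply_profile(synthetic_ref, parse_profile("T15465-".replace("T", synthetic_ref.base_at(15465))))
    aln = align_to_window(query, synthetic_ref)
    once = normalize_indels(aln, synthetic_ref)
    twice = normalize_indels(once, synthetic_ref)
    assert once.columns == twice.columns
    assert once.query_text.replace("-", "") == aln.query_text.replace("-", "")
    assert once.score == aln.score


def test_ambiguity_codes_excluded_from_profile(synthetic_ref):
    seq = list(synthetic_ref.sequence)
    seq[50] = "N"
    qp = profile_query("".join(seq), synthetic_ref)
    assert qp.coverage is Coverage.FULL
    assert len(qp.profile) == 0
    assert qp.n_ambiguous == 1
    with pytest.raises(Exception):
        profile_query("".join(seq), synthetic_ref, n_policy="strict")


def test_alignment_params_validation():
    with pytest.raises(ValueError):
        AlignmentParams(gap_open=1, gap_extend=2)
    with pytest.raises(ValueError):
        AlignmentParams(min_identity=1.5)


def test_labels_stay_inside_window(synthetic_ref):
    from hv1hap.mutation_model import apply_profile

    profile = parse_profile("")
    query = "ACCA" * 5 + apply_profile(synthetic_ref, profile) + "GGTA" * 5
    aln = normalize_indels(align_to_window(query, synthetic_ref), synthetic_ref)
    for col in aln.columns:
        if isinstance(col.label, int):
            assert synthetic_ref.start <= col.label <= synthetic_ref.end
        elif col.label is not None:
            anchor, sub_index = col.label
            assert synthetic_ref.start <= anchor <= synthetic_ref.end
            assert sub_index >= 1
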