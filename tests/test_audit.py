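"""Audit categories, summaries and the polymorphic-site table."""

import itertools

import pytest

from hv1hap.alignment import Coverage
from hv1hap.audit import (
    CATEGORIES,
    AuditVerdict,
    audit_record,
    polymorphic_sites,
    substitution_class,
    summarize,
)
from hv1hap.ingest import SequenceRecord
from hv1hap.mutation_model import parse_profile
from hv1hap.registry import (
    HaplotypeDefinition,
    MatchResult,
    Registry,
    deduplicate,
    load_registry,
    match_profile,
)


def _rec(claim, coverage=Coverage.FULL):
    rec = SequenceRecord("X1.1", "d", "Canis lupus", "ACGT", annotated_haplotype=claim)
    rec.coverage = coverage
    return rec


def _assigned(name):
    return MatchResult(status="assigned", haplotype_name=name, nearest_name=name, nearest_distance=0)


@pytest.fixture()
def published_registry():
    return deduplicate(load_registry())


def test_correct_claim(published_registry):
    v = audit_record(_rec("A1"), _assigned("A1"), published_registry)
    assert v.category == "correct" and v.recognized_name == "A1"


def test_duplicate_name_resolves_via_alias(published_registry):
    # annotated with the eliminated name A228; the profile matches A140
    v = audit_record(_rec("A228"), _assigned("A140"), published_registry)
    assert v.category == "duplicate_name"
    assert v.claim == "A228" and v.recognized_name == "A140"


def test_wrong_identification_for_assigned_haplotype(published_registry, motifs):
    profile = parse_profile("A15553G T15639A C15814T A15931-")
    match = match_profile(published_registry, profile, motifs=motifs)
    v = audit_record(_rec("A171"), match, published_registry)
    assert v.category == "wrong_id_assigned"
    assert v.recognized_name == "A246"


def test_wrong_identification_for_new_haplotype(published_registry, motifs):
    profile = parse_profile("A15653G C15814T C15955T")
    match = match_profile(published_registry, profile, motifs=motifs)
    assert match.status == "new_candidate"
    v = audit_record(_rec("A17"), match, published_registry)
    assert v.category == "wrong_id_new"


def test_other_system_and_absent_and_partial(published_registry):
    assert audit_record(_rec("Be36_2"), _assigned("A1"), published_registry).category == "other_system"
    assert audit_record(_rec(None), _assigned("A1"), published_registry).category == "absent"
    assert audit_record(_rec("A1", Coverage.PARTIAL), None, published_registry).category == "partial_excluded"


def test_every_record_gets_exactly_one_category(published_registry):
    claims = ["A1", "A228", "Be36_2", None]
    verdicts = [audit_record(_rec(c), _assigned("A1"), published_registry) for c in claims]
    verdicts.append(audit_record(_rec("A1", Coverage.NONE), None, published_registry))
    counts = summarize(verdicts)
    assert sum(counts[c] for c in CATEGORIES) == counts["entries"] == len(verdicts)


def test_summarize_empty_is_all_zero():
    counts = summarize([])
    assert counts["entries"] == 0
    assert all(counts[c] == 0 for c in CATEGORIES)


def test_summarize_distinct_sequences():
    verdicts = [AuditVerdict(f"X{i}.1", "absent") for i in range(3)]
    matches = [_assigned("A1")] * 3  # three identical sequences, one haplotype
    counts = summarize(verdicts, matches=matches)
    assert counts["distinct_sequences"] == 1
    assert counts["assigned_matches"] == 3


def test_transition_transversion_exhaustive():
    purines = set("AG")
    for a, b in itertools.permutations("ACGT", 2):
        expected = "transition" if (a in purines) == (b in purines) else "transversion"
        assert substitution_class(a, b) == expected


def test_polymorphic_sites_published_registry(published_registry):
    table = polymorphic_sites(published_registry, window_start=15458)
    by_pos = {s.position: s for s in table.sites}
    # T15639A appears in several definitions: a transversion at 15639
    site = by_pos[15639]
    assert site.ref_base == "T" and "A" in site.substitutions
    assert site.classes == {"transversion"}
    # A15931- is a deletion shared by A140 and A246
    assert set(by_pos[15931].deletion_haplotypes) == {"A140", "A246"}
    # every profile event lands in exactly one row
    n_positions = len({e.position for d in published_registry.definitions for e in d.profile})
    assert table.summary["total_sites"] == len(table.sites) == n_positions
    assert (
        table.summary["sites_in_first_k"] + table.summary["sites_after_first_k"]
        == table.summary["total_sites"]
    )


def test_polymorphic_sites_mixed_substitution_and_deletion():
    reg = Registry(
        definitions=[
            HaplotypeDefinition("A1", parse_profile("C15526T"), priority=1),
            HaplotypeDefinition("A2", parse_profile("C15526-"), priority=2),
            HaplotypeDefinition("A3", parse_profile("-15526.1G"), priority=3),
        ]
    )
    table = polymorphic_sites(reg)
    (site,) = table.sites
    assert site.has_substitution and site.has_deletion and site.has_insertion
    df = table.to_dataframe()
    assert list(df["position"]) == [15526]


def test_polymorphic_sites_empty_profile_registry():
    reg = Registry(definitions=[HaplotypeDefinition("A1", parse_profile(""), priority=1)])
    table = polymorphic_sites(reg)
    assert table.sites == [] and table.summary["total_sites"] == 0
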