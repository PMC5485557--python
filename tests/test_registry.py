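"""Registry loading, reconciliation, matching and candidate naming."""

import pytest

from hv1hap.mutation_model import parse_profile
from hv1hap.registry import (
    HaplotypeDefinition,
    PriorityTieError,
    Registry,
    RegistryError,
    assign_candidate_name,
    deduplicate,
    load_registry,
    match_profile,
    missing_indices,
    parse_haplotype_name,
    save_registry,
)


@pytest.mark.parametrize(
    "name,expected",
    [
        ("A246", ("A", False, 246)),
        ("Bn15", ("B", True, 15)),
        ("F1", ("F", False, 1)),
    ],
)
def test_parse_haplotype_name(name, expected):
    assert parse_haplotype_name(name) == expected


@pytest.mark.parametrize("bad", ["G1", "A", "n1", "a246", "An", "A-1"])
def test_parse_haplotype_name_rejects(bad):
    with pytest.raises(RegistryError):
        parse_haplotype_name(bad)


def test_packaged_registry_contents():
    reg = load_registry()
    names = {d.name for d in reg.definitions}
    assert names == {"A1", "A17", "A140", "A171", "A228", "A246"}
    a171 = reg.by_name("A171")
    assert len(a171.profile) == 4
    assert str(a171.profile) == "T15639A C15814T G15848A T16025C"


def test_empty_registry_file(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("name\tprofile\tstandard_accession\tpriority\n", encoding="utf-8")
    assert load_registry(p).definitions == []


def test_deduplicate_keeps_earliest_and_aliases_rest():
    reg = deduplicate(load_registry())
    assert "A228" not in reg.names()
    assert reg.aliases == {"A228": "A140"}
    assert reg.resolve("A228") == "A140"
    # idempotent
    again = deduplicate(reg)
    assert again.names() == reg.names() and again.aliases == reg.aliases


def test_deduplicate_three_way_duplicate():
    profile = parse_profile("A15553G")
    defs = [
        HaplotypeDefinition("A3", profile, priority=3),
        HaplotypeDefinition("A5", profile, priority=5),
        HaplotypeDefinition("A2", profile, priority=2),
    ]
    out = deduplicate(Registry(definitions=defs))
    assert out.names() == {"A2"}
    assert out.aliases == {"A3": "A2", "A5": "A2"}


def test_deduplicate_distinct_profiles_unchanged(published_registry):
    assert deduplicate(published_registry).names() == published_registry.names()


def test_deduplicate_priority_tie_is_an_error():
    profile = parse_profile("A15553G")
    reg = Registry(
        definitions=[
            HaplotypeDefinition("A1", profile, priority=1),
            HaplotypeDefinition("A2", profile, priority=1),
        ]
    )
    with pytest.raises(PriorityTieError):
        deduplicate(reg)


def test_match_is_self_consistent(published_registry, motifs):
    for d in published_registry.definitions:
        m = match_profile(published_registry, d.profile, motifs=motifs)
        assert m.status == "assigned"
        assert m.haplotype_name == d.name
        assert m.nearest_distance == 0 and m.nearest_name == d.name


def test_new_profile_becomes_candidate_with_nearest(published_registry, motifs):
    reg = deduplicate(load_registry())
    profile = parse_profile("A15653G C15814T C15955T")
    m = match_profile(reg, profile, motifs=motifs)
    assert m.status == "new_candidate"
    assert m.haplotype_name == "An1"
    assert m.nearest_distance > 0
    # stored: the same profile queried again now resolves to the candidate
    again = match_profile(reg, profile, motifs=motifs)
    assert again.status == "assigned" and again.haplotype_name == "An1"


def test_candidate_names_increment_independently_per_group(motifs):
    reg = Registry(
        definitions=[HaplotypeDefinition("Bn15", parse_profile("A15553G"), priority=1)]
    )
    assert assign_candidate_name(reg, "B") == "Bn16"
    assert assign_candidate_name(reg, "B") == "Bn17"
    assert assign_candidate_name(reg, "C") == "Cn1"
    assert assign_candidate_name(reg, "A") == "An1"
    with pytest.raises(RegistryError):
        assign_candidate_name(reg, "Z")


def _dummy_defs(names):
    # distinct single-substitution profiles keyed off consecutive positions
    defs = []
    for i, name in enumerate(names):
        defs.append(
            HaplotypeDefinition(name, parse_profile(f"A{15460 + i}G"), priority=i + 1)
        )
    return defs


def test_missing_indices_reported():
    present = [i for i in range(1, 56) if i not in {31, 42, 43, 51, 53, 54}]
    reg = Registry(definitions=_dummy_defs([f"B{i}" for i in present]))
    assert missing_indices(reg, "B") == [31, 42, 43, 51, 53, 54]


def test_missing_indices_edge_cases():
    reg = Registry(definitions=_dummy_defs(["A1", "A2", "A3"]))
    assert missing_indices(reg, "A") == []
    assert missing_indices(reg, "B") == []
    reg2 = Registry(definitions=_dummy_defs(["A2"]))
    assert missing_indices(reg2, "A") == [1]
    # candidates are not counted
    reg3 = Registry(definitions=_dummy_defs(["A1"]) + [
        HaplotypeDefinition("An5", parse_profile("C15470T"), priority=9)
    ])
    assert missing_indices(reg3, "A") == []


def test_registry_roundtrip_via_tsv(tmp_path, published_registry):
    path = tmp_path / "reg.tsv"
    save_registry(published_registry, path)
    loaded = load_registry(path)
    assert {d.name for d in loaded.definitions} == published_registry.names()
    for d in loaded.definitions:
        assert d.profile == published_registry.by_name(d.name).profile
    alias_file = tmp_path / "reg_aliases.tsv"
    assert alias_file.exists()
    assert "A228\tA140" in alias_file.read_text(encoding="utf-8")


def test_duplicate_names_rejected():
    with pytest.raises(RegistryError):
        Registry(definitions=_dummy_defs(["A1", "A1"]))
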