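"""Haplotype registry: definitions, matching, candidate naming, reconciliation.

A haplotype definition couples a name (``A246``-style for assigned
haplotypes, ``An1``-style for new candidates awaiting confirmation) with
its mutation profile and the accession of the standard (first-reported)
sequence.  Three reconciliation rules govern the registry:

1. the first sequence reported for a haplotype is its standard sequence
   (modelled by the explicit ``priority`` rank, lower = earlier);
2. of two assigned haplotypes with the same mutation profile the later one
   is eliminated and becomes an alias of the earlier;
3. a sequence annotated with a haplotype name it does not match is
   re-haplotyped from its actual mutation profile.

Matching is exact event-set equality over the whole window: sequences 100%
identical in the 582 bp region belong to one haplotype, flanks are
ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .classifier import (
    DEFAULT_PARTIAL_THRESHOLD,
    GroupCall,
    HaplogroupMotif,
    classify,
    load_motifs,
)
from .mutation_model import MutationProfile, format_profile, parse_profile, profile_distance

__all__ = [
    "HaplotypeDefinition",
    "Registry",
    "MatchResult",
    "RegistryError",
    "PriorityTieError",
    "parse_haplotype_name",
    "load_registry",
    "save_registry",
    "default_registry_path",
    "deduplicate",
    "match_profile",
    "assign_candidate_name",
    "missing_indices",
]

_NAME_RE = re.compile(r"^([A-F])(n?)(\d+)$")


class RegistryError(ValueError):
    """A registry table or name could not be interpreted."""


class PriorityTieError(RegistryError):
    """Two identically-profiled definitions share a priority rank."""


def parse_haplotype_name(name: str) -> tuple[str, bool, int]:
    """Split ``A246`` / ``Bn15`` into (haplogroup, is_candidate, index)."""
    m = _NAME_RE.match(name.strip())
    if not m:
        raise RegistryError(f"unparsable haplotype name {name!r} (expected e.g. 'A246' or 'Bn15')")
    hg, n_flag, idx = m.groups()
    return hg, n_flag == "n", int(idx)


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A named haplotype, its defining profile and standard-sequence provenance."""

    name: str
    profile: MutationProfile
    standard_accession: str = ""
    priority: int = 0
    haplogroup: str = field(init=False)
    is_candidate: bool = field(init=False)
    index: int = field(init=False)

    def __post_init__(self) -> None:
        hg, cand, idx = parse_haplotype_name(self.name)
        object.__setattr__(self, "haplogroup", hg)
        object.__setattr__(self, "is_candidate", cand)
        object.__setattr__(self, "index", idx)


@dataclass
class Registry:
    """Collection of haplotype definitions plus the alias map from rule (2)."""

    definitions: list[HaplotypeDefinition] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_names()

    def _check_names(self) -> None:
        names = [d.name for d in self.definitions]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RegistryError(f"duplicate haplotype names in registry: {dupes}")
        for old, new in self.aliases.items():
            if new not in set(names):
                raise RegistryError(f"alias target {new!r} (for {old!r}) not in registry")

    def by_name(self, name: str) -> HaplotypeDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)

    def resolve(self, name: str) -> str:
        """Follow the alias map to the surviving name (identity if unaliased)."""
        seen = set()
        while name in self.aliases and name not in seen:
            seen.add(name)
            name = self.aliases[name]
        return name

    def names(self) -> set[str]:
        return {d.name for d in self.definitions}

    def in_group(self, haplogroup: str) -> list[HaplotypeDefinition]:
        return [d for d in self.definitions if d.haplogroup == haplogroup]

    def add(self, definition: HaplotypeDefinition) -> None:
        if definition.name in self.names():
            raise RegistryError(f"name {definition.name!r} already registered")
        self.definitions.append(definition)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one profile against the registry."""

    status: str  # "assigned" | "new_candidate"
    haplotype_name: str
    nearest_name: str
    nearest_distance: int
    nearest_tie: bool = False
    group_call: Optional[GroupCall] = None


def default_registry_path() -> Path:
    """Path of the packaged registry of in-print haplotype definitions."""
    return Path(str(resources.files("hv1hap.data").joinpath("published_registry.tsv")))


def load_registry(path: Optional[Union[str, Path]] = None) -> Registry:
    """Load a registry TSV (name, profile, standard_accession, priority).

    Definitions are loaded as printed; duplicate profiles are allowed here
    and resolved explicitly by :func:`deduplicate`.  With no argument the
    packaged table of published definitions is loaded.
    """
    path = Path(path) if path is not None else default_registry_path()
    defs: list[HaplotypeDefinition] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lower().startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise RegistryError(f"{path}:{lineno}: expected 4 tab-separated columns")
            name, profile_text, accession, priority = (p.strip() for p in parts[:4])
            try:
                profile = parse_profile(profile_text, source_id=accession or None)
            except ValueError as exc:
                raise RegistryError(f"{path}:{lineno}: bad profile for {name}: {exc}") from exc
            defs.append(
                HaplotypeDefinition(
                    name=name,
                    profile=profile,
                    standard_accession=accession,
                    priority=int(priority) if priority else 0,
                )
            )
    return Registry(definitions=defs)


def save_registry(reg: Registry, path: Union[str, Path]) -> None:
    """Write a registry back to its TSV form (aliases in a sibling file)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tprofile\tstandard_accession\tpriority\n")
        for d in reg.definitions:
            fh.write(f"{d.name}\t{format_profile(d.profile)}\t{d.standard_accession}\t{d.priority}\n")
    if reg.aliases:
        alias_path = path.with_name(path.stem + "_aliases.tsv")
        with open(alias_path, "w", encoding="utf-8") as fh:
            fh.write("old_name\tnew_name\n")
            for old, new in sorted(reg.aliases.items()):
                fh.write(f"{old}\t{new}\n")


def deduplicate(reg: Registry) -> Registry:
    """Apply reconciliation rule (2): later duplicates of a profile are eliminated.

    Among definitions sharing an identical profile only the earliest
    (lowest priority rank) survives; each eliminated name is recorded as an
    alias of the survivor.  Equal ranks on identical profiles are refused —
    publication order must be made explicit.  Idempotent.
    """
    groups: dict[tuple, list[HaplotypeDefinition]] = {}
    for d in reg.definitions:
        groups.setdefault(d.profile.key, []).append(d)
    survivors: list[HaplotypeDefinition] = []
    aliases = dict(reg.aliases)
    for key, members in groups.items():
        members = sorted(members, key=lambda d: (d.priority, d.name))
        if len(members) > 1 and members[0].priority == members[1].priority:
            names = [d.name for d in members if d.priority == members[0].priority]
            raise PriorityTieError(
                f"definitions {names} share one profile and one priority rank; "
                "set explicit priorities to decide which was reported first"
            )
        survivors.append(members[0])
        for late in members[1:]:
            aliases[late.name] = members[0].name
    surviving_names = {d.name for d in survivors}
    aliases = {old: new for old, new in aliases.items() if old not in surviving_names}
    order = {d.name: i for i, d in enumerate(reg.definitions)}
    survivors.sort(key=lambda d: order[d.name])
    return Registry(definitions=survivors, aliases=aliases)


def assign_candidate_name(reg: Registry, haplogroup: str) -> str:
    """Next free candidate name in a haplogroup (``An1``, ``Bn16``, ...).

    Candidate indices count independently per haplogroup and independently
    of assigned indices.  The returned name is reserved in the registry so
    repeated calls are strictly increasing.
    """
    if haplogroup not in "ABCDEF" or len(haplogroup) != 1:
        raise RegistryError(f"invalid haplogroup {haplogroup!r}")
    reserved = getattr(reg, "_reserved_candidates", None)
    if reserved is None:
        reserved = {}
        reg._reserved_candidates = reserved  # type: ignore[attr-defined]
    existing = [d.index for d in reg.definitions if d.is_candidate and d.haplogroup == haplogroup]
    nxt = max(existing + [reserved.get(haplogroup, 0)], default=0) + 1
    reserved[haplogroup] = nxt
    return f"{haplogroup}n{nxt}"


def _nearest(
    reg: Registry, profile: MutationProfile
) -> tuple[str, int, bool]:
    """Nearest assigned haplotype (candidates only if nothing is assigned)."""
    pool = [d for d in reg.definitions if not d.is_candidate] or reg.definitions
    if not pool:
        return "", 0, False
    scored = sorted((profile_distance(profile, d.profile), d.name) for d in pool)
    best_d, best_name = scored[0]
    tie = len(scored) > 1 and scored[1][0] == best_d
    return best_name, best_d, tie


def match_profile(
    reg: Registry,
    profile: MutationProfile,
    motifs: Optional[list[HaplogroupMotif]] = None,
    partial_threshold: float = DEFAULT_PARTIAL_THRESHOLD,
    register: bool = True,
) -> MatchResult:
    """Match a profile against the registry; name a new candidate if absent.

    An exact profile match returns that haplotype's name.  Otherwise the
    profile is haplogrouped by motif and proposed as the next candidate of
    that group (``register=True`` stores the new definition, so a second
    identical query receives the same candidate name); the nearest assigned
    haplotype and its event distance are reported alongside.
    """
    for d in reg.definitions:
        if d.profile == profile:
            return MatchResult(
                status="assigned",
                haplotype_name=d.name,
                nearest_name=d.name,
                nearest_distance=0,
            )
    motifs = motifs if motifs is not None else load_motifs()
    call = classify(profile, motifs, partial_threshold=partial_threshold)
    nearest_name, nearest_distance, tie = _nearest(reg, profile)
    name = assign_candidate_name(reg, call.haplogroup)
    if register:
        max_priority = max((d.priority for d in reg.definitions), default=0)
        reg.add(
            HaplotypeDefinition(
                name=name,
                profile=profile,
                standard_accession=profile.source_id or "",
                priority=max_priority + 1,
            )
        )
    return MatchResult(
        status="new_candidate",
        haplotype_name=name,
        nearest_name=nearest_name,
        nearest_distance=nearest_distance,
        nearest_tie=tie,
        group_call=call,
    )


def missing_indices(reg: Registry, haplogroup: str) -> list[int]:
    """Skipped index numbers in a haplogroup's assigned-name sequence.

    Returns the sorted integers absent from 1..max(assigned index);
    candidates are excluded from both the range and the result.
    """
    assigned = [d.index for d in reg.definitions if d.haplogroup == haplogroup and not d.is_candidate]
    if not assigned:
        return []
    present = set(assigned)
    return [i for i in range(1, max(assigned) + 1) if i not in present]
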