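"""Annotation auditing and polymorphic-site summaries.

Every record that went through alignment and registry matching receives
exactly one audit category:

* ``correct`` — the claimed name equals the recomputed haplotype;
* ``duplicate_name`` — the claim is an eliminated duplicate name that
  resolves, via the alias map, to the recomputed haplotype (a new name was
  once assigned to an already-assigned haplotype);
* ``wrong_id_new`` — the claim names an assigned haplotype but the
  sequence actually carries a new (candidate) profile;
* ``wrong_id_assigned`` — the claim disagrees with the assigned haplotype
  the sequence really matches;
* ``other_system`` — the claim uses a different haplotyping nomenclature;
* ``absent`` — no haplotype information anywhere in the entry;
* ``partial_excluded`` — the record does not cover the full window and was
  never haplotyped.

The module also derives the per-position mutation table over a registry:
which substitutions (transition/transversion), deletions and insertions
occur where, and which haplotypes carry them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .alignment import Coverage
from .ingest import ABSENT, AF_SYSTEM, OTHER_SYSTEM, SequenceRecord
from .mutation_model import MutationKind, MutationProfile
from .registry import MatchResult, Registry

__all__ = [
    "AuditVerdict",
    "PolymorphicSite",
    "PolymorphicSiteTable",
    "CATEGORIES",
    "audit_record",
    "summarize",
    "polymorphic_sites",
    "substitution_class",
]

CATEGORIES = (
    "correct",
    "duplicate_name",
    "wrong_id_new",
    "wrong_id_assigned",
    "other_system",
    "absent",
    "partial_excluded",
)

_PURINES = frozenset("AG")


def substitution_class(ref_base: str, alt_base: str) -> str:
    """``transition`` (purine<->purine / pyrimidine<->pyrimidine) or ``transversion``."""
    return "transition" if (ref_base in _PURINES) == (alt_base in _PURINES) else "transversion"


@dataclass(frozen=True)
class AuditVerdict:
    accession: str
    category: str
    claim: Optional[str] = None
    recognized_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown audit category {self.category!r}")


def audit_record(
    rec: SequenceRecord,
    match: Optional[MatchResult],
    reg: Registry,
) -> AuditVerdict:
    """Audit one record's annotation claim against its recomputed haplotype.

    ``match`` is None for records that never reached matching (partial or
    non-homologous coverage).
    """
    claim = rec.annotated_haplotype
    if match is None or rec.coverage is not Coverage.FULL:
        return AuditVerdict(rec.accession, "partial_excluded", claim=claim)
    recognized = match.haplotype_name
    if rec.annotation_system == ABSENT:
        return AuditVerdict(rec.accession, "absent", recognized_name=recognized)
    if rec.annotation_system == OTHER_SYSTEM:
        return AuditVerdict(rec.accession, "other_system", claim=claim, recognized_name=recognized)
    # A-F system claim: compare through the alias map
    resolved = reg.resolve(claim)  # type: ignore[arg-type]
    if resolved == recognized:
        category = "correct" if claim == recognized else "duplicate_name"
        return AuditVerdict(rec.accession, category, claim=claim, recognized_name=recognized)
    recognized_def = next((d for d in reg.definitions if d.name == recognized), None)
    is_candidate = recognized_def.is_candidate if recognized_def else match.status == "new_candidate"
    category = "wrong_id_new" if is_candidate else "wrong_id_assigned"
    return AuditVerdict(rec.accession, category, claim=claim, recognized_name=recognized)


def summarize(
    verdicts: Iterable[AuditVerdict],
    records: Optional[Iterable[SequenceRecord]] = None,
    matches: Optional[Iterable[Optional[MatchResult]]] = None,
) -> dict:
    """Count verdicts per category plus pipeline totals.

    With ``records``/``matches`` supplied, also reports how many entries
    were full-length, how many distinct window profiles they carry, and
    the assigned vs new-candidate split.
    """
    verdicts = list(verdicts)
    counts = Counter(v.category for v in verdicts)
    out = {c: counts.get(c, 0) for c in CATEGORIES}
    out["entries"] = len(verdicts)
    if records is not None:
        records = list(records)
        out["full_length"] = sum(1 for r in records if r.coverage is Coverage.FULL)
    if matches is not None:
        matches = [m for m in matches if m is not None]
        out["distinct_sequences"] = len({m.haplotype_name for m in matches})
        out["assigned_matches"] = sum(1 for m in matches if m.status == "assigned")
        out["new_candidates"] = sum(1 for m in matches if m.status == "new_candidate")
    return out


@dataclass
class PolymorphicSite:
    """All changes observed at one reference position across a registry."""

    position: int
    ref_base: Optional[str]
    substitutions: dict[str, list[str]] = field(default_factory=dict)  # alt base -> haplotypes
    deletion_haplotypes: list[str] = field(default_factory=list)
    insertion_haplotypes: list[str] = field(default_factory=list)

    @property
    def has_substitution(self) -> bool:
        return bool(self.substitutions)

    @property
    def has_deletion(self) -> bool:
        return bool(self.deletion_haplotypes)

    @property
    def has_insertion(self) -> bool:
        return bool(self.insertion_haplotypes)

    @property
    def classes(self) -> set[str]:
        return {
            substitution_class(self.ref_base, alt)  # type: ignore[arg-type]
            for alt in self.substitutions
        }


@dataclass
class PolymorphicSiteTable:
    sites: list[PolymorphicSite]
    summary: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "position": s.position,
                    "ref_base": s.ref_base or "",
                    "alt_bases": ",".join(sorted(s.substitutions)),
                    "classes": ",".join(sorted(s.classes)),
                    "deletion": s.has_deletion,
                    "insertion": s.has_insertion,
                    "haplotypes": ",".join(
                        sorted(
                            set(
                                sum(s.substitutions.values(), [])
                                + s.deletion_haplotypes
                                + s.insertion_haplotypes
                            )
                        )
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "position",
                "ref_base",
                "alt_bases",
                "classes",
                "deletion",
                "insertion",
                "haplotypes",
            ],
        )


def polymorphic_sites(
    reg: Registry,
    window_start: Optional[int] = None,
    first_k: int = 200,
) -> PolymorphicSiteTable:
    """Tabulate every position mutated in any registry profile.

    Insertions are keyed to their anchor position.  The summary reports
    the total number of polymorphic sites, how many fall in the first
    ``first_k`` bp of the window, and how many carry a transversion.
    """
    by_pos: dict[int, PolymorphicSite] = {}

    def site(pos: int) -> PolymorphicSite:
        return by_pos.setdefault(pos, PolymorphicSite(position=pos, ref_base=None))

    for d in reg.definitions:
        for e in d.profile:
            s = site(e.position)
            if e.kind is MutationKind.SUBSTITUTION:
                s.ref_base = e.ref_base
                s.substitutions.setdefault(e.alt_base, []).append(d.name)  # type: ignore[arg-type]
            elif e.kind is MutationKind.DELETION:
                s.ref_base = e.ref_base
                if d.name not in s.deletion_haplotypes:
                    s.deletion_haplotypes.append(d.name)
            else:
                if d.name not in s.insertion_haplotypes:
                    s.insertion_haplotypes.append(d.name)
    sites = [by_pos[p] for p in sorted(by_pos)]
    start = window_start if window_start is not None else (min(by_pos) if by_pos else 0)
    n_first = sum(1 for s in sites if s.position < start + first_k)
    n_transversion = sum(1 for s in sites if "transversion" in s.classes)
    summary = {
        "total_sites": len(sites),
        "first_k": first_k,
        "sites_in_first_k": n_first,
        "sites_after_first_k": len(sites) - n_first,
        "transversion_sites": n_transversion,
    }
    return PolymorphicSiteTable(sites=sites, summary=summary)
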