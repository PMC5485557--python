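"""Haplogroup assignment from diagnostic substitution motifs.

Dog HV1 haplotypes fall into six phylogroups A-F.  Groups B-F each carry a
characteristic set of reference positions that are substituted in every
member (the *substitution motif*); haplogroup A has no motif and acts as
the default class.  A motif site is written as reference base + position
(e.g. ``T15639``): it is *hit* when a profile substitutes that position,
whatever the derived base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .mutation_model import MutationKind, MutationProfile

__all__ = [
    "HaplogroupMotif",
    "GroupCall",
    "MotifError",
    "load_motifs",
    "default_motif_path",
    "classify",
    "HAPLOGROUPS",
    "DEFAULT_PARTIAL_THRESHOLD",
]

HAPLOGROUPS = ("A", "B", "C", "D", "E", "F")
DEFAULT_PARTIAL_THRESHOLD = 0.8

_BASES = frozenset("ACGT")


class MotifError(ValueError):
    """A motif table could not be parsed."""


@dataclass(frozen=True)
class HaplogroupMotif:
    """The diagnostic substituted sites of one haplogroup (B-F)."""

    haplogroup: str
    sites: frozenset[tuple[str, int]]  # (reference base, position)

    def __post_init__(self) -> None:
        if self.haplogroup not in HAPLOGROUPS[1:]:
            raise MotifError(f"motifs exist only for haplogroups B-F, not {self.haplogroup!r}")
        if not self.sites:
            raise MotifError(f"motif for {self.haplogroup} has no sites")

    @property
    def size(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class GroupCall:
    """Result of motif classification for one profile."""

    haplogroup: str
    matched_sites: int
    motif_size: int
    full_match: bool
    tie: bool = False


def default_motif_path() -> Path:
    """Path of the packaged default motif table."""
    return Path(str(resources.files("hv1hap.data").joinpath("haplogroup_motifs.tsv")))


def _parse_site(token: str) -> tuple[str, int]:
    t = token.strip().upper().replace(",", "")
    if len(t) < 2 or t[0] not in _BASES or not t[1:].isdigit():
        raise MotifError(f"malformed motif site token {token!r} (expected e.g. 'T15639')")
    return t[0], int(t[1:])


def load_motifs(path: Optional[Union[str, Path]] = None) -> list[HaplogroupMotif]:
    """Load haplogroup motifs from a TSV (haplogroup, comma/space-separated sites).

    With no argument the packaged default table is used.
    """
    path = Path(path) if path is not None else default_motif_path()
    motifs: dict[str, HaplogroupMotif] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.lower().startswith("haplogroup"):
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise MotifError(f"{path}:{lineno}: expected two tab-separated columns")
            hg, raw_sites = parts[0].strip().upper(), parts[1]
            if hg in motifs:
                raise MotifError(f"{path}:{lineno}: duplicate haplogroup row {hg}")
            tokens = [t for t in raw_sites.replace(",", " ").split() if t]
            motifs[hg] = HaplogroupMotif(haplogroup=hg, sites=frozenset(map(_parse_site, tokens)))
    return [motifs[h] for h in sorted(motifs)]


def _substituted_positions(profile: MutationProfile) -> dict[int, str]:
    """position -> reference base, over the profile's substitutions."""
    return {
        e.position: e.ref_base  # type: ignore[misc]
        for e in profile
        if e.kind is MutationKind.SUBSTITUTION
    }


def classify(
    profile: MutationProfile,
    motifs: list[HaplogroupMotif],
    partial_threshold: float = DEFAULT_PARTIAL_THRESHOLD,
) -> GroupCall:
    """Assign a haplogroup to a mutation profile.

    A motif with every site hit wins outright (largest motif first,
    alphabetical on ties, tie flagged).  Otherwise the best partially
    matched motif wins if it reaches ``partial_threshold`` of its sites —
    this tolerates single back-mutations.  Profiles matching no motif well
    enough fall back to haplogroup A, which also receives the empty
    (reference) profile.
    """
    subs = _substituted_positions(profile)
    scored: list[tuple[HaplogroupMotif, int]] = []
    for motif in motifs:
        hits = 0
        for ref_base, pos in motif.sites:
            got = subs.get(pos)
            if got is None:
                continue
            if got == ref_base:
                hits += 1
            else:
                warnings.warn(
                    f"profile substitutes position {pos} from {got} but motif "
                    f"{motif.haplogroup} lists reference base {ref_base}: "
                    "possible numbering inconsistency",
                    stacklevel=2,
                )
        scored.append((motif, hits))

    full = [(m, h) for m, h in scored if h == m.size]
    if full:
        best_size = max(m.size for m, _ in full)
        winners = sorted(m.haplogroup for m, _ in full if m.size == best_size)
        m = next(m for m, _ in full if m.haplogroup == winners[0])
        return GroupCall(winners[0], m.size, m.size, full_match=True, tie=len(winners) > 1)

    partial = [(m, h) for m, h in scored if m.size and h / m.size >= partial_threshold]
    if partial:
        best_frac = max(h / m.size for m, h in partial)
        winners = sorted(m.haplogroup for m, h in partial if h / m.size == best_frac)
        m, h = next((m, h) for m, h in partial if m.haplogroup == winners[0])
        return GroupCall(winners[0], h, m.size, full_match=False, tie=len(winners) > 1)

    return GroupCall("A", 0, 0, full_match=False)
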