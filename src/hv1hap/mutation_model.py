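"""Mutation events, profiles and the ``XnumY`` token notation.

The identity key of an HV1 haplotype is its *mutation profile*: the set of
substitutions, deletions and insertions a sequence carries relative to the
reference window (by default the 582 bp light-strand segment at coordinates
15458-16039 of the dog mitochondrial genome).  Every change is written with
one uniform token grammar:

* substitution — ``T15639G`` (reference base, position, observed base)
* deletion     — ``T15465-`` (reference base, position, gap)
* insertion    — ``-15535.1C`` (gap, anchor position, run index, inserted
  base); a run of k inserted bases after one anchor gets sub-indices 1..k,
  which also handles heteropolymeric tracts such as ``CCCCCTCCCCT``.

Canonical tokens never carry thousands separators; parsers accept them
(``-15,535.1C`` and ``-15535.1C`` are the same token on input).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "MutationKind",
    "MutationEvent",
    "MutationProfile",
    "ReferenceWindow",
    "ProfileError",
    "TokenError",
    "ConsistencyError",
    "format_event",
    "parse_token",
    "parse_profile",
    "format_profile",
    "insertion_run",
    "apply_profile",
    "profile_distance",
    "DEFAULT_WINDOW_START",
    "DEFAULT_WINDOW_END",
]

DEFAULT_WINDOW_START = 15458
DEFAULT_WINDOW_END = 16039

_VALID_BASES = frozenset("ACGT")


class ProfileError(ValueError):
    """A mutation profile violates its structural invariants."""


class TokenError(ProfileError):
    """A mutation token could not be parsed."""


class ConsistencyError(ProfileError):
    """A profile disagrees with the reference sequence it is applied to."""


class MutationKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"


@dataclass(frozen=True)
class MutationEvent:
    """One substitution, deletion or insertion at a numbered position.

    ``position`` is the 1-based reference coordinate; for insertions it is
    the anchor base *after* which the new bases sit, and ``sub_index``
    (1, 2, ...) orders the bases of one insertion run.
    """

    kind: MutationKind
    position: int
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    sub_index: Optional[int] = None

    def __post_init__(self) -> None:
        k = self.kind
        if k is MutationKind.SUBSTITUTION:
            if self.ref_base not in _VALID_BASES or self.alt_base not in _VALID_BASES:
                raise ProfileError(f"substitution at {self.position} needs ACGT ref and alt bases")
            if self.ref_base == self.alt_base:
                raise ProfileError(f"substitution at {self.position} has identical ref and alt base {self.ref_base}")
            if self.sub_index is not None:
                raise ProfileError("substitution carries no sub_index")
        elif k is MutationKind.DELETION:
            if self.ref_base not in _VALID_BASES:
                raise ProfileError(f"deletion at {self.position} needs an ACGT ref base")
            if self.alt_base is not None or self.sub_index is not None:
                raise ProfileError("deletion carries no alt_base or sub_index")
        elif k is MutationKind.INSERTION:
            if self.alt_base not in _VALID_BASES:
                raise ProfileError(f"insertion at {self.position} needs an ACGT alt base")
            if self.ref_base is not None:
                raise ProfileError("insertion carries no ref_base")
            if self.sub_index is None or self.sub_index < 1:
                raise ProfileError(f"insertion at {self.position} needs sub_index >= 1")
        else:  # pragma: no cover - enum is closed
            raise ProfileError(f"unknown mutation kind {k!r}")

    @property
    def sort_key(self) -> tuple[int, int, int]:
        # non-insertion events at a position precede the insertions anchored to it
        return (self.position, 1 if self.kind is MutationKind.INSERTION else 0, self.sub_index or 0)

    def __str__(self) -> str:
        return format_event(self)


def format_event(event: MutationEvent) -> str:
    """Render an event as its canonical token (no thousands separators)."""
    if event.kind is MutationKind.SUBSTITUTION:
        return f"{event.ref_base}{event.position}{event.alt_base}"
    if event.kind is MutationKind.DELETION:
        return f"{event.ref_base}{event.position}-"
    return f"-{event.position}.{event.sub_index}{event.alt_base}"


_SUB_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_DEL_RE = re.compile(r"^([ACGT])(\d+)-$")
_INS_RE = re.compile(r"^-(\d+)\.(\d+)([ACGT])$")


def parse_token(token: str) -> MutationEvent:
    """Parse one mutation token; the inverse of :func:`format_event`.

    Thousands separators inside positions are tolerated (``-15,535.1C``);
    base letters are case-insensitive on input.
    """
    if not token:
        raise TokenError("empty mutation token")
    cleaned = token.strip().upper().replace(",", "")
    m = _SUB_RE.match(cleaned)
    if m:
        ref, pos, alt = m.groups()
        if ref == alt:
            raise TokenError(f"substitution token {token!r} has identical ref and alt base")
        return MutationEvent(MutationKind.SUBSTITUTION, int(pos), ref_base=ref, alt_base=alt)
    m = _DEL_RE.match(cleaned)
    if m:
        ref, pos = m.groups()
        return MutationEvent(MutationKind.DELETION, int(pos), ref_base=ref)
    m = _INS_RE.match(cleaned)
    if m:
        pos, sub_index, alt = m.groups()
        if int(sub_index) < 1:
            raise TokenError(f"insertion token {token!r} has sub_index < 1")
        return MutationEvent(MutationKind.INSERTION, int(pos), alt_base=alt, sub_index=int(sub_index))
    raise TokenError(f"malformed mutation token {token!r}")


@dataclass(frozen=True)
class MutationProfile:
    """An ordered, validated set of mutation events for one sequence.

    The empty profile is legal and denotes the reference haplotype itself.
    Equality and hashing ignore ``source_id``: two sequences with the same
    events are the same haplotype regardless of provenance.
    """

    events: tuple[MutationEvent, ...] = ()
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.events, key=lambda e: e.sort_key))
        object.__setattr__(self, "events", ordered)
        seen_nonins: set[int] = set()
        ins_runs: dict[int, list[int]] = {}
        for e in ordered:
            if e.kind is MutationKind.INSERTION:
                ins_runs.setdefault(e.position, []).append(e.sub_index)  # type: ignore[arg-type]
            else:
                if e.position in seen_nonins:
                    raise ProfileError(f"duplicate substitution/deletion at position {e.position}")
                seen_nonins.add(e.position)
        for pos, idxs in ins_runs.items():
            if idxs != list(range(1, len(idxs) + 1)):
                raise ProfileError(
                    f"insertion run at {pos} has sub_indices {idxs}; expected consecutive from 1"
                )

    def __iter__(self) -> Iterator[MutationEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationProfile):
            return NotImplemented
        return self.events == other.events

    def __hash__(self) -> int:
        return hash(self.events)

    def __str__(self) -> str:
        return format_profile(self)

    @property
    def key(self) -> tuple[MutationEvent, ...]:
        """Hashable identity key (the sorted event tuple)."""
        return self.events


def format_profile(profile: MutationProfile) -> str:
    """Single-line, space-separated canonical token form."""
    return " ".join(format_event(e) for e in profile.events)


def parse_profile(text: str, source_id: Optional[str] = None) -> MutationProfile:
    """Parse a whitespace-separated token list into a validated profile.

    The empty string yields the empty profile (a reference-identical
    sequence); token order in the input is irrelevant.
    """
    tokens = text.split()
    events = tuple(parse_token(t) for t in tokens)
    return MutationProfile(events=events, source_id=source_id)


def insertion_run(position: int, bases: str) -> tuple[MutationEvent, ...]:
    """Build the insertion events for ``bases`` inserted after ``position``.

    Supports heteropolymeric tracts: each inserted base becomes one event
    with sub_index 1..len(bases) in order.
    """
    if not bases:
        raise ProfileError("insertion run needs at least one base")
    up = bases.upper()
    bad = set(up) - _VALID_BASES
    if bad:
        raise ProfileError(f"insertion run contains non-ACGT characters: {sorted(bad)}")
    return tuple(
        MutationEvent(MutationKind.INSERTION, position, alt_base=b, sub_index=i)
        for i, b in enumerate(up, start=1)
    )


@dataclass(frozen=True)
class ReferenceWindow:
    """The reference segment and its coordinate frame (1-based, inclusive)."""

    sequence: str
    start: int = DEFAULT_WINDOW_START
    end: int = DEFAULT_WINDOW_END

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.end < self.start:
            raise ValueError("window end precedes start")
        if len(seq) != self.length:
            raise ValueError(
                f"reference sequence length {len(seq)} does not match window "
                f"{self.start}..{self.end} (expected {self.length})"
            )
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def base_at(self, position: int) -> str:
        if not self.start <= position <= self.end:
            raise IndexError(f"position {position} outside window {self.start}..{self.end}")
        return self.sequence[position - self.start]

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def apply_profile(ref: ReferenceWindow, profile: MutationProfile) -> str:
    """Mutate the reference window sequence according to ``profile``.

    This is the inverse of profile calling and is used to build synthetic
    sequences for testing.  Substitution and deletion ``ref_base`` fields
    are checked against the reference; a mismatch raises
    :class:`ConsistencyError`.
    """
    pieces: dict[int, str] = {p: ref.base_at(p) for p in range(ref.start, ref.end + 1)}
    inserts: dict[int, str] = {}
    for e in profile:
        if not ref.contains(e.position):
            raise ConsistencyError(f"event {format_event(e)} outside window {ref.start}..{ref.end}")
        if e.kind is MutationKind.INSERTION:
            inserts[e.position] = inserts.get(e.position, "") + e.alt_base  # sorted by sub_index
            continue
        actual = ref.base_at(e.position)
        if actual != e.ref_base:
            raise ConsistencyError(
                f"event {format_event(e)} claims reference base {e.ref_base} at "
                f"{e.position} but reference carries {actual}"
            )
        pieces[e.position] = "" if e.kind is MutationKind.DELETION else e.alt_base  # type: ignore[assignment]
    out: list[str] = []
    for p in range(ref.start, ref.end + 1):
        out.append(pieces[p])
        out.append(inserts.get(p, ""))
    return "".join(out)


def profile_distance(a: MutationProfile, b: MutationProfile) -> int:
    """Number of events by which two profiles differ (symmetric difference).

    An event only matches an identical event (same kind, position,
    sub_index, ref and alt base), so ``A15553G`` vs ``A15553T`` counts as
    two differences.  This is the nucleotide-difference count used on
    haplotype-network links.
    """
    return len(set(a.events) ^ set(b.events))
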