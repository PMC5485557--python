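"""Reference-anchored alignment, indel normalization and profile calling.

An input sequence (whole mitogenome, D-loop amplicon or HV1 fragment) is
aligned pairwise to the configured reference window with free end gaps on
both sequences, so query overhang outside the window and window positions
missing from a fragment both cost nothing.  Both orientations are tried and
the better-scoring strand kept.  Gaps are then normalized to their 3'-most
score-equivalent placement so that indels in repeat tracts always yield one
canonical token, and the numbered alignment is converted into a
:class:`~hv1hap.mutation_model.MutationProfile`.

Coverage semantics: a record is ``full`` only when the aligned query spans
every window coordinate (internal deletions are fine, missing ends are
not); ``partial`` records are excluded from haplotyping; ``none`` means the
query has no credible homology to the window (identity below
``min_identity``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from Bio import Align
from Bio.Seq import reverse_complement

from .mutation_model import (
    ConsistencyError,
    MutationEvent,
    MutationKind,
    MutationProfile,
    ReferenceWindow,
    insertion_run,
)

__all__ = [
    "AlignmentParams",
    "Coverage",
    "Strand",
    "AlignmentColumn",
    "NumberedAlignment",
    "CoverageError",
    "InputError",
    "align_to_window",
    "normalize_indels",
    "call_profile",
    "classify_coverage",
    "profile_query",
    "canonicalize_profile",
    "QueryProfile",
    "GAP",
]

GAP = "-"
_IUPAC = frozenset("ACGTRYSWKMBDHVN")
_UNAMBIGUOUS = frozenset("ACGT")


class InputError(ValueError):
    """The query sequence is not a nucleotide sequence."""


class CoverageError(ValueError):
    """Raised when profiling is attempted on a non-full-coverage alignment."""


class Coverage(str, enum.Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


class Strand(str, enum.Enum):
    FORWARD = "forward"
    REVERSE_COMPLEMENTED = "reverse_complemented"


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring and the acceptance threshold for a hit.

    Penalties are positive numbers; ``gap_open`` is charged for the first
    base of a gap and ``gap_extend`` for each further base.
    """

    match_score: float = 1.0
    mismatch_penalty: float = 2.0
    gap_open: float = 5.0
    gap_extend: float = 1.0
    min_identity: float = 0.8
    # a hit must also cover this fraction of min(query length, window length),
    # otherwise a short spurious perfect overlap would pass the identity bar
    min_aligned_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be a fraction in [0, 1]")
        if not 0.0 <= self.min_aligned_fraction <= 1.0:
            raise ValueError("min_aligned_fraction must be a fraction in [0, 1]")

    def pair_score(self, a: str, b: str) -> float:
        return self.match_score if a == b else -self.mismatch_penalty


# A column label is an integer window coordinate, or (anchor, sub_index)
# for an inserted base, or None for a query base outside the window.
Label = Union[int, tuple[int, int], None]


@dataclass(frozen=True)
class AlignmentColumn:
    ref: str
    query: str
    label: Label


@dataclass
class NumberedAlignment:
    """A pairwise alignment of query vs window with per-column coordinates."""

    columns: tuple[AlignmentColumn, ...]
    coverage: Coverage
    strand: Strand
    score: float
    identity: float
    n_ambiguous: int = 0

    @property
    def ref_text(self) -> str:
        return "".join(c.ref for c in self.columns)

    @property
    def query_text(self) -> str:
        return "".join(c.query for c in self.columns)


def _validate_query(query: str) -> str:
    if not query:
        raise InputError("empty query sequence")
    up = query.upper().replace("U", "T")
    bad = set(up) - _IUPAC
    if bad:
        raise InputError(f"query contains non-nucleotide characters: {sorted(bad)}")
    return up


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = -params.mismatch_penalty
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    # free end gaps on both sequences: semi-global / overlap alignment
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def _covered_span(ref_s: str, qry_s: str) -> Optional[tuple[int, int]]:
    """Column span from the first to the last aligned query base."""
    idx = [i for i, q in enumerate(qry_s) if q != GAP]
    if not idx:
        return None
    return idx[0], idx[-1]


def _trim_overhang(ref_s: str, qry_s: str) -> tuple[str, str]:
    """Drop query overhang columns outside the reference span."""
    first = next((i for i, r in enumerate(ref_s) if r != GAP), None)
    if first is None:
        return "", ""
    last = max(i for i, r in enumerate(ref_s) if r != GAP)
    return ref_s[first : last + 1], qry_s[first : last + 1]


def _number_columns(ref_s: str, qry_s: str, window: ReferenceWindow) -> tuple[AlignmentColumn, ...]:
    cols: list[AlignmentColumn] = []
    coord = window.start - 1
    sub_index = 0
    for r, q in zip(ref_s, qry_s):
        if r != GAP:
            coord += 1
            sub_index = 0
            cols.append(AlignmentColumn(r, q, coord))
        else:
            sub_index += 1
            label = (coord, sub_index) if coord >= window.start else None
            cols.append(AlignmentColumn(r, q, label))
    return tuple(cols)


def _coverage_and_identity(
    ref_s: str, qry_s: str, params: AlignmentParams, query_len: int
) -> tuple[Coverage, float]:
    span = _covered_span(ref_s, qry_s)
    if span is None:
        return Coverage.NONE, 0.0
    lo, hi = span
    ref_cols = [i for i, r in enumerate(ref_s) if r != GAP]
    aligned = [i for i in ref_cols if lo <= i <= hi]
    if not aligned:
        return Coverage.NONE, 0.0
    matches = sum(1 for i in aligned if ref_s[i] == qry_s[i])
    identity = matches / len(aligned)
    expected_span = min(query_len, len(ref_cols))
    if identity < params.min_identity or len(aligned) < params.min_aligned_fraction * expected_span:
        return Coverage.NONE, identity
    full = aligned[0] == ref_cols[0] and aligned[-1] == ref_cols[-1]
    return (Coverage.FULL if full else Coverage.PARTIAL), identity


def align_to_window(
    query: str,
    ref: ReferenceWindow,
    params: Optional[AlignmentParams] = None,
) -> NumberedAlignment:
    """Align ``query`` to the reference window on the better strand.

    Returns a numbered, overhang-trimmed alignment; indel placement is the
    aligner's and should be passed through :func:`normalize_indels` before
    profile calling.
    """
    params = params or AlignmentParams()
    up = _validate_query(query)
    aligner = _make_aligner(params)
    best = None
    for strand, seq in (
        (Strand.FORWARD, up),
        (Strand.REVERSE_COMPLEMENTED, reverse_complement(up)),
    ):
        aln = aligner.align(ref.sequence, seq)[0]
        if best is None or aln.score > best[1].score:
            best = (strand, aln, seq)
    strand, aln, seq = best  # type: ignore[misc]
    ref_s, qry_s = _trim_overhang(aln[0], aln[1])
    coverage, identity = _coverage_and_identity(ref_s, qry_s, params, len(up))
    return NumberedAlignment(
        columns=_number_columns(ref_s, qry_s, ref),
        coverage=coverage,
        strand=strand,
        score=float(aln.score),
        identity=identity,
    )


def _shift_gaps_3prime(ref_s: str, qry_s: str, params: AlignmentParams) -> tuple[str, str]:
    """Move every internal gap run to its 3'-most score-equivalent column."""
    ref_l, qry_l = list(ref_s), list(qry_s)
    span = _covered_span(ref_s, qry_s)
    if span is None:
        return ref_s, qry_s
    lo, hi = span
    changed = True
    while changed:
        changed = False
        i = hi
        while i >= lo:
            if qry_l[i] == GAP and ref_l[i] != GAP:  # deletion run end at j
                j = i
                while i - 1 >= lo and qry_l[i - 1] == GAP and ref_l[i - 1] != GAP:
                    i -= 1
                start = i
                # shift the run right while the swap leaves the score unchanged
                while (
                    j + 1 <= hi
                    and qry_l[j + 1] != GAP
                    and ref_l[j + 1] != GAP
                    and params.pair_score(ref_l[start], qry_l[j + 1])
                    == params.pair_score(ref_l[j + 1], qry_l[j + 1])
                ):
                    qry_l[start] = qry_l[j + 1]
                    qry_l[j + 1] = GAP
                    start += 1
                    j += 1
                    changed = True
            elif ref_l[i] == GAP and qry_l[i] != GAP:  # insertion run end at j
                j = i
                while i - 1 >= lo and ref_l[i - 1] == GAP and qry_l[i - 1] != GAP:
                    i -= 1
                start = i
                while (
                    j + 1 <= hi
                    and ref_l[j + 1] != GAP
                    and qry_l[j + 1] != GAP
                    and params.pair_score(ref_l[j + 1], qry_l[start])
                    == params.pair_score(ref_l[j + 1], qry_l[j + 1])
                ):
                    ref_l[start] = ref_l[j + 1]
                    ref_l[j + 1] = GAP
                    start += 1
                    j += 1
                    changed = True
            i -= 1
    return "".join(ref_l), "".join(qry_l)


def normalize_indels(
    aln: NumberedAlignment,
    ref: ReferenceWindow,
    params: Optional[AlignmentParams] = None,
) -> NumberedAlignment:
    """Canonicalize indel placement (3'-most equivalent position).

    Within a homopolymer or repeat tract many gap placements score the
    same; this shifts each gap run as far toward the high-coordinate end as
    possible without changing the alignment score or either sequence, so
    that e.g. a C deleted from a C-run is always reported at the run's last
    coordinate and an insertion is anchored after the run.  Idempotent.
    """
    params = params or AlignmentParams()
    ref_s, qry_s = _shift_gaps_3prime(aln.ref_text, aln.query_text, params)
    # shifting preserves score, both sequences and the match count, so the
    # align-time coverage and identity still describe this alignment
    return replace(aln, columns=_number_columns(ref_s, qry_s, ref))


def classify_coverage(aln: NumberedAlignment, ref: ReferenceWindow) -> Coverage:
    """Window coverage class of an alignment (full / partial / none)."""
    return aln.coverage


def call_profile(
    aln: NumberedAlignment,
    ref: ReferenceWindow,
    n_policy: str = "exclude",
) -> MutationProfile:
    """Convert a full-coverage, normalized alignment into a profile.

    Ambiguity codes in the query are handled per ``n_policy``:
    ``"exclude"`` (default) drops the column from the profile and counts it
    in ``aln.n_ambiguous``; ``"strict"`` raises.  Partial or non-homologous
    alignments are refused: partial segments are not haplotyped.
    """
    if aln.coverage is not Coverage.FULL:
        raise CoverageError(
            f"cannot call a profile on coverage={aln.coverage.value}; "
            "only full 582 bp-window sequences are haplotyped"
        )
    if n_policy not in ("exclude", "strict"):
        raise ValueError(f"unknown n_policy {n_policy!r}")
    events: list[MutationEvent] = []
    pending_ins: dict[int, str] = {}
    n_ambiguous = 0
    for col in aln.columns:
        if col.ref == GAP:
            if col.query == GAP or col.label is None:
                continue
            if col.query not in _UNAMBIGUOUS:
                if n_policy == "strict":
                    raise ConsistencyError(f"ambiguous base {col.query} in insertion at {col.label}")
                n_ambiguous += 1
                continue
            anchor = col.label[0]  # type: ignore[index]
            pending_ins[anchor] = pending_ins.get(anchor, "") + col.query
        else:
            pos = col.label  # integer coordinate
            if col.query == GAP:
                events.append(MutationEvent(MutationKind.DELETION, pos, ref_base=col.ref))
            elif col.query == col.ref:
                continue
            elif col.query not in _UNAMBIGUOUS:
                if n_policy == "strict":
                    raise ConsistencyError(f"ambiguous base {col.query} at position {pos}")
                n_ambiguous += 1
            else:
                events.append(
                    MutationEvent(
                        MutationKind.SUBSTITUTION, pos, ref_base=col.ref, alt_base=col.query
                    )
                )
    for anchor, bases in pending_ins.items():
        events.extend(insertion_run(anchor, bases))
    aln.n_ambiguous = n_ambiguous
    return MutationProfile(events=tuple(events))


@dataclass(frozen=True)
class QueryProfile:
    """Record-level profiling result for one query sequence."""

    strand: Strand
    coverage: Coverage
    identity: float
    n_ambiguous: int
    profile: Optional[MutationProfile]


def profile_query(
    query: str,
    ref: ReferenceWindow,
    params: Optional[AlignmentParams] = None,
    n_policy: str = "exclude",
) -> QueryProfile:
    """Align, normalize and (when coverage is full) call one query."""
    params = params or AlignmentParams()
    aln = normalize_indels(align_to_window(query, ref, params), ref, params)
    if aln.coverage is Coverage.FULL:
        profile = call_profile(aln, ref, n_policy=n_policy)
    else:
        profile = None
    return QueryProfile(
        strand=aln.strand,
        coverage=aln.coverage,
        identity=aln.identity,
        n_ambiguous=aln.n_ambiguous,
        profile=profile,
    )


def canonicalize_profile(
    ref: ReferenceWindow,
    profile: MutationProfile,
    params: Optional[AlignmentParams] = None,
) -> MutationProfile:
    """Rewrite a profile into the canonical 3'-shifted form.

    Applies the profile to the reference and re-calls it through the
    align/normalize/call path, so indels specified anywhere inside a repeat
    tract come back at the tract's 3' end.
    """
    from .mutation_model import apply_profile

    mutated = apply_profile(ref, profile)
    result = profile_query(mutated, ref, params=params)
    if result.profile is None:  # pragma: no cover - applying a valid profile keeps coverage full
        raise ConsistencyError("profile application lost window coverage")
    return result.profile
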