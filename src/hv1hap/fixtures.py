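"""Synthetic references, registries and GenBank-like records for testing.

Everything the pipeline consumes can be generated offline: a reference
window with homopolymer tracts (the feature that makes indel placement
ambiguous), a registry of motif-consistent haplotype definitions per
haplogroup, and GenBank flat-file records whose annotations can be
corrupted in each of the audit categories.  All randomness flows from
``FixtureSpec.seed``; the same spec always yields byte-identical output.

Generated profiles are stored in canonical 3'-shifted form (via the real
align/normalize/call path), so a generated registry is exactly what the
pipeline recovers from the generated sequences.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .alignment import canonicalize_profile
from .classifier import HaplogroupMotif, load_motifs
from .mutation_model import (
    DEFAULT_WINDOW_START,
    MutationEvent,
    MutationKind,
    MutationProfile,
    ReferenceWindow,
    apply_profile,
    insertion_run,
)
from .registry import HaplotypeDefinition, Registry

__all__ = [
    "FixtureSpec",
    "CORRUPTIONS",
    "make_reference",
    "make_registry",
    "make_records",
    "random_profile",
]

_BASES = "ACGT"

CORRUPTIONS = (
    "correct",
    "wrong_assigned",
    "wrong_new",
    "duplicate_name",
    "other_system",
    "absent",
    "truncate",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic study; same seed, same outputs."""

    seed: int = 0
    window_length: int = 582
    window_start: int = DEFAULT_WINDOW_START
    n_per_group: int = 2
    events_min: int = 1
    events_max: int = 4
    indel_fraction: float = 0.2
    homopolymer_injection: bool = True
    flank_length: int = 25
    organism: str = "Canis lupus familiaris"

    @property
    def window_end(self) -> int:
        return self.window_start + self.window_length - 1


def make_reference(
    spec: FixtureSpec, motifs: Optional[list[HaplogroupMotif]] = None
) -> ReferenceWindow:
    """Random reference window, optionally homopolymer-laced.

    When motifs are given, the reference base at every motif site inside
    the window is forced to the motif's listed base, so motif-consistent
    profiles can be applied to this reference.
    """
    rng = random.Random(spec.seed)
    seq = [rng.choice(_BASES) for _ in range(spec.window_length)]
    if spec.homopolymer_injection:
        n_runs = max(1, spec.window_length // 80)
        for _ in range(n_runs):
            run_len = rng.randint(5, 8)
            start = rng.randrange(0, max(1, spec.window_length - run_len))
            base = rng.choice(_BASES)
            for i in range(start, min(start + run_len, spec.window_length)):
                seq[i] = base
    if motifs:
        for motif in motifs:
            for ref_base, pos in motif.sites:
                if spec.window_start <= pos <= spec.window_end:
                    seq[pos - spec.window_start] = ref_base
    return ReferenceWindow(
        sequence="".join(seq), start=spec.window_start, end=spec.window_end
    )


def _motif_positions(motifs: list[HaplogroupMotif]) -> set[int]:
    return {pos for m in motifs for _, pos in m.sites}


def random_profile(
    rng: random.Random,
    ref: ReferenceWindow,
    n_events: int,
    forbidden_positions: set[int],
    indel_fraction: float = 0.2,
    edge_margin: int = 12,
) -> MutationProfile:
    """Random private events at positions outside ``forbidden_positions``.

    Events may be placed anywhere inside a repeat tract; callers wanting
    the canonical form should pass the result through
    :func:`~hv1hap.alignment.canonicalize_profile`.  ``edge_margin`` keeps
    events away from the window boundaries, where an indel in a sequence
    without flanks is indistinguishable from truncation.
    """
    events: list[MutationEvent] = []
    used: set[int] = set()
    candidates = [
        p
        for p in range(ref.start + edge_margin, ref.end - edge_margin + 1)
        if p not in forbidden_positions
    ]
    rng.shuffle(candidates)
    for pos in candidates:
        if len(events) >= n_events or any(abs(pos - u) < 2 for u in used):
            if len(events) >= n_events:
                break
            continue
        used.add(pos)
        roll = rng.random()
        if roll < indel_fraction / 2:
            events.append(MutationEvent(MutationKind.DELETION, pos, ref_base=ref.base_at(pos)))
        elif roll < indel_fraction:
            bases = "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 3)))
            events.extend(insertion_run(pos, bases))
        else:
            refb = ref.base_at(pos)
            alt = rng.choice([b for b in _BASES if b != refb])
            events.append(
                MutationEvent(MutationKind.SUBSTITUTION, pos, ref_base=refb, alt_base=alt)
            )
    return MutationProfile(events=tuple(events))


def make_registry(
    spec: FixtureSpec,
    ref: ReferenceWindow,
    motifs: Optional[list[HaplogroupMotif]] = None,
) -> Registry:
    """Motif-consistent synthetic registry.

    For each haplogroup B-F, every generated haplotype substitutes all of
    the group's motif sites (random derived bases) plus private events at
    non-motif positions; haplogroup A haplotypes carry only non-motif
    events and therefore never fully contain a motif.  Profiles are
    canonicalized and guaranteed pairwise distinct.
    """
    motifs = motifs if motifs is not None else load_motifs()
    for m in motifs:
        for _, pos in m.sites:
            if not ref.contains(pos):
                raise ValueError(
                    f"window {ref.start}..{ref.end} too short to host motif "
                    f"{m.haplogroup} site at {pos}"
                )
    rng = random.Random(spec.seed + 1)
    forbidden = _motif_positions(motifs)
    defs: list[HaplotypeDefinition] = []
    seen_profiles: set[tuple] = set()
    priority = 0
    by_group = {m.haplogroup: m for m in motifs}
    for hg in "ABCDEF":
        made = 0
        attempts = 0
        while made < spec.n_per_group and attempts < 50 * spec.n_per_group:
            attempts += 1
            base_events: list[MutationEvent] = []
            if hg in by_group:
                for ref_base, pos in sorted(by_group[hg].sites, key=lambda s: s[1]):
                    alt = rng.choice([b for b in _BASES if b != ref_base])
                    base_events.append(
                        MutationEvent(
                            MutationKind.SUBSTITUTION, pos, ref_base=ref_base, alt_base=alt
                        )
                    )
            n_private = rng.randint(spec.events_min, spec.events_max)
            private = random_profile(
                rng, ref, n_private, forbidden, indel_fraction=spec.indel_fraction
            )
            try:
                profile = MutationProfile(events=tuple(base_events) + private.events)
                profile = canonicalize_profile(ref, profile)
            except ValueError:
                continue
            if profile.key in seen_profiles or not profile.events:
                continue
            seen_profiles.add(profile.key)
            made += 1
            priority += 1
            defs.append(
                HaplotypeDefinition(
                    name=f"{hg}{made}",
                    profile=profile,
                    standard_accession=f"SYN{priority:05d}.1",
                    priority=priority,
                )
            )
        if made < spec.n_per_group:
            raise RuntimeError(f"could not generate {spec.n_per_group} distinct {hg} profiles")
    return Registry(definitions=defs)


def _random_flank(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def make_records(
    reg: Registry,
    ref: ReferenceWindow,
    spec: FixtureSpec,
    corruptions: Optional[dict[str, str]] = None,
) -> str:
    """Emit GenBank flat-file text carrying the registry's sequences.

    ``corruptions`` maps a haplotype name to one of :data:`CORRUPTIONS`;
    unlisted haplotypes get a correct annotation.  ``duplicate_name``
    requires the registry to carry aliases (the record is annotated with
    an eliminated alias of its haplotype); ``wrong_new`` adds one extra
    private substitution so the sequence carries a profile absent from the
    registry while still claiming the original name.
    """
    corruptions = corruptions or {}
    unknown = set(corruptions.values()) - set(CORRUPTIONS)
    if unknown:
        raise ValueError(f"unknown corruption categories: {sorted(unknown)}")
    rng = random.Random(spec.seed + 2)
    assigned = [d for d in reg.definitions if not d.is_candidate]
    out: list[SeqRecord] = []
    for i, d in enumerate(reg.definitions):
        mode = corruptions.get(d.name, "correct")
        profile = d.profile
        claim: Optional[str] = d.name
        if mode == "wrong_assigned":
            others = [o.name for o in assigned if o.name != d.name]
            if not others:
                raise ValueError("wrong_assigned needs at least two assigned haplotypes")
            claim = rng.choice(others)
        elif mode == "wrong_new":
            profile = _perturb(rng, ref, profile)
        elif mode == "duplicate_name":
            alias_names = [old for old, new in reg.aliases.items() if new == d.name]
            if not alias_names:
                raise ValueError(f"duplicate_name corruption for {d.name} needs an alias")
            claim = sorted(alias_names)[0]
        elif mode == "other_system":
            claim = f"Hx{d.index}_{rng.randint(1, 9)}"
        elif mode == "absent":
            claim = None
        seq = (
            _random_flank(rng, spec.flank_length)
            + apply_profile(ref, profile)
            + _random_flank(rng, spec.flank_length)
        )
        if mode == "truncate":
            seq = seq[: len(seq) // 2]
        accession = f"SYN{i + 1:05d}.1"
        record = SeqRecord(
            Seq(seq),
            id=accession,
            name=accession.split(".")[0],
            description=f"{spec.organism} synthetic record for {d.name}, D-loop HV1",
            annotations={"molecule_type": "DNA", "organism": spec.organism, "topology": "linear"},
        )
        qualifiers: dict[str, list[str]] = {"organism": [spec.organism]}
        if claim is not None:
            qualifiers["haplotype"] = [claim]
        record.features.append(
            SeqFeature(FeatureLocation(0, len(seq)), type="source", qualifiers=qualifiers)
        )
        out.append(record)
    buf = StringIO()
    SeqIO.write(out, buf, "genbank")
    return buf.getvalue()


def _perturb(rng: random.Random, ref: ReferenceWindow, profile: MutationProfile) -> MutationProfile:
    """Add one private substitution, yielding a new canonical profile."""
    taken = {e.position for e in profile}
    for _ in range(200):
        pos = rng.randrange(ref.start + 12, ref.end - 11)
        if any(abs(pos - t) < 2 for t in taken):
            continue
        refb = ref.base_at(pos)
        alt = rng.choice([b for b in _BASES if b != refb])
        event = MutationEvent(MutationKind.SUBSTITUTION, pos, ref_base=refb, alt_base=alt)
        new = canonicalize_profile(ref, MutationProfile(events=profile.events + (event,)))
        if new != profile:
            return new
    raise RuntimeError("could not perturb profile")
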