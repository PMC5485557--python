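# Methods

## Coordinate frame and mutation notation

All positions are 1-based light-strand coordinates of the reference
mitogenome; the HV1 window defaults to 15,458–16,039 (582 bp). A mutation
profile is the sorted set of events in that window, each written as one
token: `XposY` for a substitution (`X` the reference base, `Y` the
observed base), `Xpos-` for a deletion, and `-pos.kY` for the *k*-th base
of an insertion run anchored **after** position `pos`. Indexing inserted
bases individually (rather than counting them, as the older
`15,534.2C`-style shorthand does) keeps heteropolymeric insertions such
as the 11-mer `CCCCCTCCCCT` representable in the same grammar. Canonical
tokens carry no thousands separators; the parsers accept them, as the
typeset literature uses `15,535`-style grouping. The empty profile is
legal and denotes the reference haplotype itself. Event equality is
full-field equality, so a substitution and a deletion at one position are
distinct events, and `A15553G` vs `A15553T` differ by two events; the
profile distance used throughout (nearest-haplotype reporting, network
links) is the symmetric-difference count, which is a metric.

## Alignment

Queries are aligned to the window by pairwise semi-global alignment
(Biopython `PairwiseAligner`; affine gap scoring, free end gaps on both
sequences). Free end gaps make a single pass serve both whole-mitogenome
queries (overhang beyond the window is free) and fragments (missing
window positions are free, the record is classed `partial`). Both
orientations are aligned and the better-scoring strand kept; reverse-
strand hits are profiled on the reverse complement and flagged. Defaults:
match +1, mismatch −2, gap open 5, gap extend 1 — a deliberately
gap-averse scheme appropriate to a region where point substitutions
dominate; all are tunable. A multiple-sequence aligner would add nothing
here: only query-versus-reference pairs are ever consulted, and pairwise
alignment is deterministic and dependency-light.

A hit is accepted when identity over the aligned window columns reaches
`min_identity` (default 0.8) **and** the aligned span covers at least
`min_aligned_fraction` (default 0.5) of `min(query length, window
length)`. The second criterion exists because with free end gaps an
unrelated sequence can produce a short spurious overlap of perfect
identity; span length, not identity alone, separates `none` from
`partial`. Coverage is `full` only when the aligned query spans every
window coordinate — internal deletions count as covered, missing ends do
not — and only full-coverage records are haplotyped.

## Indel normalization

Within a homopolymer or repeat tract many gap placements score
identically, and the same physical variant would otherwise yield
different tokens. After alignment every internal gap run is shifted
stepwise toward higher coordinates as long as the move preserves the
alignment score and both sequences (for a deletion run this is the
classic rotate-right within a repeat; for an insertion the anchor slides
past equal next bases). The procedure is idempotent and score-preserving,
and reports indels at the 3′ end of their tract — e.g. an insertion is
anchored *after* the last base of the run it extends. The shift
direction is a convention; the normalizer is written so a 5′ variant
would be a localized change, but 3′ is the package-wide canonical form
and the one the packaged registry profiles use.

One boundary case is intrinsic, not an implementation choice: an indel
in the first or last few window positions of a *flankless* sequence is
indistinguishable from truncation, because the score-optimal reading
absorbs it into the free end gap. Sequences with flanking context (whole
genomes, amplicons) do not have this ambiguity. The synthetic generator
therefore keeps events 12 bp clear of the window edges.

Ambiguity codes (N, R, Y, …) in a query are never counted as
substitutions: by default the column is excluded from the profile and
counted in a per-record ambiguity tally (`n_policy="exclude"`); a strict
policy that raises instead is available. This conservative default
avoids fabricating haplotypes from low-quality bases.

## Haplogroup classification

Haplogroups B–F carry diagnostic substitution motifs — sets of
(reference base, position) pairs substituted in every member; the
packaged motif table lists 8, 7, 10, 8 and 10 sites respectively.
A motif site is *hit* when the profile substitutes that position from
the listed reference base, whatever the derived base (the motif tokens
name reference bases: the printed profiles substitute *from* them, e.g.
motif site `T15639` against profile token `T15639A`). A profile fully
containing at least one motif is assigned the largest such motif
(alphabetical on ties, tie flagged). Otherwise the best partial match
wins if it reaches `partial_threshold` (default 0.8) of its motif — this
tolerates a single back-mutation in the 7–10-site motifs without
over-claiming. Anything else falls to haplogroup A, the motif-less
default, which also receives the empty profile. A substitution at a
motif position whose reference base disagrees with the motif's is a
warning (possible numbering slip), never fatal.

## Registry, matching and reconciliation

A haplotype definition binds a name (`A246`; candidates `An1`, `Bn15`)
to its profile, the accession of its standard (first-reported) sequence,
and an integer `priority` rank standing in for publication order —
explicit, because release dates are not reliably recoverable offline,
and ties on identical profiles are an error rather than a silent choice.
Reconciliation eliminates the later of two identically-profiled names
and records it as an alias of the survivor; deduplication is idempotent
and every alias resolves. Matching is exact event-set equality; a miss
classifies the profile by motif and reserves the next candidate index in
that haplogroup (`An1` for the first new A). New candidates are stored
in the registry, so a later identical query receives the same candidate
name, and candidate numbering survives save/load. The nearest assigned
haplotype and its distance accompany every candidate proposal;
assignment of a new haplotype name proper remains a human decision.

## Audit semantics

Each record receives exactly one category. Partial/non-homologous
coverage short-circuits to `partial_excluded`; no claim is `absent`; a
claim outside the one-letter-plus-digits A–F pattern is `other_system`
(candidate-style `An3` claims are deliberately not canonical). An A–F
claim is compared through the alias map: equality after resolution but
not before is `duplicate_name`, preserving the distinction between a
merely superseded name and a genuinely wrong one; a wrong claim is
`wrong_id_assigned` or `wrong_id_new` according to whether the sequence's
recomputed haplotype is assigned or a new candidate. Headline counts of
any given public-database snapshot depend on that snapshot; the category
logic here is exercised on packaged and synthetic fixtures.

The polymorphic-site table aggregates every registry profile per
position (insertions keyed to their anchor), classifies substitutions as
transitions or transversions, and summarizes total sites, sites in the
first *K* bp of the window (default 200, where HV1 variation
concentrates) and transversion-bearing sites.

## Networks

Per haplogroup, the complete profile-distance graph is reduced by
Kruskal's algorithm with edges sorted by (distance, endpoint names), so
the tree is deterministic; any non-tree edge whose distance equals the
bottleneck on the tree path between its endpoints belongs to some other
minimum tree and is retained, flagged as an alternative link. This is a
minimum-spanning approximation to median-joining-style haplotype
networks: link distances and node commonness match that presentation,
but no median (inferred intermediate) vectors are constructed. Exports:
GML, DOT, and a TSV edge list that round-trips losslessly.

## Synthetic data

The generator emulates the study conditions at desk scale: a 582 bp
reference with injected homopolymer runs (≥5 bases — the feature that
makes indel placement ambiguous), optionally constrained to carry the
motif reference bases; per haplogroup, haplotypes that substitute all
motif sites plus 1–4 private events (20% indels) at non-motif positions,
haplogroup A haplotypes from private events only, so they never contain
a motif; and GenBank-format records with 25 bp random flanks and
controllable annotation corruptions, one per audit category. Generated
profiles are stored in canonical 3′ form by running them through the
real apply→align→normalize→call path, so a generated registry is
*exactly* what the pipeline should recover — the round-trip tests are
strict equalities, not approximate ones. All randomness flows from
`FixtureSpec.seed`; equal specs give byte-identical outputs.

What the generator does not emulate: sequencing error and chromatogram
ambiguity, biased base composition of the real control region, the
VNTR-adjacent context outside the window, database-scale haplotype
frequency skew, and indels at window edges (excluded as unresolvable
without flanks, see above). Passing tests therefore demonstrate the
correctness of the profiling, naming, reconciliation and audit logic
under clean sequence, not robustness to noisy reads.

## Problem sizes and numerical choices

The test suite runs the apply→call round trip on 200 seeded random
profiles of ≤4 events against the full 582 bp window, the full
fixtures→ingest→haplotype→audit pipeline on 205 records (204 haplotypes
plus one duplicate for the alias path), normalization against a
brute-force gap-placement oracle over every central position of a
repeat-rich window, metric axioms by exhaustive small-profile
enumeration, and network minimality against exhaustive spanning-tree
enumeration for up to 7 nodes. These sizes exercise every code path
while keeping the suite fast enough to run habitually. Determinism:
alignments, tie-breaks (alphabetical names, lexicographic edge order)
and generator seeds are all fixed, so repeated runs are byte-identical.

## Known limitations

- Exact-equality matching means one ambiguous base excluded from a
  profile can make a sequence match a haplotype it may not carry; the
  per-record ambiguity tally is reported so such calls can be reviewed.
- The 3′-shift convention follows the "right position" placement of the
  adopted nomenclature as this package reads it; projects requiring
  5′-normalization (e.g. VCF-style left alignment) must renormalize.
- Candidate naming is per-registry-instance: two curators starting from
  the same registry and processing different queries will mint
  overlapping candidate names, which is why candidates are proposals,
  not assignments.
- The network builder does not infer unsampled intermediate haplotypes;
  long links that a median-joining method would subdivide remain long.
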