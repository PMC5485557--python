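# hv1hap

Haplotyping toolkit for the 582 bp hypervariable region 1 (HV1) window of
the dog and wolf mitochondrial control region (reference coordinates
15,458–16,039, light strand).

Mitochondrial HV1 haplotypes are widely used in canine forensics, breed
tracing and phylogeography, but public-database entries carry the
haplotype information inconsistently: wrong names, names from other
nomenclatures, duplicated names for one sequence variant, or no annotation
at all. `hv1hap` recomputes haplotypes from the sequences themselves so
the annotations can be checked and reconciled. It is aimed at researchers
and curators who work with *Canis lupus* control-region data.

## What it computes

Every sequence is reduced to its **mutation profile**: the set of changes
in the 582 bp window relative to the reference, written in one uniform
token grammar — `T15639G` (substitution), `T15465-` (deletion),
`-15535.1C -15535.2C` (two bases inserted after position 15,535; the
`.k` suffix indexes the bases of a run, so heteropolymeric insertions such
as `CCCCCTCCCCT` are representable). The profile is the haplotype
identity key: two sequences with identical 582 bp windows have the same
haplotype regardless of flanking sequence.

The pipeline is:

1. **align** — semi-global pairwise alignment of the query (whole
   mitogenome, amplicon or fragment) to the reference window, affine gap
   scoring, both strands tried; free end gaps on both sequences.
2. **normalize** — every gap is shifted to its 3′-most score-equivalent
   placement, so an indel inside a homopolymer or repeat tract always
   yields one canonical token.
3. **call** — mismatch columns become substitutions, reference-gap and
   query-gap columns become insertions/deletions; only sequences covering
   the full window are haplotyped, partial segments are reported and
   excluded.
4. **classify** — haplogroups B–F are recognized by their diagnostic
   substitution motifs (sets of reference positions substituted in every
   member, e.g. `C15508, C15526, T15639, T15650, T15800, C15912, C15955`
   for haplogroup C); haplogroup A is the motif-less default.
5. **match** — exact profile equality against a registry of named
   definitions; unmatched profiles are proposed as new candidates
   (`An1`, `Bn15`, …) with the nearest assigned haplotype and its
   nucleotide distance reported.
6. **reconcile & audit** — the registry obeys three rules: the
   first-reported sequence is a haplotype's standard; of two names with
   one profile the later is eliminated (kept as an alias); a sequence
   annotated with a name it does not match is re-haplotyped from its
   profile. Each audited entry gets one verdict: `correct`,
   `duplicate_name`, `wrong_id_new`, `wrong_id_assigned`, `other_system`,
   `absent`, or `partial_excluded`.
7. **network** — per haplogroup, a minimum-distance spanning network of
   haplotypes with links labelled by nucleotide differences and node
   weights giving commonness; equal-cost alternative links are retained
   and flagged as reticulations.

A registry of the haplotype definitions printed in the source literature
and the haplogroup motif table ship as packaged TSV fixtures, so the
worked examples run with no downloads. The reference sequence itself is
supplied by configuration (any FASTA with the window at a known offset);
synthetic references for testing come from `hv1hap.fixtures`.

## Worked example

Matching the printed profile of GenBank entry JF342836.1 (annotated
`A171`) against the packaged, reconciled registry:

```python
from hv1hap import parse_profile, load_registry, deduplicate, match_profile, load_motifs

reg = deduplicate(load_registry())
profile = parse_profile("A15553G T15639A C15814T A15931-")
m = match_profile(reg, profile, motifs=load_motifs())
print(f"haplotype: {m.haplotype_name}  status: {m.status}  nearest: {m.nearest_name} (d={m.nearest_distance})")
```

prints

```
haplotype: A246  status: assigned  nearest: A246 (d=0)
```

i.e. the sequence's three substitutions plus one deletion are exactly the
defining profile of haplotype A246 — the `A171` annotation is wrong.
A profile absent from the registry is proposed as a candidate instead:

```
candidate: An1  status: new_candidate  nearest: A17 (d=4)
```

(the first new haplogroup-A haplotype; its nearest assigned neighbour is
A17, four events away).

The same operations are available from the shell. A fully synthetic
round trip:

```sh
hv1hap fixtures --seed 7 --outdir demo --n-per-group 2
hv1hap haplotype demo/records.gb --reference demo/reference.fasta --registry demo/registry.tsv
hv1hap audit demo/records.gb --reference demo/reference.fasta \
    --registry demo/registry.tsv --out demo/audit.tsv --summary demo/summary.json
hv1hap network --registry demo/registry.tsv --haplogroup C --fmt tsv --out demo/net.tsv
```

The haplotype table assigns every generated record back to its generating
name (`SYN00001.1  A1  assigned  A1  0` …), the audit summary counts
`"correct": 12` of `"entries": 12`, and the network TSV lists the
haplogroup-C nodes with their single distance-labelled link.

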