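"""Reading GenBank flat files and FASTA into pipeline records.

Each ingested entry keeps the fields the haplotyping pipeline and the
annotation audit need: accession, definition line, source organism, raw
sequence, and the haplotype the submitter claimed (from the ``/haplotype``
qualifier, or failing that from a ``haplotype <token>`` phrase in the
definition line).  Claims written as one letter A-F plus digits are tagged
as belonging to the A-F naming system; anything else (``Be36_2`` etc.) is
another haplotyping system.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO

from .alignment import Coverage

__all__ = [
    "SequenceRecord",
    "IngestError",
    "read_genbank",
    "read_fasta",
    "species_filter",
    "partition_by_species",
    "AF_SYSTEM",
    "OTHER_SYSTEM",
    "ABSENT",
]

AF_SYSTEM = "AF_system"
OTHER_SYSTEM = "other_system"
ABSENT = "absent"

# candidate ("n") names in annotations are deliberately NOT canonical
_AF_NAME_RE = re.compile(r"^[A-F][0-9]+$")
_DEFLINE_HAPLO_RE = re.compile(r"\bhaplotype[:=\s]+([A-Za-z0-9_.\-]+)", re.IGNORECASE)
_HEADER_HAPLO_RE = re.compile(r"\bhaplotype=([A-Za-z0-9_.\-]+)")


class IngestError(ValueError):
    """An input file could not be parsed."""


@dataclass
class SequenceRecord:
    """One ingested sequence entry with its annotation claim."""

    accession: str
    definition: str
    organism: str
    sequence: str
    annotated_haplotype: Optional[str] = None
    annotation_system: str = ABSENT
    coverage: Optional[Coverage] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise IngestError("record without accession")
        self.sequence = self.sequence.upper()
        self.annotation_system = _annotation_system(self.annotated_haplotype)


def _annotation_system(claim: Optional[str]) -> str:
    if not claim:
        return ABSENT
    return AF_SYSTEM if _AF_NAME_RE.match(claim) else OTHER_SYSTEM


def _strip_punct(token: str) -> str:
    return token.strip(".,;:()[]\"'")


def _claim_from_definition(definition: str) -> Optional[str]:
    m = _DEFLINE_HAPLO_RE.search(definition)
    if m:
        token = _strip_punct(m.group(1))
        return token or None
    return None


def read_genbank(path: Union[str, Path]) -> list[SequenceRecord]:
    """Parse a GenBank flat file into sequence records.

    Organism comes from the source feature / annotations; the haplotype
    claim prefers the ``/haplotype`` qualifier over the definition line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        context = records[-1].accession if records else "start of file"
        raise IngestError(f"{path}: GenBank parse failure after {context}: {exc}") from exc
    for rec in parsed:
        organism = rec.annotations.get("organism", "")
        claim: Optional[str] = None
        for feature in rec.features:
            if feature.type == "source":
                organism = feature.qualifiers.get("organism", [organism])[0]
                if "haplotype" in feature.qualifiers:
                    claim = _strip_punct(feature.qualifiers["haplotype"][0])
                break
        if claim is None:
            claim = _claim_from_definition(rec.description)
        records.append(
            SequenceRecord(
                accession=rec.id,
                definition=rec.description,
                organism=organism,
                sequence=str(rec.seq),
                annotated_haplotype=claim,
            )
        )
    return records


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Parse a FASTA file; ``haplotype=<name>`` in the header is honoured."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise IngestError(f"{path}: empty sequence for record {rec.id!r}")
        claim = None
        m = _HEADER_HAPLO_RE.search(rec.description)
        if m:
            claim = _strip_punct(m.group(1))
        records.append(
            SequenceRecord(
                accession=rec.id,
                definition=rec.description,
                organism="",
                sequence=str(rec.seq),
                annotated_haplotype=claim,
            )
        )
    return records


def partition_by_species(
    records: Iterable[SequenceRecord], allowed_prefix: str = "Canis lupus"
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Split records into (kept, excluded-organism counts).

    A record is kept when its organism is exactly the allowed species or a
    trinomial beneath it (whole-word prefix match), so ``Canis lupus
    familiaris`` stays and ``Canis lupus`` itself stays, but ``Canis
    lupaster`` or ``Vulpes vulpes`` do not.
    """
    kept: list[SequenceRecord] = []
    excluded: dict[str, int] = {}
    for rec in records:
        org = rec.organism.strip()
        if org == allowed_prefix or org.startswith(allowed_prefix + " "):
            kept.append(rec)
        else:
            excluded[org] = excluded.get(org, 0) + 1
    return kept, excluded


def species_filter(
    records: Iterable[SequenceRecord], allowed_prefix: str = "Canis lupus"
) -> list[SequenceRecord]:
    """Keep only records from the allowed species or its subspecies."""
    kept, _ = partition_by_species(records, allowed_prefix)
    return kept
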