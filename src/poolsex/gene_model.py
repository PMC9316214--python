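"""Exon/intron gene-model arithmetic and validation, CDS translation, and
primer-amplicon coordinates.

Size bookkeeping follows the usual conventions: genomic size is the sum of
all segment sizes, transcript size the sum of exon sizes.  When segment
sequences are available the canonical splice signals (introns start ``gt``,
end ``ag``) and the open reading frame (ATG start, in-frame {TAA, TAG, TGA}
stop) are checked.  Validation reports violations rather than rejecting the
model, so genuinely noncanonical structures remain inspectable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "GeneSegment",
    "GeneModel",
    "Amplicon",
    "StructureError",
    "OrfError",
    "build_gene_model",
    "translate_cds",
    "amplicon_from_primers",
    "load_segments_tsv",
    "load_amplicon_table",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


class StructureError(ValueError):
    """Segment list violates the alternating exon/intron structure."""


class OrfError(ValueError):
    """No valid open reading frame where one was required."""


@dataclass(frozen=True)
class GeneSegment:
    """One exon or intron: kind, 1-based ordinal within its kind, size, optional sequence."""

    kind: str  # "exon" | "intron"
    ordinal: int
    size: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"segment kind must be exon or intron, got {self.kind!r}")
        if self.size < 1:
            raise ValueError(f"segment size must be >= 1, got {self.size}")
        if self.sequence is not None and len(self.sequence) != self.size:
            raise ValueError(
                f"{self.kind} {self.ordinal}: sequence length "
                f"{len(self.sequence)} != declared size {self.size}"
            )


@dataclass
class GeneModel:
    segments: tuple[GeneSegment, ...]
    genomic_size: int
    transcript_size: int
    transcript: Optional[str] = None
    cds: Optional[str] = None
    protein: Optional[str] = None
    violations: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    @property
    def exons(self) -> tuple[GeneSegment, ...]:
        return tuple(s for s in self.segments if s.kind == "exon")

    @property
    def introns(self) -> tuple[GeneSegment, ...]:
        return tuple(s for s in self.segments if s.kind == "intron")


def build_gene_model(segments: Sequence[GeneSegment]) -> GeneModel:
    """Aggregate sizes and validate structure, splice signals and the ORF.

    Segments must alternate exon/intron, starting and ending with an exon
    (a single exon with no introns is fine).  Splice and codon checks run
    only where sequences are present; each violation is recorded on the
    returned model instead of raising.
    """
    if not segments:
        raise StructureError("gene model needs at least one exon")
    for i, seg in enumerate(segments):
        expect = "exon" if i % 2 == 0 else "intron"
        if seg.kind != expect:
            raise StructureError(
                f"segment {i + 1} should be an {expect} in an alternating "
                f"exon/intron model, got {seg.kind}"
            )
    if segments[-1].kind != "exon":
        raise StructureError("gene model must end with an exon")

    model = GeneModel(
        segments=tuple(segments),
        genomic_size=sum(s.size for s in segments),
        transcript_size=sum(s.size for s in segments if s.kind == "exon"),
    )

    for seg in model.introns:
        if seg.sequence is None:
            continue
        seq = seg.sequence.lower()
        if not seq.startswith("gt"):
            model.violations.append(
                f"intron {seg.ordinal}: donor site {seq[:2]!r} is not the canonical 'gt'"
            )
        if not seq.endswith("ag"):
            model.violations.append(
                f"intron {seg.ordinal}: acceptor site {seq[-2:]!r} is not the canonical 'ag'"
            )

    if all(s.sequence is not None for s in model.exons):
        transcript = "".join(s.sequence for s in model.exons).upper()
        model.transcript = transcript
        start = transcript.find("ATG")
        if start < 0:
            model.violations.append("transcript has no ATG initiation codon")
        else:
            try:
                model.protein, cds_len = translate_cds(transcript, start)
                model.cds = transcript[start : start + cds_len]
            except OrfError as exc:
                model.violations.append(str(exc))
    return model


def translate_cds(transcript: str, start_offset: int) -> tuple[str, int]:
    """Translate from the ATG at ``start_offset`` to the first in-frame stop.

    Returns ``(protein, cds_length)``; the stop codon is counted in the CDS
    length but excluded from the protein.  Standard genetic code.
    """
    transcript = transcript.upper()
    if transcript[start_offset : start_offset + 3] != "ATG":
        raise ValueError(
            f"no ATG at offset {start_offset} "
            f"(found {transcript[start_offset:start_offset + 3]!r})"
        )
    for i in range(start_offset, len(transcript) - 2, 3):
        if transcript[i : i + 3] in STOP_CODONS:
            cds = transcript[start_offset : i + 3]
            protein = str(Seq(cds[:-3]).translate())
            return protein, len(cds)
    raise OrfError(f"no in-frame stop codon downstream of offset {start_offset}")


@dataclass(frozen=True)
class Amplicon:
    """A PCR product located on a template by 1-based inclusive coordinates."""

    marker: str
    template: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"amplicon start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"amplicon {self.marker}: end {self.end} < start {self.start}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def amplicon_from_primers(template: str, start: int, end: int, marker: str) -> Amplicon:
    """Build an amplicon from primer-bounded coordinates; size = end - start + 1."""
    return Amplicon(marker=marker, template=template, start=start, end=end)


def load_segments_tsv(path: str | Path) -> list[GeneSegment]:
    """Read a segment table TSV: kind, ordinal, size[, sequence]."""
    out: list[GeneSegment] = []
    with Path(path).open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "kind":
                continue
            kind, ordinal, size = row[:3]
            seq = row[3] if len(row) > 3 and row[3] else None
            out.append(GeneSegment(kind, int(ordinal), int(size), seq))
    return out


def load_amplicon_table(path: str | Path) -> list[tuple[Amplicon, Optional[int]]]:
    """Read a marker coordinate TSV (marker, template, start, end[, printed size]).

    Returns each recomputed :class:`Amplicon` with the table's printed size
    (if any) so callers can cross-check the arithmetic.
    """
    out = []
    with Path(path).open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0].lower() == "marker":
                continue
            marker, template, start, end = row[:4]
            printed = int(row[4].replace(",", "")) if len(row) > 4 and row[4] else None
            amp = amplicon_from_primers(
                template, int(start.replace(",", "")), int(end.replace(",", "")), marker
            )
            out.append((amp, printed))
    return out
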