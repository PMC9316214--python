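"""Electronic PCR: probe detection in read libraries by exact shared words.

A read "hits" a probe when the two share at least one exact word of a fixed
length (default 64) on either strand — a deterministic proxy for BLASTN
seeding at high identity.  Presence/absence is called at a minimum read
count (default 3), and expression is summarised as RPKM
(hits x 10^9 / (library reads x probe length)).  The duplex genotype call
combines an X-form and a Y-form probe to type a library as xx, xy, "yy?" or
a failed assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "Probe",
    "ReadLibrary",
    "EpcrReport",
    "probe_hits",
    "epcr_report",
    "duplex_genotype",
    "read_fasta_library",
    "read_probes_fasta",
    "WORD_SIZE_DEFAULT",
    "MIN_READS_DEFAULT",
]

WORD_SIZE_DEFAULT = 64
MIN_READS_DEFAULT = 3


@dataclass(frozen=True)
class Probe:
    """A nucleotide probe; the sequence is upper-cased and must be plain ACGT."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"probe {self.id} contains non-ACGT symbols {sorted(bad)}")
        if not self.sequence:
            raise ValueError(f"probe {self.id} is empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def words(self, word_size: int) -> frozenset[str]:
        """All exact words of ``word_size`` on both strands of the probe."""
        if word_size < 8:
            raise ValueError(f"word size must be >= 8, got {word_size}")
        if len(self) < word_size:
            raise ValueError(
                f"probe {self.id} ({len(self)} bp) shorter than word size {word_size}"
            )
        seqs = (self.sequence, reverse_complement(self.sequence))
        return frozenset(
            s[i : i + word_size] for s in seqs for i in range(len(s) - word_size + 1)
        )


@dataclass
class ReadLibrary:
    """A collection of reads; ``total_reads`` may be declared externally
    (e.g. the depositor's library size) and defaults to the number supplied."""

    id: str
    reads: list[str]
    total_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if self.total_reads is None:
            self.total_reads = len(self.reads)


@dataclass(frozen=True)
class EpcrReport:
    probe_id: str
    library_id: str
    hit_count: int
    detected: bool
    rpkm: Optional[float]


def probe_hits(probe: Probe, library: ReadLibrary, word_size: int = WORD_SIZE_DEFAULT) -> int:
    """Count reads sharing >= 1 exact ``word_size``-mer with the probe, either strand.

    Each read counts at most once.  Ambiguity codes in reads never match
    (probe words are strictly ACGT).
    """
    words = probe.words(word_size)
    hits = 0
    for read in library.reads:
        seq = read.upper()
        n = len(seq) - word_size + 1
        for i in range(n):
            if seq[i : i + word_size] in words:
                hits += 1
                break
    return hits


def epcr_report(
    probe: Probe,
    library: ReadLibrary,
    word_size: int = WORD_SIZE_DEFAULT,
    min_reads: int = MIN_READS_DEFAULT,
) -> EpcrReport:
    """Run probe detection and summarise as an :class:`EpcrReport`.

    RPKM = hits x 10^9 / (total_reads x probe_length_bp); undefined (None)
    for an empty library.
    """
    hits = probe_hits(probe, library, word_size)
    if library.total_reads == 0:
        if hits:
            raise ValueError(
                f"library {library.id} declares 0 total reads but has {hits} hits"
            )
        rpkm = None
    else:
        rpkm = hits * 1e9 / (library.total_reads * len(probe))
    return EpcrReport(
        probe_id=probe.id,
        library_id=library.id,
        hit_count=hits,
        detected=hits >= min_reads,
        rpkm=rpkm,
    )


def duplex_genotype(x_report: EpcrReport, y_report: EpcrReport) -> str:
    """Combine X-form and Y-form probe reports into a duplex genotype call.

    ``xx`` — only the X form detected; ``xy`` — both; ``yy?`` — only the Y
    form (the assay cannot distinguish yy from a failed X reaction, hence the
    query); ``fail`` — neither.
    """
    if x_report.library_id != y_report.library_id:
        raise ValueError(
            f"duplex reports are for different libraries: "
            f"{x_report.library_id} vs {y_report.library_id}"
        )
    if x_report.detected and y_report.detected:
        return "xy"
    if x_report.detected:
        return "xx"
    if y_report.detected:
        return "yy?"
    return "fail"


def read_fasta_library(path: str | Path, library_id: str | None = None) -> ReadLibrary:
    """Load reads from FASTA or FASTQ (format inferred from extension; .gz accepted)."""
    path = Path(path)
    name = path.name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    import gzip

    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        reads = [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]
    return ReadLibrary(id=library_id or path.stem, reads=reads)


def read_probes_fasta(path: str | Path) -> list[Probe]:
    return [Probe(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_epcr_tsv(reports: Iterable[EpcrReport], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("probe\tlibrary\thits\tdetected\trpkm\n")
        for r in reports:
            rpkm = "" if r.rpkm is None else f"{r.rpkm:.4g}"
            fh.write(
                f"{r.probe_id}\t{r.library_id}\t{r.hit_count}\t"
                f"{'yes' if r.detected else 'no'}\t{rpkm}\n"
            )
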