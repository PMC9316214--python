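"""Multi-sample VCF input, study-design bookkeeping and TSV report output.

Pooled-sex sequencing genotypes each pool (all females or all males of one
species) as a single diploid sample.  This module maps VCF sample names onto
(species, sex) roles and yields one :class:`VariantRecord` per site inside the
analysis window, normalising phased/unphased genotype separators and missing
calls.  All coordinates in public contracts are 1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam
import yaml

__all__ = [
    "ConfigurationError",
    "VcfParseError",
    "GenomicWindow",
    "PoolCall",
    "NULL_CALL",
    "VariantRecord",
    "SpeciesPair",
    "StudyDesign",
    "read_vcf",
    "write_results_tsv",
    "load_run_config",
    "DEFAULT_WINDOW",
]


class ConfigurationError(ValueError):
    """The study design or run configuration is inconsistent with the data."""


class VcfParseError(ValueError):
    """A VCF record could not be interpreted under the pipeline's contracts."""


@dataclass(frozen=True)
class GenomicWindow:
    """A 1-based inclusive genomic interval on one sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"window start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"window end {self.end} < start {self.start}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Critical sex-determination interval on LG1 of the O. aureus assembly,
#: orthologous by synteny to the 24-27 Mbp O. niloticus region.
DEFAULT_WINDOW = GenomicWindow("LG1", 25_400_000, 28_700_000)


@dataclass(frozen=True)
class PoolCall:
    """A diploid genotype call for one pool: two allele indices or a null call.

    Index 0 is the reference allele; indices >= 1 address the ALT list in
    order.  A null call ("./.") has both alleles ``None`` and models absence
    of read support, interpreted downstream as a locus missing from one sex
    chromosome.
    """

    allele_a: Optional[int]
    allele_b: Optional[int]

    def __post_init__(self) -> None:
        nulls = (self.allele_a is None) + (self.allele_b is None)
        if nulls == 1:
            raise ValueError("half-null genotype: both alleles must be null or neither")
        if nulls == 0 and (self.allele_a < 0 or self.allele_b < 0):
            raise ValueError("allele indices must be >= 0")

    @property
    def is_null(self) -> bool:
        return self.allele_a is None

    @property
    def is_hom(self) -> bool:
        """Both alleles identical and called; allele-agnostic (0/0, 1/1, 2/2...)."""
        return not self.is_null and self.allele_a == self.allele_b

    @property
    def is_het(self) -> bool:
        return not self.is_null and self.allele_a != self.allele_b

    def indices(self) -> tuple[int, int]:
        if self.is_null:
            raise ValueError("null call has no allele indices")
        return (self.allele_a, self.allele_b)

    def __str__(self) -> str:
        if self.is_null:
            return "./."
        return f"{self.allele_a}/{self.allele_b}"

    @classmethod
    def from_string(cls, text: str) -> "PoolCall":
        """Parse ``0/1``, ``0|1`` or ``./.``; phase separators are equivalent."""
        norm = text.replace("|", "/").strip()
        if norm in {"./.", ".", ".|."}:
            return NULL_CALL
        parts = norm.split("/")
        if len(parts) != 2:
            raise VcfParseError(f"expected a diploid genotype, got {text!r}")
        try:
            return cls(int(parts[0]), int(parts[1]))
        except ValueError as exc:
            raise VcfParseError(f"unparseable genotype {text!r}") from exc


NULL_CALL = PoolCall(None, None)


@dataclass
class VariantRecord:
    """One VCF site with a per-pool diploid call for every pool in the design.

    ``alts`` may include the spanning-deletion symbol ``*``, which is treated
    as an ordinary allele.  Sites with no ALT (".") carry an empty tuple and
    are classified as fitting no sex model downstream.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    calls: dict[str, PoolCall]

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("REF allele must be non-empty")
        if len(set(self.alts)) != len(self.alts):
            raise ValueError(f"duplicate ALT alleles at {self.chrom}:{self.pos}")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def allele_seq(self, index: int) -> str:
        """Resolve an allele index to its sequence (0 = REF)."""
        if index == 0:
            return self.ref
        if 1 <= index <= len(self.alts):
            return self.alts[index - 1]
        raise IndexError(
            f"allele index {index} out of range at {self.chrom}:{self.pos} "
            f"({self.n_alleles} alleles)"
        )

    def call_valid(self, call: PoolCall) -> bool:
        return call.is_null or all(0 <= i < self.n_alleles for i in call.indices())


@dataclass(frozen=True)
class SpeciesPair:
    """One species' female and male pool labels."""

    species: str
    female_pool: str
    male_pool: str


@dataclass(frozen=True)
class StudyDesign:
    """The pooled study layout: one (female, male) pool pair per species."""

    species_pairs: tuple[SpeciesPair, ...]

    def __post_init__(self) -> None:
        if not self.species_pairs:
            raise ConfigurationError("study design needs at least one species pair")
        labels = list(self.pool_labels)
        if len(set(labels)) != len(labels):
            raise ConfigurationError("pool labels must be unique across the design")

    @property
    def pool_labels(self) -> tuple[str, ...]:
        out: list[str] = []
        for pair in self.species_pairs:
            out.extend((pair.female_pool, pair.male_pool))
        return tuple(out)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(p.species for p in self.species_pairs)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[str]]) -> "StudyDesign":
        return cls(tuple(SpeciesPair(*p) for p in pairs))


def _pool_call_from_gt(gt: Optional[tuple], where: str) -> PoolCall:
    if gt is None:
        return NULL_CALL
    alleles = tuple(a for a in gt)
    if all(a is None for a in alleles):
        return NULL_CALL
    if len(alleles) != 2 or any(a is None for a in alleles):
        raise VcfParseError(
            f"pools are genotyped as single diploid samples; got ploidy "
            f"{len(alleles)} call {alleles} at {where}"
        )
    return PoolCall(alleles[0], alleles[1])


def read_vcf(
    path: str | Path,
    design: StudyDesign,
    window: GenomicWindow,
    *,
    pass_only: bool = False,
) -> Iterator[VariantRecord]:
    """Stream window-restricted variant records from a VCF v4.x file.

    Every yielded record carries exactly one :class:`PoolCall` per design pool
    label; pools with no GT or "./." become null calls.  FILTER and QUAL are
    ignored unless ``pass_only`` is set (then only PASS/unfiltered records are
    yielded).

    Raises
    ------
    ConfigurationError
        If a design pool label is absent from the VCF header.
    VcfParseError
        On records violating the diploid-pool contract.
    """
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = set(vcf.header.samples)
        missing = [lbl for lbl in design.pool_labels if lbl not in header_samples]
        if missing:
            raise ConfigurationError(
                f"pool label(s) {missing} not found in VCF header of {path} "
                f"(header has {sorted(header_samples)})"
            )
        for rec in vcf:
            if rec.chrom != window.chrom:
                continue
            if not (window.start <= rec.pos <= window.end):
                continue
            if pass_only and rec.filter.keys() not in ([], ["PASS"]):
                continue
            where = f"{rec.chrom}:{rec.pos} in {path}"
            calls = {}
            for label in design.pool_labels:
                sample = rec.samples[label]
                calls[label] = _pool_call_from_gt(sample.get("GT"), where)
            alts = tuple(a for a in (rec.alts or ()) if a != ".")
            record = VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=alts, calls=calls
            )
            for label, call in record.calls.items():
                if not record.call_valid(call):
                    raise VcfParseError(
                        f"genotype {call} of pool {label} addresses a missing "
                        f"allele at {where}"
                    )
            yield record


def write_results_tsv(results, path: str | Path, design: StudyDesign) -> None:
    """Write concordance results as a TSV mirroring the published report layout.

    Columns: Position, REF, ALT, one F and M genotype column per species,
    Model, Conserved, Region, 5' End, 3' End.  Deterministic column order
    (design order).
    """
    path = Path(path)
    header = ["Position", "REF", "ALT"]
    for pair in design.species_pairs:
        header.extend([f"{pair.species}_F", f"{pair.species}_M"])
    header.extend(["Model", "Conserved", "Region", "5_End", "3_End"])
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for res in results:
            site = res.site
            row = [str(site.pos), site.ref, ", ".join(site.alts)]
            for pair in design.species_pairs:
                row.append(str(site.calls[pair.female_pool]))
                row.append(str(site.calls[pair.male_pool]))
            model = res.concordant_model.name if res.concordant_model else "NONE"
            row.extend(
                [
                    model,
                    "yes" if res.male_alleles_conserved else "no",
                    res.region_label,
                    res.flank_5 or "",
                    res.flank_3 or "",
                ]
            )
            writer.writerow(row)


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration holding the study design, window and thresholds.

    Expected keys: ``species_pairs`` (list of [species, female_pool,
    male_pool]), optional ``window`` ({chrom, start, end}; defaults to the
    LG1 25.4-28.7 Mbp interval) and optional threshold overrides.
    """
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if "species_pairs" not in raw:
        raise ConfigurationError(f"config {path} lacks 'species_pairs'")
    design = StudyDesign.from_pairs(raw["species_pairs"])
    if "window" in raw:
        w = raw["window"]
        window = GenomicWindow(str(w["chrom"]), int(w["start"]), int(w["end"]))
    else:
        window = DEFAULT_WINDOW
    out = {k: v for k, v in raw.items() if k not in {"species_pairs", "window"}}
    out["design"] = design
    out["window"] = window
    return out
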