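"""Cross-species XX/XY genotype-model classification of pooled variant calls.

A male-heterogametic (XY) sex-determination locus leaves one of three
footprints in pooled female/male genotypes:

* ``Y_ALLELE`` — the Y carries a different allele than the X: females are
  homozygous, males heterozygous;
* ``X_NULL``   — the locus is absent from the X: females yield a null call
  (no reads), males a homozygous call;
* ``Y_NULL``   — the locus is absent from the Y: males are homozygous,
  females heterozygous.

A site is *concordant* when the same model holds in every species of the
study design; only concordant sites survive the scan.  Male-allele
conservation is annotated by comparing allele sequences (not indices) across
species, since the same index may denote different bases in different VCFs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .vcf_io import PoolCall, StudyDesign, VariantRecord

__all__ = [
    "SexModel",
    "SpeciesFit",
    "GeneInterval",
    "ConcordanceResult",
    "classify_pair",
    "classify_site",
    "scan_window",
    "load_annotations",
]


class SexModel(enum.Enum):
    """The three pooled-genotype footprints of an XY locus."""

    Y_ALLELE = "y_allele"
    X_NULL = "x_null"
    Y_NULL = "y_null"


def classify_pair(female: PoolCall, male: PoolCall) -> Optional[SexModel]:
    """Classify one species' (female, male) pooled calls against the XY models.

    Returns ``None`` when no model's predicate holds.  The three predicates
    are mutually exclusive: Y_ALLELE and Y_NULL disagree on the female's
    zygosity, and X_NULL requires a null female call which neither other
    model permits.
    """
    if female.is_hom and male.is_het:
        return SexModel.Y_ALLELE
    if female.is_null and male.is_hom:
        return SexModel.X_NULL
    if male.is_hom and female.is_het:
        return SexModel.Y_NULL
    return None


@dataclass(frozen=True)
class SpeciesFit:
    """Per-species model fit at one site."""

    species: str
    model: Optional[SexModel]
    female_call: PoolCall
    male_call: PoolCall


@dataclass(frozen=True)
class GeneInterval:
    """A named 1-based inclusive annotation interval (gene, exon or intron)."""

    name: str
    chrom: str
    start: int
    end: int
    feature: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def label(self) -> str:
        return f"{self.name} {self.feature}".strip()


@dataclass
class ConcordanceResult:
    site: VariantRecord
    fits: tuple[SpeciesFit, ...]
    concordant_model: Optional[SexModel]
    male_alleles_conserved: bool
    region_label: str = ""
    flank_5: Optional[str] = None
    flank_3: Optional[str] = None


def _male_alleles_conserved(record: VariantRecord, design: StudyDesign) -> bool:
    """True iff the unordered pair of male allele *sequences* is identical across species."""
    pairs = []
    for sp in design.species_pairs:
        call = record.calls[sp.male_pool]
        if call.is_null:
            return False
        pairs.append(frozenset_multiset(record.allele_seq(i) for i in call.indices()))
    return len(set(pairs)) == 1


def frozenset_multiset(items: Iterable[str]) -> tuple[str, ...]:
    """Order-free, duplicate-preserving key for a small multiset."""
    return tuple(sorted(items))


def classify_site(record: VariantRecord, design: StudyDesign) -> ConcordanceResult:
    """Fit every species' call pair and derive the cross-species verdict.

    ``concordant_model`` is set iff all species fit the same non-null model.
    Sites with no ALT allele fit no model by convention (nothing segregates).
    """
    fits = []
    for sp in design.species_pairs:
        female = record.calls[sp.female_pool]
        male = record.calls[sp.male_pool]
        model = classify_pair(female, male) if record.alts else None
        fits.append(SpeciesFit(sp.species, model, female, male))
    models = {f.model for f in fits}
    concordant = models.pop() if len(models) == 1 and None not in models else None
    conserved = _male_alleles_conserved(record, design) if concordant else False
    return ConcordanceResult(
        site=record,
        fits=tuple(fits),
        concordant_model=concordant,
        male_alleles_conserved=conserved,
    )


def _annotate(result: ConcordanceResult, annotations: Sequence[GeneInterval]) -> None:
    site = result.site
    hits = [a for a in annotations if a.contains(site.chrom, site.pos)]
    if hits:
        result.region_label = hits[0].label
        return
    result.region_label = "intergenic"
    left = [a for a in annotations if a.chrom == site.chrom and a.end < site.pos]
    right = [a for a in annotations if a.chrom == site.chrom and a.start > site.pos]
    if left:
        result.flank_5 = max(left, key=lambda a: a.end).name
    if right:
        result.flank_3 = min(right, key=lambda a: a.start).name


def scan_window(
    records: Iterable[VariantRecord],
    design: StudyDesign,
    annotations: Sequence[GeneInterval] = (),
) -> tuple[list[ConcordanceResult], int]:
    """Scan position-sorted records; keep concordant sites, annotate, count all.

    Returns ``(concordant_results, total_scanned)``.  Input must be sorted by
    position (within each chromosome); unsorted input raises ``ValueError``.
    """
    results: list[ConcordanceResult] = []
    total = 0
    last: tuple[str, int] | None = None
    for record in records:
        key = (record.chrom, record.pos)
        if last is not None and key[0] == last[0] and key[1] < last[1]:
            raise ValueError(
                f"records not position-sorted: {key[0]}:{key[1]} after {last[0]}:{last[1]}"
            )
        last = key
        total += 1
        res = classify_site(record, design)
        if res.concordant_model is not None:
            _annotate(res, annotations)
            results.append(res)
    return results, total


def load_annotations(path: str | Path) -> list[GeneInterval]:
    """Read a BED-like TSV (name, chrom, start, end[, feature]) of 1-based inclusive intervals."""
    out: list[GeneInterval] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            name, chrom, start, end = fields[:4]
            feature = fields[4] if len(fields) > 4 else ""
            out.append(GeneInterval(name, chrom, int(start), int(end), feature))
    return out
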