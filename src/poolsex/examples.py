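"""Published worked-example inputs from the tilapia LG1 sex-determination study.

These are the *inputs* the pipeline is exercised on — the six cross-species
sex-concordant variant sites reported in the 25.4-28.7 Mbp LG1 interval of
the O. aureus assembly, the figla-like exon/intron sizes, the diagnostic
primer coordinates, and the family genotype-by-sex counts.  Derived
quantities (concordance verdicts, sizes, p-values) are always recomputed by
the pipeline, never stored here.
"""

from __future__ import annotations

from .concordance import GeneInterval
from .gene_model import GeneSegment
from .vcf_io import DEFAULT_WINDOW, GenomicWindow, StudyDesign

__all__ = [
    "LG1_WINDOW",
    "LG1_DESIGN",
    "CONCORDANT_SITE_ROWS",
    "LG1_ANNOTATIONS",
    "FIGLA_LIKE_SEGMENTS",
    "PRIMER_COORDINATES",
    "FAMILY_TABLES",
    "sites_as_vcf_lines",
]

LG1_WINDOW: GenomicWindow = DEFAULT_WINDOW

#: Three species segregating sex on LG1, one female and one male pool each.
#: "Sm" follows the depositors' labelling of those libraries; barcode
#: comparison later re-identified them as S. galilaeus.
LG1_DESIGN = StudyDesign.from_pairs(
    [
        ("As", "As_F", "As_M"),
        ("Sm", "Sm_F", "Sm_M"),
        ("Cz", "Cz_F", "Cz_M"),
    ]
)

#: The six sex-concordant variant sites: (pos, ref, alts, genotypes in design
#: pool order As_F, As_M, Sm_F, Sm_M, Cz_F, Cz_M).
CONCORDANT_SITE_ROWS: list[tuple[int, str, tuple[str, ...], tuple[str, ...]]] = [
    (25_672_475, "C", ("T", "G"), ("0/0", "0/1", "0/0", "0/2", "0/0", "0/1")),
    (26_488_670, "T", ("A",), ("1/1", "0/1", "1/1", "0/1", "1/1", "0/1")),
    (26_490_716, "G", ("C",), ("./.", "0/0", "./.", "1/1", "./.", "1/1")),
    (26_490_863, "C", ("T",), ("./.", "0/0", "./.", "1/1", "./.", "1/1")),
    (26_509_215, "A", ("C",), ("0/0", "0/1", "0/0", "0/1", "0/0", "0/1")),
    (26_510_329, "C", ("*", "T"), ("0/0", "0/1", "0/0", "0/2", "0/0", "0/1")),
]

#: Gene context of the region: figla-like with its exons/introns between
#: csmd1 and chs1, and the depdc7a exon carrying the non-conserved site.
#: figla-like exon/intron coordinates are anchored at the reported exon-2
#: variant position; only overlap relations (which site falls in which
#: feature) matter for annotation.
_FIGLA_START = 26_489_200
_FIGLA_SIZES = [("exon 1", 174), ("intron 1", 1290), ("exon 2", 147), ("intron 2", 122), ("exon 3", 931)]


def _figla_feature_intervals() -> list[GeneInterval]:
    out = []
    pos = _FIGLA_START
    for feature, size in _FIGLA_SIZES:
        out.append(GeneInterval("figla-like", "LG1", pos, pos + size - 1, feature))
        pos += size
    return out


LG1_ANNOTATIONS: list[GeneInterval] = [
    GeneInterval("csmd1", "LG1", 26_380_000, 26_470_000, ""),
    GeneInterval("depdc7a", "LG1", 25_672_000, 25_673_000, "exon 8"),
    *_figla_feature_intervals(),
    GeneInterval("chs1", "LG1", 26_520_000, 26_600_000, ""),
]

#: figla-like genomic organization: exon and intron sizes in gene order.
FIGLA_LIKE_SEGMENTS: list[GeneSegment] = [
    GeneSegment("exon", 1, 174),
    GeneSegment("intron", 1, 1290),
    GeneSegment("exon", 2, 147),
    GeneSegment("intron", 2, 122),
    GeneSegment("exon", 3, 931),
]

#: Diagnostic and resequencing markers: (marker, template accession, start, end).
PRIMER_COORDINATES: list[tuple[str, str, int, int]] = [
    ("LG1y", "LOC116310109", 1_520, 1_821),
    ("LG1x", "NC_031965.2", 24_979_876, 24_980_010),
    ("Reseq1", "NC_031965.2", 26_489_072, 26_490_461),
    ("Reseq2", "NC_031965.2", 26_490_237, 26_491_052),
    ("Reseq3", "ERZ9148259", 1_556, 2_526),
    ("Reseq4", "NC_031965.2", 26_490_991, 26_491_772),
]

#: Family/group genotype-by-sex counts: name -> (xy_females, xy_males,
#: xx_females, xx_males).
FAMILY_TABLES: dict[str, tuple[int, int, int, int]] = {
    "OmI_family_1": (0, 8, 7, 0),
    "OmI_family_2": (0, 8, 6, 0),
    "Sg": (0, 15, 18, 1),
    "Cz": (0, 9, 13, 0),
    "As": (0, 58, 33, 0),
    "Cs": (2, 11, 12, 0),
}


def sites_as_vcf_lines(design: StudyDesign = LG1_DESIGN) -> list[str]:
    """Render the six concordant sites as VCF data lines in design pool order."""
    lines = []
    for pos, ref, alts, gts in CONCORDANT_SITE_ROWS:
        fields = ["LG1", str(pos), ".", ref, ",".join(alts), ".", ".", ".", "GT", *gts]
        lines.append("\t".join(fields))
    return lines
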