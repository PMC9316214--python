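"""Shared fixtures: the published LG1 worked example rendered as files, and
small synthetic configurations."""

from __future__ import annotations

import pytest

from poolsex.examples import (
    CONCORDANT_SITE_ROWS,
    LG1_DESIGN,
    LG1_WINDOW,
    sites_as_vcf_lines,
)
from poolsex.vcf_io import PoolCall, VariantRecord


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=LG1,length=40000000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    + "\t".join(LG1_DESIGN.pool_labels)
    + "\n"
)

#: Decoy lines inside the window: same genotype in both sexes of every
#: species, so no XY model can fire.
DECOY_POSITIONS = [25_500_000 + 10_000 * i for i in range(12)]


def _decoy_line(pos: int) -> str:
    gts = ["0/1"] * 6  # het in both sexes everywhere -> fits no model
    return "\t".join(["LG1", str(pos), ".", "A", "G", ".", ".", ".", "GT", *gts])


@pytest.fixture
def published_records() -> list[VariantRecord]:
    """The six sex-concordant sites as in-memory records."""
    recs = []
    for pos, ref, alts, gts in CONCORDANT_SITE_ROWS:
        calls = {
            label: PoolCall.from_string(gt)
            for label, gt in zip(LG1_DESIGN.pool_labels, gts)
        }
        recs.append(VariantRecord("LG1", pos, ref, alts, calls))
    return recs


@pytest.fixture
def worked_example_vcf(tmp_path):
    """VCF file holding the six published sites plus 12 in-window decoys,
    one out-of-window record, and one phased genotype variant."""
    lines = [_decoy_line(p) for p in DECOY_POSITIONS] + sites_as_vcf_lines()
    lines.sort(key=lambda l: int(l.split("\t")[1]))
    outside = "\t".join(
        ["LG1", "25000000", ".", "A", "C", ".", ".", ".", "GT"] + ["0/0", "0/1"] * 3
    )
    path = tmp_path / "example.vcf"
    path.write_text(VCF_HEADER + outside + "\n" + "\n".join(lines) + "\n")
    return path


@pytest.fixture
def design():
    return LG1_DESIGN


@pytest.fixture
def window():
    return LG1_WINDOW
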