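# poolsex

Sex-determination locus discovery from pooled-sex whole-genome sequencing.

Tilapia and other cichlids segregate sex at several chromosomal loci; on
linkage group 1 (LG1) the male-determining factor is a male-specific
*figla-like* gene, present on the y haplotype and absent from x.  `poolsex`
is a reusable implementation of the discovery analysis behind that finding:
it takes multi-sample VCFs in which each pooled-sex library (all females or
all males of one species) is genotyped as a single diploid sample, and
narrows tens of thousands of variants down to the handful that behave like
a male-heterogametic (xx/xy) locus in *every* species examined.

## The method

For each variant site and each species, the female/male pooled genotype
pair is tested against three XY-system models:

* **Y-allele** — the Y carries a different allele than the X: females
  homozygous, males heterozygous (F `0/0`, M `0/1`);
* **X-null** — the locus is missing from the X chromosome: females yield a
  null call `./.` (no aligned reads), males a homozygous call;
* **Y-null** — the locus is missing from the Y: males homozygous, females
  heterozygous.

A site is retained only when the *same* model holds in every species
(cross-species concordance), which is the filter that reduces a ~3 Mbp
window with tens of thousands of variants to a handful of candidates.
Around that core the package implements the supporting analyses:

* `presence_absence` — male-specific intervals from per-pool depth tracks
  (positions with zero female coverage and solid male coverage);
* `epcr` — electronic PCR: counting reads that share an exact 64-bp word
  with a probe, presence/absence at a ≥3-read threshold, and RPKM;
* `gene_model` — exon/intron size arithmetic, gt/ag splice-site and
  start/stop-codon validation, CDS translation, and primer-amplicon sizes;
* `association` — genotype-by-sex 2×2 tables and the two-sided Fisher
  exact test;
* `barcode` — cox1 p-distances against the ~1% interspecies floor, with
  misidentification flags;
* `synthetic` — seeded generators for every input, with exact truth sets.

## Worked example

The six cross-species sex-concordant sites of the LG1 study, scanned from a
VCF together with decoy variants:

```python
from poolsex.examples import LG1_DESIGN, LG1_ANNOTATIONS, CONCORDANT_SITE_ROWS
from poolsex.vcf_io import PoolCall, VariantRecord
from poolsex.concordance import scan_window

records = [
    VariantRecord("LG1", pos, ref, alts,
                  {lbl: PoolCall.from_string(gt)
                   for lbl, gt in zip(LG1_DESIGN.pool_labels, gts)})
    for pos, ref, alts, gts in CONCORDANT_SITE_ROWS
]
results, total = scan_window(records, LG1_DESIGN, LG1_ANNOTATIONS)
for r in results:
    print(r.site.pos, r.concordant_model.name, r.male_alleles_conserved,
          r.region_label)
```

prints

```
25672475 Y_ALLELE False depdc7a exon 8
26488670 Y_ALLELE True intergenic
26490716 X_NULL False figla-like exon 2
26490863 X_NULL False figla-like intron 2
26509215 Y_ALLELE True intergenic
26510329 Y_ALLELE False intergenic
```

— four Y-allele sites and the two X-null sites that fall inside
*figla-like* itself, pointing at a gene present only on the male
haplotype.  The tri-allelic coding site at 25,672,475 is concordant but its
male alleles differ between species (`False`), so it is annotated as
non-conserved rather than filtered out.  The association side reproduces
the family tests: 8 xy males against 7 xx females gives the exact two-sided
Fisher p = 1/6435 ≈ 0.0002, and the exon/intron sizes 174/1290/147/122/931
give the 2664 bp gene and its 1252 bp transcript.

A command-line interface mirrors the library (`poolsex scan`,
`null-region`, `epcr`, `gene-model`, `amplicon`, `assoc`, `barcode`,
`simulate`); run `poolsex --help` for the defaults.

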