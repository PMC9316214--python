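# Methods

## Model and assumptions

The pipeline targets male-heterogametic (XX/XY-type) sex determination
mapped with pooled-sex sequencing: for each species, one library of pooled
females and one of pooled males, each genotyped as a *single diploid
sample*.  That convention is what makes the three genotype models sharp.
With many individuals pooled, a Y-linked allele appears in the male pool as
a heterozygous call (the pool carries both X- and Y-haplotype reads), while
the female pool is homozygous; a locus deleted from the X yields no female
reads at all (a `./.` null call) and a homozygous male call; a locus
deleted from the Y is the mirror case.  Classification is purely
qualitative — null / homozygous / heterozygous — so it assumes the
genotyper collapses each pool to one diploid call.  Allele-frequency
modelling of pools is deliberately out of scope.

Homozygosity is allele-agnostic: `0/0`, `1/1` and `2/2` all count, because
the same biological allele can receive different indices in different
species' VCFs (the X-null sites in the worked example are `0/0` in one
species and `1/1` in the others).  For the same reason, male-allele
conservation across species is computed on allele *sequences*, never
indices, and is an annotation rather than a filter: a concordant site with
non-conserved male alleles stays in the report, flagged.

Concordance demands the *same* model in every species of the design.  A
site fitting Y-allele in one species and X-null in another is rejected;
this is the cross-species conservation assumption that gives the filter
its power (in the motivating study it reduced 66,372 variants to six).
Consequences: a species with a locally mis-genotyped pool vetoes a true
site, and the filter's specificity grows with the number of species.

## Coordinates and formats

All public coordinates are 1-based inclusive (VCF/GenBank convention); no
half-open interval appears in any contract.  VCF parsing is delegated to
pysam; `/` and `|` genotype separators are equivalent, FILTER/QUAL are
ignored by default (an optional pass-only flag exists) since the
discovery analysis filters on genotype patterns, not call quality.
Non-diploid GT fields are rejected rather than coerced.  The
spanning-deletion ALT `*` is an ordinary allele.  Sites with ALT `.`
classify as fitting no model.  Malformed records surface as errors carrying
the record's chromosome and position (pysam does not expose file line
numbers).  Depth input is a 4-column BED-like TSV declared 1-based
inclusive; annotation tables likewise.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| analysis window | LG1 25,400,000–28,700,000 | bp | the critical sex region on the *O. aureus* assembly, syntenic to the 24–27 Mbp interval of the *O. niloticus* map |
| `female_ceiling` | 0 | reads | "no aligned reads in females" taken literally |
| `male_floor` | 3 | reads | mirrors the ≥3-read electronic-PCR detection limit |
| `min_length` | 200 | bp | suppresses short stochastic zero-coverage runs; no published value exists, so it is configurable |
| `merge_gap` | 100 | bp | bridges sub-read-length coverage dropouts |
| e-PCR `word_size` | 64 | bp | the BLASTN word size used for library screening |
| e-PCR `min_reads` | 3 | reads | the published genomic-library detection threshold |
| barcode threshold | 1.0 | % | conventional minimal interspecies cox1 divergence |
| Fisher tie tolerance | 1e-7 | relative | guards float equality when accumulating equally extreme tables |

## Numerical and procedural choices

**Fisher exact test.** Two-sided p by the probability-mass criterion: sum
the hypergeometric probabilities of all tables sharing the observed
margins whose probability is ≤ the observed one (× (1+1e-7)).  Computed by
direct enumeration with log-factorial (`lgamma`) arithmetic — the support
of a 2×2 margin set is tiny, so enumeration is exact and fast.  Tests
cross-check against an integer-binomial enumerator (exact ties) and
`scipy.stats.fisher_exact`.  Reported values keep full precision; rounding
to 4 decimals happens only at report formatting.  Note that for two of the
published family tables (15 xy males vs 18 xx+1 discordant, and the
hybrid-strain family), exact enumeration yields p ≈ 8.6e-9 and 2.0e-5,
far below the printed 0.0001 — those displays appear to be a package floor
in the original analysis, so only the two fully concordant families are
used as worked examples.

**Electronic PCR.** A "hit" is a read sharing at least one exact
`word_size`-mer with the probe on either strand, each read counted once —
a deterministic proxy for BLASTN seeding at >99% identity, without
extension or scoring.  Ambiguity codes never match (probe words are
strictly ACGT).  RPKM is hits × 10⁹ / (total_reads × probe_length_bp); the
denominator uses total supplied (or declared) library reads, since whether
the original analysis used total or mapped reads is not stated.  The
duplex genotype labels a library `yy?` when only the Y-form probe
amplifies, because a diploid assay cannot distinguish yy from xy with a
failed X reaction.

**Gene models.** Validation reports violations instead of rejecting:
noncanonical introns (not `gt`...`ag`), missing ATG, or no in-frame stop
are collected on the model so real noncanonical structures can be
examined.  The stop-codon set is {TAA, TAG, TGA}; translation uses the
standard code and excludes the stop from the protein.  Case encodes
feature in sequence I/O (lowercase introns), with the segment table
authoritative over case.

**Male-specific intervals.** Interval statistics (min male depth, max
female depth) are computed over the full merged interval, including
bridged gaps, so the numbers describe what is reported.  Lowering the
female ceiling or raising the male floor can only shrink the marked set
(monotonicity, property-tested).

**Barcodes.** Uncorrected p-distance on comparable columns only — both
bases unambiguous A/C/G/T; gap or ambiguity columns leave numerator *and*
denominator.  No Jukes–Cantor correction, matching how raw percent
differences are reported in practice.  Misidentification flags compare the
barcode call with the declared species relation in both directions:
declared-different but conspecific (mislabel candidate) and declared-same
but divergent (cryptic split).

## The synthetic generators

The generators emit every input the pipeline consumes, with exact truth:

* **VCF**: defaults plant 4 Y-allele + 2 X-null sites among 500 decoys in
  the LG1 window across 3 species — the condition the discovery scan faced
  in miniature.  Decoy genotypes are drawn from classes non-concordant *by
  construction* (monomorphic, heterozygous-in-both-sexes, or
  discordant-across-species), and every planted/decoy site is re-checked
  through the classifier at generation time, so recovery tests are exact,
  not probabilistic.
* **Depth tracks**: a 2664 bp zero-female interval (the *figla-like* gene
  size) with constant male depth 30 inside, Poisson(20)/Poisson(30)
  female/male background elsewhere.  Female background is clamped to ≥ 1
  outside the interval so the planted boundaries are deterministic truth.
  Tracks cover a 100 kb subwindow around the interval; dense per-bp arrays
  over the full 3.3 Mbp would add cost without adding signal.
* **Reads**: the probe (147 bp by default, the published exon-2 probe
  length) is planted verbatim, forward or reverse-complement, into a known
  number of 150 bp reads; background reads are rejection-sampled to share
  no word with the probe, making the planted count the exact expected hit
  count.
* **Families and barcodes**: genotype/sex tables matching target 2×2
  counts exactly (including discordant xy females), and 650 bp aligned
  barcode pairs with planted mismatch counts.

All randomness flows through one seeded numpy generator per config; equal
configs give byte-identical outputs.

What the generators do *not* emulate: sequencing error, base qualities,
read-depth autocorrelation, alignment artefacts at repeats, or real
coalescent structure between species.  Passing the synthetic suite
therefore demonstrates the *logic* of the pipeline — the filters implement
their definitions exactly and recover planted truth — not robustness to
noisy genotyping, which in the real analysis is absorbed upstream by the
variant caller.

## Problem sizes

Default test and reproduction scales: 506-site windows × 20 seeds for
recovery, 100 kb depth windows, 200–1000-read libraries, 650 bp barcodes —
small enough to run in seconds while exercising every code path at the
study's structural scale (3 species × 2 pools, six planted sites, 2664 bp
interval).

## Known limitations

* Pool genotypes are consumed as-is; there is no modelling of pool allele
  frequencies, so low-coverage pools that miscall heterozygosity degrade
  the filter upstream of this package.
* The window is a configuration constant; no synteny liftover between
  assemblies is performed.
* e-PCR has no gapped alignment or E-values; probes must be high-identity.
* Barcode input must be pre-aligned; length mismatches are errors, not
  auto-trimmed.
* Quantities tied to the original raw data (the 66,372 pre-filter variant
  count, 86-fold transcript coverage, RPKM 7.6, inter-library barcode
  percentages) require the SRA libraries and are documented but not
  reproduced; the corresponding mechanisms are exercised on planted
  synthetic data instead.
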