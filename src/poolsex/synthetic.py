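"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator emulates the structure the analysis assumes — pooled-sex VCF
genotypes with variant sites planted under the three XY models plus
provably non-concordant decoys, depth tracks with a zero-female-coverage
interval, read libraries with probe copies planted at known counts, family
genotype/sex tables, and aligned barcode pairs with planted divergences —
and returns a :class:`TruthSet` describing exactly what was planted, so
recovery tests are exact rather than probabilistic.

All randomness flows through one ``numpy`` generator derived from the
config seed; identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .association import IndividualCall
from .barcode import AlignedBarcodePair
from .concordance import SexModel, classify_site
from .epcr import Probe, ReadLibrary
from .presence_absence import DepthTrack
from .vcf_io import (
    DEFAULT_WINDOW,
    GenomicWindow,
    NULL_CALL,
    PoolCall,
    StudyDesign,
    VariantRecord,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "GenerationError",
    "generate_vcf",
    "generate_depth_tracks",
    "generate_reads",
    "generate_family",
    "generate_barcode_pairs",
    "simulate_all",
    "random_orf_transcript",
]

_BASES = "ACGT"

DECOY_CLASSES = ("monomorphic", "discordant", "both_het")


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition defaults: 3 species, the LG1 analysis window, six
    planted concordant sites (4 Y-allele, 2 X-null), 500 decoys, a 2664 bp
    zero-female interval, 147 bp probe planted in 12 of 1000 reads, and a
    family of 8 xy males + 7 xx females."""

    seed: int = 0
    n_species: int = 3
    window: GenomicWindow = DEFAULT_WINDOW
    planted_sites: dict = field(
        default_factory=lambda: {
            SexModel.Y_ALLELE: 4,
            SexModel.X_NULL: 2,
            SexModel.Y_NULL: 0,
        }
    )
    n_decoys: int = 500
    decoy_classes: tuple = DECOY_CLASSES
    multiallelic_fraction: float = 0.2

    # depth-track generation runs on a 100 kb subwindow around the planted
    # null interval; dense per-bp tracks over the full 3.3 Mbp add nothing
    depth_window: GenomicWindow = GenomicWindow("LG1", 26_440_000, 26_539_999)
    null_interval: Optional[tuple[int, int]] = (26_489_200, 26_491_863)  # 2664 bp
    null_male_depth: int = 30
    female_depth_mean: float = 20.0
    male_depth_mean: float = 30.0

    read_length: int = 150
    library_reads: int = 1000
    word_size: int = 64

    family_counts: tuple[int, int, int, int] = (0, 8, 7, 0)  # xy_F, xy_M, xx_F, xx_M

    barcode_length: int = 650
    barcode_mismatches: tuple[int, ...] = (0, 2, 30)

    def design(self) -> StudyDesign:
        return StudyDesign.from_pairs(
            [(f"sp{i + 1}", f"sp{i + 1}_F", f"sp{i + 1}_M") for i in range(self.n_species)]
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """What the generators planted, for exact recovery checks."""

    planted: dict[int, SexModel] = field(default_factory=dict)
    decoys: list[int] = field(default_factory=list)
    null_interval: Optional[tuple[int, int]] = None
    probe_counts: dict[str, int] = field(default_factory=dict)
    family_table: Optional[tuple[int, int, int, int]] = None
    barcode_mismatches: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": {str(k): v.name for k, v in self.planted.items()},
            "decoys": self.decoys,
            "null_interval": self.null_interval,
            "probe_counts": self.probe_counts,
            "family_table": self.family_table,
            "barcode_mismatches": self.barcode_mismatches,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# pooled-sex VCF


def _hom(rng, n_alleles: int) -> PoolCall:
    i = int(rng.integers(0, n_alleles))
    return PoolCall(i, i)


def _het(rng, n_alleles: int) -> PoolCall:
    i, j = rng.choice(n_alleles, size=2, replace=False)
    return PoolCall(int(min(i, j)), int(max(i, j)))


def _calls_for_model(rng, model: SexModel, n_alleles: int) -> tuple[PoolCall, PoolCall]:
    if model is SexModel.Y_ALLELE:
        return _hom(rng, n_alleles), _het(rng, n_alleles)
    if model is SexModel.X_NULL:
        return NULL_CALL, _hom(rng, n_alleles)
    return _het(rng, n_alleles), _hom(rng, n_alleles)


def _decoy_calls(rng, klass: str, species_index: int, n_species: int, n_alleles: int):
    """Genotypes guaranteed non-concordant across the whole design."""
    if klass == "monomorphic":
        call = _hom(rng, n_alleles)
        return call, call  # hom/hom fits no model
    if klass == "both_het":
        het = _het(rng, n_alleles)
        return het, het  # het females exclude Y_ALLELE/X_NULL; het males exclude the rest
    # discordant: first species fits Y_ALLELE, second X_NULL, rest no model,
    # so no single model holds design-wide
    if species_index == 0 and n_species > 1:
        return _calls_for_model(rng, SexModel.Y_ALLELE, n_alleles)
    if species_index == 1:
        return _calls_for_model(rng, SexModel.X_NULL, n_alleles)
    return _hom(rng, n_alleles), _hom(rng, n_alleles)


def _alleles(rng, multiallelic: bool) -> tuple[str, tuple[str, ...]]:
    bases = list(_BASES)
    rng.shuffle(bases)
    if multiallelic:
        alts = [bases[1], bases[2]]
        if rng.random() < 0.25:
            alts[0] = "*"  # spanning deletion behaves as an ordinary allele
        return bases[0], tuple(alts)
    return bases[0], (bases[1],)


def generate_vcf(
    config: SimulationConfig, path: Optional[str | Path] = None
) -> tuple[list[VariantRecord], TruthSet, str]:
    """Plant model-fitting sites and decoys in a pooled-sex multi-sample VCF.

    Returns ``(records, truth, vcf_text)``; ``path`` (optional) receives the
    VCF text.  Every planted site is verified at generation time to be
    concordant under its model, and every decoy to be non-concordant.
    """
    rng = config.rng()
    design = config.design()
    n_sites = sum(config.planted_sites.values()) + config.n_decoys
    width = config.window.end - config.window.start + 1
    if n_sites > width:
        raise GenerationError("more sites requested than window positions")
    positions = np.sort(
        rng.choice(width, size=n_sites, replace=False) + config.window.start
    )

    roles: list[tuple[str, object]] = []
    for model, count in config.planted_sites.items():
        roles.extend(("planted", model) for _ in range(count))
    for i in range(config.n_decoys):
        roles.append(("decoy", config.decoy_classes[i % len(config.decoy_classes)]))
    order = rng.permutation(len(roles))
    roles = [roles[i] for i in order]

    records: list[VariantRecord] = []
    truth = TruthSet()
    for pos, (kind, detail) in zip(positions, roles):
        pos = int(pos)
        multi = bool(rng.random() < config.multiallelic_fraction)
        ref, alts = _alleles(rng, multi)
        n_alleles = 1 + len(alts)
        calls: dict[str, PoolCall] = {}
        for si, pair in enumerate(design.species_pairs):
            if kind == "planted":
                female, male = _calls_for_model(rng, detail, n_alleles)
            else:
                female, male = _decoy_calls(rng, detail, si, config.n_species, n_alleles)
            calls[pair.female_pool] = female
            calls[pair.male_pool] = male
        record = VariantRecord(config.window.chrom, pos, ref, alts, calls)
        verdict = classify_site(record, design).concordant_model
        if kind == "planted":
            if verdict is not detail:
                raise GenerationError(f"planted site {pos} failed its model check")
            truth.planted[pos] = detail
        else:
            if verdict is not None:
                raise GenerationError(f"decoy at {pos} is accidentally concordant")
            truth.decoys.append(pos)
        records.append(record)

    text = _vcf_text(records, design, config.window)
    if path is not None:
        Path(path).write_text(text)
    return records, truth, text


def _vcf_text(records: Sequence[VariantRecord], design: StudyDesign, window: GenomicWindow) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={window.chrom},length={window.end + 1000}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(design.pool_labels),
    ]
    for rec in records:
        gts = [str(rec.calls[label]) for label in design.pool_labels]
        lines.append(
            "\t".join(
                [rec.chrom, str(rec.pos), ".", rec.ref, ",".join(rec.alts) or ".",
                 ".", ".", ".", "GT", *gts]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# depth tracks


def generate_depth_tracks(config: SimulationConfig) -> tuple[list[DepthTrack], TruthSet]:
    """Per-pool depth tracks with a zero-female interval planted for recovery.

    Female background depth is Poisson with the configured mean, clamped to
    >= 1 outside the null interval so the planted boundaries are exact truth;
    inside it female depth is 0.  Male depth is Poisson throughout except a
    constant plateau inside the interval.
    """
    rng = config.rng()
    design = config.design()
    win = config.depth_window
    n = win.length
    null_slice = None
    if config.null_interval is not None:
        s, e = config.null_interval
        if not (win.start <= s <= e <= win.end):
            raise GenerationError("null interval falls outside the depth window")
        null_slice = slice(s - win.start, e - win.start + 1)

    tracks: list[DepthTrack] = []
    for pair in design.species_pairs:
        fdepth = np.maximum(rng.poisson(config.female_depth_mean, n), 1)
        mdepth = rng.poisson(config.male_depth_mean, n)
        if null_slice is not None:
            fdepth[null_slice] = 0
            mdepth[null_slice] = config.null_male_depth
        tracks.append(DepthTrack(pair.female_pool, win.chrom, win.start, fdepth))
        tracks.append(DepthTrack(pair.male_pool, win.chrom, win.start, mdepth))
    truth = TruthSet(null_interval=config.null_interval)
    return tracks, truth


def write_depth_tsv(track: DepthTrack, path: str | Path) -> None:
    """Run-length encode a track as a 1-based inclusive (chrom, start, end, depth) TSV."""
    depths = track.depths
    with Path(path).open("w") as fh:
        run_start = 0
        for i in range(1, len(depths) + 1):
            if i == len(depths) or depths[i] != depths[run_start]:
                fh.write(
                    f"{track.chrom}\t{track.start + run_start}\t"
                    f"{track.start + i - 1}\t{int(depths[run_start])}\n"
                )
                run_start = i


# ---------------------------------------------------------------------------
# read libraries


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_reads(
    config: SimulationConfig,
    probe: Probe,
    plant_counts: dict[str, int],
) -> tuple[dict[str, ReadLibrary], TruthSet]:
    """Libraries with the probe planted verbatim into a known number of reads.

    Planted reads embed the full probe (forward or reverse-complement at
    random); background reads are rejection-sampled to share no word of
    ``config.word_size`` with the probe, so the planted count is the exact
    expected hit count.
    """
    if config.read_length < len(probe):
        raise GenerationError(
            f"read length {config.read_length} shorter than probe ({len(probe)} bp)"
        )
    rng = config.rng()
    words = probe.words(config.word_size)
    libraries: dict[str, ReadLibrary] = {}
    truth = TruthSet(probe_counts=dict(plant_counts))
    for lib_id, n_planted in plant_counts.items():
        if n_planted > config.library_reads:
            raise GenerationError(f"cannot plant {n_planted} reads in {config.library_reads}")
        reads: list[str] = []
        for _ in range(n_planted):
            insert = probe.sequence if rng.random() < 0.5 else _revcomp(probe.sequence)
            pad = config.read_length - len(insert)
            offset = int(rng.integers(0, pad + 1))
            read = _random_seq(rng, offset) + insert + _random_seq(rng, pad - offset)
            reads.append(read)
        while len(reads) < config.library_reads:
            read = _random_seq(rng, config.read_length)
            kmers = (
                read[i : i + config.word_size]
                for i in range(len(read) - config.word_size + 1)
            )
            if any(k in words for k in kmers):
                continue  # rejection keeps background hit-free
            reads.append(read)
        order = rng.permutation(len(reads))
        libraries[lib_id] = ReadLibrary(lib_id, [reads[i] for i in order])
    return libraries, truth


def write_fasta(library: ReadLibrary, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for i, read in enumerate(library.reads):
            fh.write(f">{library.id}_read{i}\n{read}\n")


def random_probe(config: SimulationConfig, length: int = 147) -> Probe:
    """A random probe sequence, as long as the published exon-2 probe by default."""
    return Probe("probe", _random_seq(config.rng(), length))


# ---------------------------------------------------------------------------
# families


def generate_family(config: SimulationConfig) -> tuple[list[IndividualCall], TruthSet]:
    """Individuals matching the configured (xy_F, xy_M, xx_F, xx_M) counts exactly."""
    rng = config.rng()
    a, b, c, d = config.family_counts
    calls = (
        [("xy", "F")] * a + [("xy", "M")] * b + [("xx", "F")] * c + [("xx", "M")] * d
    )
    order = rng.permutation(len(calls))
    out = [
        IndividualCall(f"ind{i + 1}", calls[j][1], calls[j][0])
        for i, j in enumerate(order)
    ]
    return out, TruthSet(family_table=(a, b, c, d))


def write_calls_tsv(calls: Sequence[IndividualCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("id\tsex\tgenotype\n")
        for c in calls:
            fh.write(f"{c.individual}\t{c.sex or ''}\t{c.genotype or ''}\n")


# ---------------------------------------------------------------------------
# barcodes


def generate_barcode_pairs(
    config: SimulationConfig,
) -> tuple[list[AlignedBarcodePair], TruthSet]:
    """Aligned pairs diverging from one base sequence by planted mismatch counts."""
    rng = config.rng()
    base = _random_seq(rng, config.barcode_length)
    pairs: list[AlignedBarcodePair] = []
    truth = TruthSet()
    for k in config.barcode_mismatches:
        if k > config.barcode_length:
            raise GenerationError("more mismatches than barcode columns")
        mutated = list(base)
        for pos in rng.choice(config.barcode_length, size=k, replace=False):
            alternatives = [b for b in _BASES if b != base[pos]]
            mutated[pos] = alternatives[int(rng.integers(0, 3))]
        pair = AlignedBarcodePair("reference", f"diverged_{k}", base, "".join(mutated))
        pairs.append(pair)
        truth.barcode_mismatches[pair.id_b] = k
    return pairs, truth


# ---------------------------------------------------------------------------
# gene models


def random_orf_transcript(rng: np.random.Generator, n_residues: int = 99) -> str:
    """A transcript carrying an ORF encoding ``n_residues`` amino acids.

    Codons are sampled uniformly from the standard-code sense codons
    (excluding ATG-internal constraints); the ORF starts with ATG and ends
    with a random stop codon, with short random UTRs on both sides that
    contain no upstream ATG.
    """
    stops = ("TAA", "TAG", "TGA")
    codons = [
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in stops
    ]
    body = "".join(codons[int(i)] for i in rng.integers(0, len(codons), n_residues - 1))
    orf = "ATG" + body + stops[int(rng.integers(0, 3))]

    def utr(length: int) -> str:
        while True:
            s = _random_seq(rng, length)
            if "ATG" not in s:
                return s

    return utr(int(rng.integers(5, 30))) + orf + utr(int(rng.integers(5, 30)))


# ---------------------------------------------------------------------------
# one-stop emitter


def simulate_all(config: SimulationConfig, outdir: str | Path) -> TruthSet:
    """Emit every synthetic input (VCF, depth TSVs, FASTA libraries, calls TSV,
    truth JSON) into ``outdir`` and return the merged truth set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.design()

    _, vcf_truth, _ = generate_vcf(config, outdir / "variants.vcf")
    tracks, depth_truth = generate_depth_tracks(config)
    for track in tracks:
        write_depth_tsv(track, outdir / f"depth_{track.pool}.tsv")
    probe = random_probe(config)
    (outdir / "probe.fasta").write_text(f">{probe.id}\n{probe.sequence}\n")
    plant_counts = {
        pair.male_pool: 12 if i == 0 else 5 for i, pair in enumerate(design.species_pairs)
    }
    plant_counts.update({pair.female_pool: 0 for pair in design.species_pairs})
    libraries, read_truth = generate_reads(config, probe, plant_counts)
    for lib in libraries.values():
        write_fasta(lib, outdir / f"reads_{lib.id}.fasta")
    calls, family_truth = generate_family(config)
    write_calls_tsv(calls, outdir / "family_calls.tsv")
    pairs, barcode_truth = generate_barcode_pairs(config)
    with (outdir / "barcodes.fasta").open("w") as fh:
        if pairs:
            fh.write(f">{pairs[0].id_a}\n{pairs[0].seq_a}\n")
            for pair in pairs:
                fh.write(f">{pair.id_b}\n{pair.seq_b}\n")

    truth = TruthSet(
        planted=vcf_truth.planted,
        decoys=vcf_truth.decoys,
        null_interval=depth_truth.null_interval,
        probe_counts=read_truth.probe_counts,
        family_table=family_truth.family_table,
        barcode_mismatches=barcode_truth.barcode_mismatches,
    )
    truth.to_json(outdir / "truth.json")
    return truth
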