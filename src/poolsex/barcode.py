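"""cox1 barcode percent differences and species-identity checks.

Species identity of sequencing libraries is checked against the
mitochondrial cytochrome-oxidase-I (cox1) barcode.  Distance is the
uncorrected p-distance over comparable alignment columns — columns where
both sequences have an unambiguous A/C/G/T base; gap or ambiguity columns
are excluded from both numerator and denominator.  Pairs below the
conventional ~1% interspecies floor are called conspecific; disagreements
with the declared species labels are flagged as misidentification
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "AlignedBarcodePair",
    "BarcodeComparison",
    "MisidentificationFlag",
    "compare_barcodes",
    "classify_library_set",
    "pairwise_comparisons",
    "read_aligned_fasta",
    "INTERSPECIES_THRESHOLD_DEFAULT",
]

#: Conventional minimal interspecies divergence for cox1 barcodes (percent).
INTERSPECIES_THRESHOLD_DEFAULT = 1.0

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class AlignedBarcodePair:
    """Two equal-length aligned barcode sequences (gaps allowed)."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"aligned sequences {self.id_a} and {self.id_b} differ in length "
                f"({len(self.seq_a)} vs {len(self.seq_b)}); align them first"
            )


@dataclass(frozen=True)
class BarcodeComparison:
    id_a: str
    id_b: str
    percent_difference: float
    comparable_columns: int
    same_species_call: bool


@dataclass(frozen=True)
class MisidentificationFlag:
    id_a: str
    id_b: str
    declared_same: bool
    called_same: bool
    percent_difference: float

    @property
    def kind(self) -> str:
        # declared different but sequence-identical range -> probable mislabel;
        # declared same but divergent -> cryptic split
        return "misidentified" if not self.declared_same else "cryptic_split"


def compare_barcodes(
    pair: AlignedBarcodePair,
    threshold_percent: float = INTERSPECIES_THRESHOLD_DEFAULT,
) -> BarcodeComparison:
    """Uncorrected p-distance (as a percentage) over comparable columns.

    Raises when no column is comparable (distance undefined).
    """
    comparable = 0
    mismatches = 0
    for x, y in zip(pair.seq_a.upper(), pair.seq_b.upper()):
        if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS:
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        raise ValueError(
            f"no comparable columns between {pair.id_a} and {pair.id_b}; "
            "p-distance is undefined"
        )
    percent = 100.0 * mismatches / comparable
    return BarcodeComparison(
        id_a=pair.id_a,
        id_b=pair.id_b,
        percent_difference=percent,
        comparable_columns=comparable,
        same_species_call=percent < threshold_percent,
    )


def classify_library_set(
    comparisons: Iterable[BarcodeComparison],
    labels: Mapping[str, str],
) -> list[MisidentificationFlag]:
    """Flag pairs whose declared-species relation contradicts the barcode call.

    ``labels`` maps sequence id -> declared species name.  A pair declared as
    different species but conspecific by barcode is a misidentification
    candidate; a pair declared conspecific but divergent is a cryptic split.
    """
    flags: list[MisidentificationFlag] = []
    for comp in comparisons:
        declared_same = labels[comp.id_a] == labels[comp.id_b]
        if declared_same != comp.same_species_call:
            flags.append(
                MisidentificationFlag(
                    id_a=comp.id_a,
                    id_b=comp.id_b,
                    declared_same=declared_same,
                    called_same=comp.same_species_call,
                    percent_difference=comp.percent_difference,
                )
            )
    return flags


def pairwise_comparisons(
    sequences: Mapping[str, str],
    threshold_percent: float = INTERSPECIES_THRESHOLD_DEFAULT,
) -> list[BarcodeComparison]:
    """All-vs-all comparisons of an aligned set (dict id -> aligned sequence)."""
    out = []
    for (id_a, seq_a), (id_b, seq_b) in combinations(sequences.items(), 2):
        pair = AlignedBarcodePair(id_a, id_b, seq_a, seq_b)
        out.append(compare_barcodes(pair, threshold_percent))
    return out


def read_aligned_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered id -> sequence mapping."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequences in {path} are not aligned (lengths {sorted(lengths)})")
    return seqs


def write_barcode_tsv(
    comparisons: Sequence[BarcodeComparison],
    flags: Sequence[MisidentificationFlag],
    path: str | Path,
) -> None:
    flagged = {(f.id_a, f.id_b): f for f in flags}
    with Path(path).open("w") as fh:
        fh.write("id_a\tid_b\tpercent_difference\tcomparable_columns\tsame_species\tflag\n")
        for c in comparisons:
            f = flagged.get((c.id_a, c.id_b))
            fh.write(
                f"{c.id_a}\t{c.id_b}\t{c.percent_difference:.4f}\t"
                f"{c.comparable_columns}\t{'yes' if c.same_species_call else 'no'}\t"
                f"{f.kind if f else ''}\n"
            )
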