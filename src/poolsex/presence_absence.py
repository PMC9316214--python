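"""Male-specific interval detection from per-pool depth-of-coverage tracks.

A locus present only on the Y chromosome shows aligned reads in every male
pool and none in any female pool.  This module formalises that
presence/absence signal: positions where all female tracks are at or below a
ceiling (default 0, "no aligned reads") and all male tracks at or above a
floor are marked, maximal marked runs are merged across small gaps, and runs
shorter than a minimum length are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .concordance import GeneInterval
from .vcf_io import ConfigurationError, GenomicWindow, StudyDesign

__all__ = [
    "DepthTrack",
    "MaleSpecificInterval",
    "find_male_specific_intervals",
    "interval_gene_overlap",
    "load_depth_track",
    "write_intervals_tsv",
]

FEMALE_CEILING_DEFAULT = 0
MALE_FLOOR_DEFAULT = 3  # mirrors the >= 3-read electronic-PCR detection limit
MIN_LENGTH_DEFAULT = 200
MERGE_GAP_DEFAULT = 100


@dataclass
class DepthTrack:
    """Dense per-position read depth for one pool over the analysis window."""

    pool: str
    chrom: str
    start: int  # 1-based position of depths[0]
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if (self.depths < 0).any():
            raise ValueError(f"negative depth in track for pool {self.pool}")

    @property
    def end(self) -> int:
        return self.start + len(self.depths) - 1

    def window(self) -> GenomicWindow:
        return GenomicWindow(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class MaleSpecificInterval:
    """A candidate Y-specific region: male coverage, zero/low female coverage."""

    chrom: str
    start: int
    end: int
    min_male_depth: int
    max_female_depth: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _check_tracks(tracks: Sequence[DepthTrack], design: StudyDesign):
    by_pool = {t.pool: t for t in tracks}
    missing = [lbl for lbl in design.pool_labels if lbl not in by_pool]
    if missing:
        raise ConfigurationError(f"no depth track for pool(s) {missing}")
    ref = by_pool[design.pool_labels[0]]
    for t in by_pool.values():
        if (t.chrom, t.start, len(t.depths)) != (ref.chrom, ref.start, len(ref.depths)):
            raise ConfigurationError(
                f"depth track windows differ: {t.pool} vs {ref.pool}"
            )
    females = [by_pool[p.female_pool] for p in design.species_pairs]
    males = [by_pool[p.male_pool] for p in design.species_pairs]
    return females, males, ref


def find_male_specific_intervals(
    tracks: Sequence[DepthTrack],
    design: StudyDesign,
    *,
    female_ceiling: int = FEMALE_CEILING_DEFAULT,
    male_floor: int = MALE_FLOOR_DEFAULT,
    min_length: int = MIN_LENGTH_DEFAULT,
    merge_gap: int = MERGE_GAP_DEFAULT,
) -> list[MaleSpecificInterval]:
    """Detect intervals covered in every male pool but not in any female pool.

    A position is marked when every female track is <= ``female_ceiling`` AND
    every male track is >= ``male_floor``.  Maximal marked runs separated by
    <= ``merge_gap`` unmarked positions are merged; merged runs shorter than
    ``min_length`` are discarded.  Output is sorted and disjoint.
    """
    females, males, ref = _check_tracks(tracks, design)
    fmat = np.vstack([t.depths for t in females])
    mmat = np.vstack([t.depths for t in males])
    marked = (fmat <= female_ceiling).all(axis=0) & (mmat >= male_floor).all(axis=0)

    runs: list[list[int]] = []  # [start_idx, end_idx] inclusive
    idx = np.flatnonzero(marked)
    for i in idx:
        if runs and i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    out = []
    for s, e in merged:
        if e - s + 1 < min_length:
            continue
        out.append(
            MaleSpecificInterval(
                chrom=ref.chrom,
                start=int(ref.start + s),
                end=int(ref.start + e),
                min_male_depth=int(mmat[:, s : e + 1].min()),
                max_female_depth=int(fmat[:, s : e + 1].max()),
            )
        )
    return out


def interval_gene_overlap(
    intervals: Sequence[MaleSpecificInterval],
    annotations: Sequence[GeneInterval],
) -> dict[MaleSpecificInterval, list[str]]:
    """Inclusive-overlap join of detected intervals against gene annotations."""
    out: dict[MaleSpecificInterval, list[str]] = {}
    for iv in intervals:
        names = [
            a.name
            for a in annotations
            if a.chrom == iv.chrom and a.start <= iv.end and a.end >= iv.start
        ]
        out[iv] = names
    return out


def load_depth_track(
    path: str | Path, pool: str, window: GenomicWindow
) -> DepthTrack:
    """Read a 4-column BED-like depth TSV (chrom, start, end, depth), 1-based inclusive.

    Positions of the window not covered by any row default to depth 0.
    """
    depths = np.zeros(window.length, dtype=np.int64)
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, depth = line.split("\t")[:4]
            if chrom != window.chrom:
                continue
            s = max(int(start), window.start) - window.start
            e = min(int(end), window.end) - window.start
            if e >= s:
                depths[s : e + 1] = int(depth)
    return DepthTrack(pool=pool, chrom=window.chrom, start=window.start, depths=depths)


def write_intervals_tsv(
    intervals: Sequence[MaleSpecificInterval],
    overlap: dict[MaleSpecificInterval, list[str]] | None,
    path: str | Path,
) -> None:
    with Path(path).open("w") as fh:
        fh.write("chrom\tstart\tend\tlength\tmin_male_depth\tmax_female_depth\tgenes\n")
        for iv in intervals:
            genes = ",".join(overlap.get(iv, [])) if overlap else ""
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.length}\t"
                f"{iv.min_male_depth}\t{iv.max_female_depth}\t{genes}\n"
            )
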