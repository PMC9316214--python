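"""Male-specific interval detection: planted recovery, merge semantics,
threshold monotonicity and annotation overlap."""

import numpy as np
import pytest

from poolsex.concordance import GeneInterval
from poolsex.presence_absence import (
    DepthTrack,
    find_male_specific_intervals,
    interval_gene_overlap,
    load_depth_track,
)
from poolsex.synthetic import SimulationConfig, generate_depth_tracks, write_depth_tsv
from poolsex.vcf_io import ConfigurationError, GenomicWindow, StudyDesign

DESIGN1 = StudyDesign.from_pairs([("sp1", "F", "M")])


def _tracks(female: list[int], male: list[int], start: int = 1000):
    return [
        DepthTrack("F", "LG1", start, np.array(female)),
        DepthTrack("M", "LG1", start, np.array(male)),
    ]


def test_planted_interval_recovered_exactly():
    cfg = SimulationConfig(seed=11)
    tracks, truth = generate_depth_tracks(cfg)
    intervals = find_male_specific_intervals(tracks, cfg.design(), min_length=500)
    assert [(iv.start, iv.end) for iv in intervals] == [truth.null_interval]
    assert intervals[0].length == 2664
    # brute-force position scan over the same tracks confirms the boundaries
    by_pool = {t.pool: t.depths for t in tracks}
    females = [by_pool[p.female_pool] for p in cfg.design().species_pairs]
    males = [by_pool[p.male_pool] for p in cfg.design().species_pairs]
    marked = np.flatnonzero(
        np.all([f == 0 for f in females], axis=0) & np.all([m >= 3 for m in males], axis=0)
    )
    assert marked[0] + tracks[0].start == truth.null_interval[0]
    assert marked[-1] + tracks[0].start == truth.null_interval[1]


def test_all_female_covered_window_yields_nothing():
    tracks = _tracks([5] * 100, [30] * 100)
    assert find_male_specific_intervals(tracks, DESIGN1, min_length=1) == []


def test_merge_gap_joins_nearby_intervals():
    female = [0] * 40 + [9] * 10 + [0] * 40
    male = [30] * 90
    tracks = _tracks(female, male)
    merged = find_male_specific_intervals(
        tracks, DESIGN1, min_length=10, merge_gap=50
    )
    assert len(merged) == 1 and merged[0].length == 90
    split = find_male_specific_intervals(tracks, DESIGN1, min_length=10, merge_gap=5)
    assert [iv.length for iv in split] == [40, 40]


def test_runs_shorter_than_min_length_dropped():
    female = [0] * 30 + [9] * 10 + [0] * 100
    male = [30] * 140
    (iv,) = find_male_specific_intervals(tracks := _tracks(female, male), DESIGN1,
                                         min_length=50, merge_gap=0)
    assert iv.length == 100


def test_threshold_monotonicity():
    rng = np.random.default_rng(5)
    female = rng.integers(0, 3, 400)
    male = rng.integers(0, 40, 400)
    tracks = _tracks(list(female), list(male))

    def covered(ceiling, floor):
        ivs = find_male_specific_intervals(
            tracks, DESIGN1, female_ceiling=ceiling, male_floor=floor,
            min_length=1, merge_gap=0,
        )
        return {p for iv in ivs for p in range(iv.start, iv.end + 1)}

    base = covered(2, 3)
    assert covered(1, 3) <= base  # lowering the female ceiling never adds positions
    assert covered(2, 10) <= base  # raising the male floor never adds positions


def test_degenerate_thresholds_cover_whole_window():
    tracks = _tracks([7] * 64, [0] * 64)
    (iv,) = find_male_specific_intervals(
        tracks, DESIGN1, female_ceiling=10**9, male_floor=0, min_length=1
    )
    assert (iv.start, iv.end) == (1000, 1063)


def test_output_sorted_and_disjoint():
    female = ([0] * 20 + [9] * 20) * 5
    male = [30] * 200
    ivs = find_male_specific_intervals(tracks := _tracks(female, male), DESIGN1,
                                       min_length=5, merge_gap=0)
    starts = [iv.start for iv in ivs]
    assert starts == sorted(starts)
    for left, right in zip(ivs, ivs[1:]):
        assert left.end < right.start


def test_mismatched_windows_rejected():
    tracks = [
        DepthTrack("F", "LG1", 1000, np.zeros(10)),
        DepthTrack("M", "LG1", 2000, np.full(10, 30)),
    ]
    with pytest.raises(ConfigurationError, match="differ"):
        find_male_specific_intervals(tracks, DESIGN1)


def test_interval_gene_overlap_inclusive_boundary():
    cfg = SimulationConfig(seed=11)
    tracks, truth = generate_depth_tracks(cfg)
    (iv,) = find_male_specific_intervals(tracks, cfg.design(), min_length=500)
    gene = GeneInterval("figla-like", "LG1", iv.start, iv.end)
    touching = GeneInterval("edge", "LG1", iv.end, iv.end + 500)  # one shared bp
    away = GeneInterval("far", "LG1", iv.end + 10_000, iv.end + 11_000)
    overlap = interval_gene_overlap([iv], [gene, touching, away])
    assert overlap[iv] == ["figla-like", "edge"]


def test_depth_tsv_round_trip(tmp_path):
    cfg = SimulationConfig(seed=2)
    tracks, _ = generate_depth_tracks(cfg)
    track = tracks[0]
    path = tmp_path / "depth.tsv"
    write_depth_tsv(track, path)
    loaded = load_depth_track(path, track.pool, track.window())
    assert np.array_equal(loaded.depths, track.depths)
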