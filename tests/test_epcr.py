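"""Electronic PCR: planted-hit recovery, a naive substring oracle, strand
symmetry, RPKM arithmetic and the duplex genotype call."""

import pytest

from poolsex.epcr import (
    EpcrReport,
    Probe,
    ReadLibrary,
    duplex_genotype,
    epcr_report,
    probe_hits,
)
from poolsex.synthetic import SimulationConfig, generate_reads, random_probe, _revcomp


def naive_probe_hits(probe: Probe, library: ReadLibrary, word_size: int) -> int:
    """Independent oracle: compare every read substring against every probe
    substring on both strands."""
    probe_subs = set()
    for strand in (probe.sequence, _revcomp(probe.sequence)):
        for i in range(len(strand) - word_size + 1):
            probe_subs.add(strand[i : i + word_size])
    count = 0
    for read in library.reads:
        read = read.upper()
        read_subs = {read[i : i + word_size] for i in range(len(read) - word_size + 1)}
        if read_subs & probe_subs:
            count += 1
    return count


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(seed=21, library_reads=200)
    probe = random_probe(cfg)
    libraries, truth = generate_reads(cfg, probe, {"A": 12, "B": 0, "C": 3, "D": 2})
    return cfg, probe, libraries, truth


def test_planted_counts_recovered(planted):
    cfg, probe, libraries, truth = planted
    for lib_id, expected in truth.probe_counts.items():
        assert probe_hits(probe, libraries[lib_id], cfg.word_size) == expected


def test_matches_naive_oracle(planted):
    cfg, probe, libraries, _ = planted
    for library in libraries.values():
        assert probe_hits(probe, library, cfg.word_size) == naive_probe_hits(
            probe, library, cfg.word_size
        )


def test_reverse_complement_reads_count(planted):
    _, probe, libraries, _ = planted
    flipped = ReadLibrary("flipped", [_revcomp(r) for r in libraries["A"].reads])
    assert probe_hits(probe, flipped) == probe_hits(probe, libraries["A"])


def test_hits_monotone_in_word_size(planted):
    cfg, probe, libraries, _ = planted
    counts = [probe_hits(probe, libraries["A"], w) for w in (16, 32, 64, 128)]
    assert counts == sorted(counts, reverse=True)


def test_empty_library():
    probe = Probe("p", "ACGT" * 20)
    assert probe_hits(probe, ReadLibrary("empty", [])) == 0


def test_ambiguity_codes_never_match():
    probe = Probe("p", "A" * 64)
    library = ReadLibrary("lib", ["A" * 31 + "N" + "A" * 31 + "CGTCGT"])
    assert probe_hits(probe, library, 64) == 0


def test_probe_shorter_than_word_size_rejected():
    probe = Probe("p", "ACGTACGT")
    with pytest.raises(ValueError, match="shorter than word size"):
        probe_hits(probe, ReadLibrary("lib", []), 64)


def test_word_size_floor():
    probe = Probe("p", "ACGTACGT")
    with pytest.raises(ValueError, match=">= 8"):
        probe_hits(probe, ReadLibrary("lib", []), 4)


def test_detection_threshold_boundary(planted):
    cfg, probe, libraries, _ = planted
    # 3 planted reads -> detected at the >= 3-read limit; 2 -> not
    assert epcr_report(probe, libraries["C"], cfg.word_size, 3).detected
    assert not epcr_report(probe, libraries["D"], cfg.word_size, 3).detected


def test_rpkm_formula():
    probe = Probe("p", "A" * 147)
    library = ReadLibrary("lib", ["A" * 147] * 10, total_reads=10**6)
    report = epcr_report(probe, library)
    assert report.hit_count == 10
    assert report.rpkm == pytest.approx(10 * 1e9 / (10**6 * 147))  # ~68.03


def test_rpkm_linear_in_hits():
    probe = Probe("p", "A" * 64)
    hit, miss = "A" * 64 + "C" * 10, "C" * 80
    reports = [
        epcr_report(probe, ReadLibrary("lib", [hit] * k + [miss] * (50 - k), total_reads=10**5))
        for k in (1, 2, 4)
    ]
    assert reports[1].rpkm == pytest.approx(2 * reports[0].rpkm)
    assert reports[2].rpkm == pytest.approx(4 * reports[0].rpkm)


def test_rpkm_undefined_for_empty_library():
    probe = Probe("p", "A" * 64)
    assert epcr_report(probe, ReadLibrary("lib", [])).rpkm is None


def test_declared_zero_reads_with_hits_is_impossible():
    probe = Probe("p", "A" * 64)
    library = ReadLibrary("lib", ["A" * 64], total_reads=0)
    with pytest.raises(ValueError, match="0 total reads"):
        epcr_report(probe, library)


def _report(lib, probe_id, detected):
    return EpcrReport(probe_id, lib, 3 if detected else 0, detected, 1.0)


@pytest.mark.parametrize(
    "x_detected, y_detected, expected",
    [
        (True, False, "xx"),  # female pools: only the gene-absent form
        (True, True, "xy"),  # male pools: both forms amplify
        (False, True, "yy?"),
        (False, False, "fail"),
    ],
)
def test_duplex_genotype(x_detected, y_detected, expected):
    call = duplex_genotype(_report("lib", "LG1x", x_detected), _report("lib", "LG1y", y_detected))
    assert call == expected


def test_duplex_requires_same_library():
    with pytest.raises(ValueError, match="different libraries"):
        duplex_genotype(_report("a", "LG1x", True), _report("b", "LG1y", True))
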