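"""XY-model classification: definition examples, an independent brute-force
oracle over the full enumerable call space, and cross-species concordance."""

from itertools import permutations, product

import pytest

from poolsex.concordance import SexModel, classify_pair, classify_site, scan_window
from poolsex.examples import LG1_DESIGN
from poolsex.vcf_io import NULL_CALL, PoolCall, StudyDesign, VariantRecord


def _call_space(n_alleles: int = 3) -> list[PoolCall]:
    calls = [NULL_CALL]
    calls += [PoolCall(i, j) for i in range(n_alleles) for j in range(n_alleles)]
    return calls


def oracle_classify(female: PoolCall, male: PoolCall):
    """Independent predicate evaluator: works on genotype strings only."""

    def kind(call: PoolCall) -> str:
        text = str(call)
        if text == "./.":
            return "null"
        a, b = text.split("/")
        return "hom" if a == b else "het"

    f, m = kind(female), kind(male)
    if (f, m) == ("hom", "het"):
        return SexModel.Y_ALLELE
    if (f, m) == ("null", "hom"):
        return SexModel.X_NULL
    if (f, m) == ("het", "hom"):
        return SexModel.Y_NULL
    return None


@pytest.mark.parametrize(
    "female, male, expected",
    [
        # the published worked-example genotype pairs
        (PoolCall(0, 0), PoolCall(0, 1), SexModel.Y_ALLELE),
        (NULL_CALL, PoolCall(1, 1), SexModel.X_NULL),
        (PoolCall(1, 1), PoolCall(0, 1), SexModel.Y_ALLELE),
        (PoolCall(0, 0), PoolCall(0, 2), SexModel.Y_ALLELE),
        # definition-level cases
        (PoolCall(0, 1), PoolCall(0, 0), SexModel.Y_NULL),
        (PoolCall(0, 1), PoolCall(0, 1), None),
        (NULL_CALL, NULL_CALL, None),
        (PoolCall(0, 0), PoolCall(0, 0), None),
        (NULL_CALL, PoolCall(0, 1), None),
    ],
)
def test_classify_pair_examples(female, male, expected):
    assert classify_pair(female, male) is expected


def test_classify_pair_matches_oracle_on_full_call_space():
    for female, male in product(_call_space(), repeat=2):
        assert classify_pair(female, male) is oracle_classify(female, male), (
            f"disagreement at F={female} M={male}"
        )


def test_models_are_mutually_exclusive():
    for female, male in product(_call_space(), repeat=2):
        hits = [
            model
            for model, pred in [
                (SexModel.Y_ALLELE, female.is_hom and male.is_het),
                (SexModel.X_NULL, female.is_null and male.is_hom),
                (SexModel.Y_NULL, male.is_hom and female.is_het),
            ]
            if pred
        ]
        assert len(hits) <= 1


def _record(pos, ref, alts, gts, design=LG1_DESIGN):
    calls = {
        label: PoolCall.from_string(gt) for label, gt in zip(design.pool_labels, gts)
    }
    return VariantRecord("LG1", pos, ref, alts, calls)


def test_classify_site_published_rows(published_records):
    expected = {
        25_672_475: (SexModel.Y_ALLELE, False),  # tri-allelic, males differ
        26_488_670: (SexModel.Y_ALLELE, True),
        26_490_716: (SexModel.X_NULL, False),
        26_490_863: (SexModel.X_NULL, False),
        26_509_215: (SexModel.Y_ALLELE, True),
        26_510_329: (SexModel.Y_ALLELE, False),  # 0/1 vs 0/2 over ALT "*, T"
    }
    for rec in published_records:
        res = classify_site(rec, LG1_DESIGN)
        model, conserved = expected[rec.pos]
        assert res.concordant_model is model, rec.pos
        assert res.male_alleles_conserved is conserved, rec.pos


def test_mixed_models_are_not_concordant():
    # species fits: Y_ALLELE, X_NULL, Y_ALLELE -> no single design-wide model
    rec = _record(26_000_000, "A", ("C",), ("0/0", "0/1", "./.", "1/1", "0/0", "0/1"))
    assert classify_site(rec, LG1_DESIGN).concordant_model is None


def test_site_without_alt_fits_no_model():
    rec = _record(26_000_000, "A", (), ("0/0", "0/1", "0/0", "0/1", "0/0", "0/1"))
    assert classify_site(rec, LG1_DESIGN).concordant_model is None


def test_scan_window_published_plus_decoys(published_records):
    decoys = [
        _record(25_500_000 + i, "A", ("G",), ("0/1",) * 6) for i in range(10)
    ]
    records = sorted(decoys + published_records, key=lambda r: r.pos)
    results, total = scan_window(records, LG1_DESIGN)
    assert total == 16
    assert [r.site.pos for r in results] == sorted(r.pos for r in published_records)


def test_scan_window_rejects_identical_genotype_decoys():
    # same genotype in both sexes of every species can never fit a model:
    # confirmed per-site by the independent oracle, then by scan_window
    records = []
    for i in range(500):
        gt = ["0/0", "0/1", "1/1"][i % 3]
        records.append(_record(25_400_000 + i, "A", ("G",), (gt,) * 6))
    for rec in records:
        for pair in LG1_DESIGN.species_pairs:
            assert oracle_classify(rec.calls[pair.female_pool], rec.calls[pair.male_pool]) is None
    results, total = scan_window(records, LG1_DESIGN)
    assert results == [] and total == 500


def test_scan_window_empty():
    assert scan_window([], LG1_DESIGN) == ([], 0)


def test_scan_window_rejects_unsorted_input(published_records):
    records = list(reversed(published_records))
    with pytest.raises(ValueError, match="sorted"):
        scan_window(records, LG1_DESIGN)


def test_species_order_never_changes_verdict(published_records):
    base = {r.pos: classify_site(r, LG1_DESIGN).concordant_model for r in published_records}
    for perm in permutations(LG1_DESIGN.species_pairs):
        design = StudyDesign(tuple(perm))
        for rec in published_records:
            assert classify_site(rec, design).concordant_model is base[rec.pos]
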