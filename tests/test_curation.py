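"""Annotation labelling, filtering, deduplication and splitting."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpdetect.curation import (
    CdsRecord,
    CurationConfig,
    curate_records,
    deduplicate,
    is_excluded_other,
    is_excluded_rbp,
    match_rbp_annotation,
    passes_quality_filters,
    split_by_date,
    subsample_others,
)

# keyword variants that must pass / fail the RBP annotation pattern
TABLE_PASS = ["tailspike", "tail spike", "tail-fiber", "receptor-binding protein"]
TABLE_FAIL = ["spike", "tail protein", "binding protein"]


def _rec(seq="A" * 250, product="tail fiber protein", pid="p1",
         day=date(2021, 5, 1)):
    return CdsRecord("ACC1", pid, product, seq, day)


@pytest.mark.parametrize("product", TABLE_PASS)
def test_rbp_keyword_variants_match(product):
    assert match_rbp_annotation(product)


@pytest.mark.parametrize("product", TABLE_FAIL)
def test_ambiguous_keywords_do_not_match(product):
    assert not match_rbp_annotation(product)


@pytest.mark.parametrize(
    "product,expected",
    [
        ("tail fibre protein", True),
        ("TAIL-SPIKE", True),
        ("receptor recognizing protein", True),
        ("", False),
        ("putative tail fiber", True),  # uncertainty words filter Others only
    ],
)
def test_rbp_pattern_spacing_and_case(product, expected):
    assert match_rbp_annotation(product) is expected


@pytest.mark.parametrize(
    "product,expected",
    [
        ("tail fiber assembly protein", True),
        ("tail fiber protein", False),
        ("tail-fiber hinge connector", True),
        ("Tail Spike BASEPLATE protein", True),
    ],
)
def test_rbp_exclusion_keywords(product, expected):
    assert is_excluded_rbp(product) is expected


@pytest.mark.parametrize(
    "product,expected",
    [
        ("hypothetical protein", True),
        ("major capsid protein", False),
        ("Putative holin", True),
        ("PREDICTED terminase", True),
        ("portal protein", False),
    ],
)
def test_other_exclusion_keywords(product, expected):
    assert is_excluded_other(product) is expected


@pytest.mark.parametrize(
    "group,length,mutate,expected",
    [
        ("RBP", 199, None, (False, "length")),
        ("RBP", 200, None, (True, None)),
        ("RBP", 1500, None, (True, None)),
        ("RBP", 1501, None, (False, "length")),
        ("Other", 30, None, (True, None)),
        ("Other", 29, None, (False, "length")),
        ("Other", 500, "X", (False, "unknown_aa")),
        ("RBP", 300, "B", (False, "unknown_aa")),
    ],
)
def test_quality_filter_boundaries(group, length, mutate, expected):
    seq = "A" * length
    if mutate:
        seq = seq[:10] + mutate + seq[11:]
    assert passes_quality_filters(_rec(seq=seq), group) == expected


def test_trailing_stop_is_tolerated():
    ok, reason = passes_quality_filters(_rec(seq="A" * 250 + "*"), "RBP")
    assert ok and reason is None


def test_unknown_aa_takes_priority_over_length():
    # a too-short RBP with an X reports the residue problem first
    ok, reason = passes_quality_filters(_rec(seq="AX" + "A" * 50), "RBP")
    assert (ok, reason) == (False, "unknown_aa")


class TestDeduplicate:
    def test_within_group_collapse_keeps_first(self):
        s1, s2, s3 = "AA" * 100, "CC" * 100, "DD" * 100
        rbps = [_rec(seq=s1, pid="a"), _rec(seq=s1, pid="b"), _rec(seq=s2, pid="c")]
        others = [_rec(seq=s3, pid="d")]
        r, o, counts = deduplicate(rbps, others)
        assert [x.protein_id for x in r] == ["a", "c"]
        assert counts["dup_within_rbp"] == 1 and counts["dup_cross_rbp"] == 0

    def test_cross_group_duplicates_removed_from_both(self):
        s1, s2 = "AA" * 100, "CC" * 100
        r, o, counts = deduplicate(
            [_rec(seq=s1, pid="a")],
            [_rec(seq=s1, pid="b"), _rec(seq=s2, pid="c")],
        )
        assert r == [] and [x.protein_id for x in o] == ["c"]
        assert counts["dup_cross_rbp"] == 1 and counts["dup_cross_other"] == 1

    def test_empty_input(self):
        assert deduplicate([], [])[:2] == ([], [])


class TestSplitByDate:
    def test_boundary_is_inclusive(self):
        recs = [
            _rec(pid="before", day=date(2021, 8, 15)),
            _rec(pid="at", day=date(2021, 9, 30)),
            _rec(pid="after", day=date(2021, 10, 1)),
        ]
        split = split_by_date(recs, cutoff=(2021, 9))
        assert split == {"before": "train", "at": "train", "after": "test"}

    def test_unparseable_date_names_record(self):
        bad = _rec(pid="oops")
        bad.record_date = "2021-13-40"
        with pytest.raises(ValueError, match="oops"):
            split_by_date([bad])


class TestSubsample:
    def test_requested_size(self):
        pool = [_rec(pid=f"o{i}", seq="AC" * (20 + i)) for i in range(100)]
        subset = subsample_others(pool, n_rbp=5, ratio=10, seed=1)
        assert len(subset) == 50

    def test_zero_ratio_gives_empty(self):
        pool = [_rec(pid=f"o{i}", seq="AC" * (20 + i)) for i in range(10)]
        assert subsample_others(pool, n_rbp=5, ratio=0, seed=1) == []

    def test_deterministic_and_error_on_overdraw(self):
        pool = [_rec(pid=f"o{i}", seq="AC" * (20 + i)) for i in range(30)]
        a = subsample_others(pool, 2, 10, seed=9)
        b = subsample_others(pool, 2, 10, seed=9)
        assert [r.protein_id for r in a] == [r.protein_id for r in b]
        with pytest.raises(ValueError):
            subsample_others(pool, 4, 10, seed=9)


class TestCurateRecords:
    def test_hand_counted_mix(self):
        recs = [
            _rec(pid="r1", product="tailspike protein"),
            _rec(pid="r2", product="tail fiber assembly protein"),
            _rec(pid="r3", product="tail fiber protein", seq="A" * 100),
            _rec(pid="o1", product="major capsid protein", seq="C" * 100),
            _rec(pid="o2", product="hypothetical protein", seq="D" * 100),
            _rec(pid="o3", product="holin", seq="E" * 10),
        ]
        ds = curate_records(recs, CurationConfig(subsample_ratio=None))
        assert [r.protein_id for r in ds.rbps] == ["r1"]
        assert [r.protein_id for r in ds.others] == ["o1"]
        assert ds.ledger == {
            "rbp_excluded_keyword": 1,
            "other_excluded_keyword": 1,
            "rbp_length": 1,
            "other_length": 1,
        }

    def test_ledger_conservation_and_partition(self, curated, genbank_fixture):
        _, _, truth = genbank_fixture
        ds = curated
        assert len(ds.rbps) + len(ds.others) + sum(ds.ledger.values()) == len(truth)
        retained = {r.protein_id for r in ds.rbps} | {r.protein_id for r in ds.others}
        assert set(ds.split) == retained
        assert set(ds.split.values()) <= {"train", "test"}

    def test_all_hypothetical_yields_no_others(self):
        recs = [_rec(pid=f"h{i}", product="hypothetical protein", seq="C" * 100)
                for i in range(5)]
        ds = curate_records(recs, CurationConfig(subsample_ratio=None))
        assert ds.others == [] and ds.ledger["other_excluded_keyword"] == 5

    def test_empty_input(self):
        ds = curate_records([], CurationConfig(subsample_ratio=None))
        assert ds.rbps == [] and ds.others == [] and ds.ledger == {}

    def test_subsampling_applies_ratio(self):
        recs = [_rec(pid=f"r{i}", product="tailspike protein",
                     seq="ACDEFGHIKL" * 25 + "MNPQRSTVWY" * i) for i in range(3)]
        recs += [_rec(pid=f"o{i}", product="portal protein",
                      seq="ACDEF" * 12 + "GHIKL" * (i + 1)) for i in range(40)]
        ds = curate_records(recs, CurationConfig(subsample_ratio=10.0, seed=0))
        assert len(ds.rbps) == 3 and len(ds.others) == 30
        assert ds.ledger["other_subsample_discarded"] == 10


@settings(max_examples=200, derandomize=True)
@given(st.text(max_size=60))
def test_rbp_match_never_crashes_and_excludes_fail_strings(product):
    # total function on arbitrary text; bare fail keywords never match
    result = match_rbp_annotation(product)
    assert isinstance(result, bool)
    if result:
        assert any(w in product.lower() for w in ("fib", "spike", "receptor"))
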