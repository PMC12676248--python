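"""Case-table parsing, karyotype clone counts, and the retention statistic."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from shepherdsim.cases import (
    CaseTableError,
    Origin,
    RatioKind,
    RatioValue,
    TransmissionCase,
    TransmissionClass,
    cases_to_csv,
    classify_transmission,
    effective_ratio,
    parse_case_table,
    parse_iscn_mosaic,
    parse_ratio_cell,
    ratio_from_counts,
    retention_summary,
)


def _case(off, par, tol_kind="point"):
    return TransmissionCase(
        case_id="x",
        smc_type="min (t)",
        offspring_ratio=off if isinstance(off, RatioValue) else RatioValue.point(off),
        parent_ratio=par if isinstance(par, RatioValue) else RatioValue.point(par),
        origin=Origin.MATERNAL,
    )


class TestRatioParsing:
    @pytest.mark.parametrize(
        "cell, kind, low, high",
        [
            ("75%", RatioKind.POINT, 0.75, 0.75),
            ("90% Mosaic", RatioKind.POINT, 0.90, 0.90),
            ("42.5%", RatioKind.POINT, 0.425, 0.425),
            ("100%", RatioKind.POINT, 1.0, 1.0),
            ("90%–97%", RatioKind.RANGE, 0.90, 0.97),
            ("4%–10% Mosaic", RatioKind.RANGE, 0.04, 0.10),
            ("Mosaic (proportion not recorded)", RatioKind.UNRECORDED, None, None),
        ],
    )
    def test_cell_forms(self, cell, kind, low, high):
        r = parse_ratio_cell(cell)
        assert r.kind is kind
        assert r.low == low and r.high == high

    def test_malformed_cell_names_row_and_column(self):
        with pytest.raises(CaseTableError, match="row 7.*offspring_ratio"):
            parse_ratio_cell("garbage", row=7, column="offspring_ratio")

    def test_invalid_ratio_values_rejected(self):
        with pytest.raises(CaseTableError):
            RatioValue.point(1.5)
        with pytest.raises(CaseTableError):
            RatioValue.range(0.9, 0.4)


class TestCaseTable:
    def test_reference_table_loads_all_rows(self, reference_cases):
        assert len(reference_cases) == 34

    def test_first_row_point_ratios(self, reference_cases):
        c = reference_cases[0]
        assert c.offspring_ratio == RatioValue.point(0.75)
        assert c.parent_ratio == RatioValue.point(0.90)
        assert c.origin is Origin.MATERNAL

    def test_unrecorded_parent_preserved(self, reference_cases):
        c = next(c for c in reference_cases if c.case_id == "16")
        assert c.parent_ratio.kind is RatioKind.UNRECORDED

    def test_range_ratios_preserved(self, reference_cases):
        c = next(c for c in reference_cases if c.case_id == "26")
        assert c.offspring_ratio == RatioValue.range(0.90, 0.97)
        assert c.parent_ratio == RatioValue.range(0.04, 0.10)

    def test_duplicate_case_id_rejected(self, reference_cases):
        text = cases_to_csv([reference_cases[0], reference_cases[0]])
        with pytest.raises(CaseTableError, match="duplicate"):
            parse_case_table(text)

    def test_csv_round_trip_preserves_ratios(self, reference_cases):
        reparsed = parse_case_table(cases_to_csv(reference_cases))
        for a, b in zip(reference_cases, reparsed):
            assert a.offspring_ratio == b.offspring_ratio
            assert a.parent_ratio == b.parent_ratio
            assert a.origin is b.origin


class TestIscnMosaic:
    def test_two_clone_karyotype(self):
        clones = parse_iscn_mosaic("46,XY,ins(11;?)(p11;?)[17]/46,XY[13]")
        assert clones == [("46,XY,ins(11;?)(p11;?)", 17), ("46,XY", 13)]
        assert sum(n for _, n in clones) == 30

    def test_single_and_multi_clone(self):
        assert parse_iscn_mosaic("46,XX[50]") == [("46,XX", 50)]
        assert parse_iscn_mosaic("A[2]/B[3]/C[5]") == [("A", 2), ("B", 3), ("C", 5)]

    @pytest.mark.parametrize("bad", ["46,XX", "46,XX[0]", "A[3]/B", "A[-2]"])
    def test_malformed_clone_strings_rejected(self, bad):
        with pytest.raises(CaseTableError):
            parse_iscn_mosaic(bad)

    def test_clone_totals_feed_ratio(self):
        clones = parse_iscn_mosaic("46,XX,ins(11;?)(p11;?)[45]/46,XX[54]")
        abnormal = clones[0][1]
        total = sum(n for _, n in clones)
        frac, pct = ratio_from_counts(abnormal, total)
        assert (total, pct) == (99, 45)


class TestRatioFromCounts:
    @pytest.mark.parametrize(
        "abnormal, total, frac, pct",
        [
            (17, 30, 17 / 30, 57),
            (45, 99, 45 / 99, 45),
            (13, 34, 13 / 34, 38),
            (0, 30, 0.0, 0),
            (1, 200, 0.005, 1),  # half-up at the .5 boundary
        ],
    )
    def test_fraction_and_halfup_percent(self, abnormal, total, frac, pct):
        f, p = ratio_from_counts(abnormal, total)
        assert f == pytest.approx(frac)
        assert p == pct

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ratio_from_counts(0, 0)


class TestEffectiveRatio:
    def test_point_range_unrecorded(self):
        assert effective_ratio(RatioValue.point(0.425)) == 0.425
        assert effective_ratio(RatioValue.range(0.90, 0.97)) == pytest.approx(0.935)
        assert effective_ratio(RatioValue.unrecorded()) is None


class TestClassification:
    @pytest.mark.parametrize(
        "off, par, expected",
        [
            (0.75, 0.90, TransmissionClass.LOWER),
            (0.60, 0.59, TransmissionClass.COMPARABLE),
            (0.77, 0.25, TransmissionClass.HIGHER),
            (0.80, 0.70, TransmissionClass.COMPARABLE),  # exactly at tolerance
        ],
    )
    def test_direction_rule(self, off, par, expected):
        assert classify_transmission(_case(off, par), 0.10) is expected

    def test_unrecorded_side_is_undetermined(self):
        c = _case(0.5, RatioValue.unrecorded())
        assert classify_transmission(c) is TransmissionClass.UNDETERMINED

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            classify_transmission(_case(0.5, 0.5), -0.1)

    @given(
        off=st.floats(0, 1),
        par=st.floats(0, 1),
        tol1=st.floats(0, 0.5),
        tol2=st.floats(0, 0.5),
    )
    def test_monotone_in_tolerance(self, off, par, tol1, tol2):
        """Enlarging the tolerance never converts COMPARABLE to HIGHER."""
        lo, hi = sorted([tol1, tol2])
        first = classify_transmission(_case(off, par), lo)
        second = classify_transmission(_case(off, par), hi)
        if first is TransmissionClass.COMPARABLE:
            assert second in (TransmissionClass.COMPARABLE,)
        if first is TransmissionClass.LOWER:
            assert second is TransmissionClass.LOWER


class TestRetentionSummary:
    def test_reference_table_at_default_tolerance(self, reference_cases):
        rs = retention_summary(reference_cases, 0.10)
        assert rs.n_usable == 33
        assert rs.n_lower + rs.n_comparable == 24
        assert rs.lower_or_comparable_fraction == pytest.approx(24 / 33)

    def test_reference_table_strict(self, reference_cases):
        rs = retention_summary(reference_cases, 0.0)
        assert rs.n_lower == 21

    def test_counts_partition_usable(self, reference_cases):
        for tol in (0.0, 0.05, 0.10, 0.25):
            rs = retention_summary(reference_cases, tol)
            assert rs.n_lower + rs.n_comparable + rs.n_higher == rs.n_usable

    def test_single_lower_case(self):
        rs = retention_summary([_case(0.3, 0.9)])
        assert rs.n_usable == 1 and rs.lower_or_comparable_fraction == 1.0

    def test_all_undetermined_rejected(self):
        with pytest.raises(CaseTableError):
            retention_summary([_case(0.5, RatioValue.unrecorded())])
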