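"""Aggregation tables: totals, per-channel statistics, planted-table cells."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanoplex_qc.classify import Assignment, ReadAttributes
from nanoplex_qc.errors import ConfigError, ContractError, DataError
from nanoplex_qc.io_formats import UNCLASSIFIED
from nanoplex_qc.planted import plant_table_fixture
from nanoplex_qc.summary import (
    channel_summary,
    classified_summary,
    length_quality_stats,
    library_summary,
    percent,
    round_half_up,
    to_gbp,
    to_millions,
)


def row(
    read_id="r1",
    length=1000,
    mapped=True,
    tandem=0,
    channel=1,
    barcode="barcode01",
    assignment=None,
    matched=None,
    library="LIG",
    qscore=10.0,
):
    if assignment is None:
        assignment = Assignment.CORRECT if mapped else (
            Assignment.UNMAPPED if barcode != UNCLASSIFIED else Assignment.UNCLASSIFIED_UNMAPPED
        )
    return ReadAttributes(
        read_id=read_id,
        length=length,
        mean_qscore=qscore,
        channel=channel,
        passes_filtering=True,
        barcode=barcode,
        library=library,
        mapped=mapped,
        mapped_target="g1" if mapped else None,
        matched_length=(matched if matched is not None else length) if mapped else 0,
        percent_identity=95.0 if mapped else None,
        query_coverage=90.0 if mapped else None,
        assignment=assignment,
        total_tandem_length=tandem,
    )


class TestLibrarySummary:
    def test_hand_summed_totals(self):
        rows = [
            row("a", 1000, mapped=True, tandem=50),
            row("b", 2000, mapped=True, tandem=0),
            row("c", 500, mapped=False, tandem=500),
        ]
        s = library_summary(rows)
        assert (s.all.read_count, s.all.cum_read_length) == (3, 3500)
        assert (s.mapped.read_count, s.mapped.cum_read_length) == (2, 3000)
        assert s.all.tandem_read_count == 2
        assert s.all.cum_tandem_length == 550

    def test_empty_input_is_all_zero(self):
        s = library_summary([])
        assert s.all.read_count == 0 and s.all.cum_read_length == 0

    def test_mixed_libraries_rejected(self):
        with pytest.raises(ContractError):
            library_summary([row(library="LIG"), row("r2", library="TAG")])

    def test_planted_flow_cell_totals_reproduce_printed_cells(self):
        # fixture planted at 1:10,000 scale against the ligation run's
        # published totals: 6.52 M reads, 35.14 Gbp
        scale = 10_000
        rows = plant_table_fixture("table3", "LIG", scale=scale)
        s = library_summary(rows)
        assert to_millions(s.all.read_count * scale) == 6.52
        assert to_gbp(s.all.cum_read_length * scale) == 35.14
        assert to_millions(s.mapped.read_count * scale) == 6.06
        assert to_gbp(s.all.cum_tandem_length * scale) == 0.32

    @given(
        st.lists(
            st.tuples(st.integers(0, 10**5), st.booleans(), st.integers(0, 1000)),
            max_size=30,
        )
    )
    def test_mapped_plus_unmapped_equals_all(self, specs):
        rows = [
            row(f"r{i}", length=max(length, tandem), mapped=mapped, tandem=tandem)
            for i, (length, mapped, tandem) in enumerate(specs)
        ]
        s = library_summary(rows)
        for metric in ("read_count", "cum_read_length", "tandem_read_count",
                       "cum_tandem_length"):
            assert getattr(s.mapped, metric) + getattr(s.unmapped, metric) == getattr(
                s.all, metric
            )


class TestChannelSummary:
    def test_constant_counts_have_zero_sd(self):
        rows = [row(f"r{i}", channel=1 + i % 2) for i in range(20)]
        s = channel_summary(rows)
        assert s.mean("all", "read_count") == 10
        assert s.sd("all", "read_count") == 0

    def test_population_sd_of_unequal_counts(self):
        rows = [row(f"r{i}", channel=1) for i in range(4)]
        rows += [row(f"s{i}", channel=2) for i in range(8)]
        s = channel_summary(rows)
        assert s.mean("all", "read_count") == 6
        assert s.sd("all", "read_count") == 2  # population SD of {4, 8}
        assert s.sd("all", "read_count") != pytest.approx(
            channel_summary(rows, ddof=1).sd("all", "read_count")
        )

    def test_single_active_channel_sd_zero(self):
        s = channel_summary([row("a", channel=7), row("b", channel=7)])
        assert s.sd("all", "read_count") == 0.0

    def test_inactive_channels_excluded_from_mean(self):
        # 510 silent channels must not drag the mean toward zero
        s = channel_summary([row("a", channel=1), row("b", channel=512)])
        assert s.mean("all", "read_count") == 1.0

    def test_channel_out_of_range_rejected(self):
        with pytest.raises(DataError):
            channel_summary([row(channel=513)])

    def test_channel_totals_sum_to_library_totals(self, lig_synthesis):
        lib = library_summary(lig_synthesis)
        chan = channel_summary(lig_synthesis)
        for part in ("mapped", "unmapped", "all"):
            assert chan.total(part, "cum_read_length") == getattr(lib, part).cum_read_length
            assert chan.total(part, "read_count") == getattr(lib, part).read_count


class TestLengthQualityStats:
    def test_mean_and_max_of_lengths(self):
        stats = length_quality_stats([row("a", 1000), row("b", 3000)])
        assert stats.loc["all", "read_length_mean"] == 2000
        assert stats.loc["all", "read_length_max"] == 3000

    def test_matched_mean_below_read_length_mean(self):
        rows = [row("a", 1000, matched=900), row("b", 3000, matched=2700)]
        stats = length_quality_stats(rows)
        assert stats.loc["mapped", "matched_length_mean"] == 1800
        assert stats.loc["mapped", "matched_length_mean"] < stats.loc[
            "mapped", "read_length_mean"
        ]

    def test_single_row_mean_equals_max(self):
        stats = length_quality_stats([row("a", 4200)])
        assert stats.loc["all", "read_length_mean"] == stats.loc["all", "read_length_max"]

    def test_matched_undefined_for_unmapped(self):
        stats = length_quality_stats([row("a", 1000, mapped=False)])
        assert math.isnan(stats.loc["unmapped", "matched_length_mean"])


class TestClassifiedSummary:
    def test_counts_partition_classified_reads(self):
        rows = [row(f"c{i}") for i in range(8)]
        rows.append(row("l", assignment=Assignment.LEAKED))
        rows.append(row("u", mapped=False))
        s = classified_summary(rows)
        assert (s.correct_reads, s.leaked_reads, s.unmapped_reads) == (8, 1, 1)
        assert s.all_reads == 10
        assert s.correct_reads + s.leaked_reads + s.unmapped_reads == s.all_reads
        assert s.correct_bp + s.leaked_bp + s.unmapped_bp == s.all_bp

    def test_planted_classified_content_matches_printed_cells(self):
        # tagmentation run's published classified content at 1:10,000 scale
        rows = plant_table_fixture("table6", "TAG", scale=10_000)
        s = classified_summary(rows)
        assert (s.correct_reads, s.leaked_reads, s.unmapped_reads) == (161, 2, 7)
        assert s.all_reads == 170
        assert to_gbp(s.all_bp * 10_000) == 10.07

    def test_no_classified_rows(self):
        s = classified_summary([row("a", barcode=UNCLASSIFIED,
                                    assignment=Assignment.UNCLASSIFIED_MAPPED)])
        assert s.all_reads == 0
        assert s.unclassified_fraction == 1.0

    def test_unknown_planted_table_rejected(self):
        with pytest.raises(ConfigError):
            plant_table_fixture("table9", "TAG")
        with pytest.raises(ConfigError):
            plant_table_fixture("table6", "LIG")  # no barcoded ligation run

    def test_huge_scale_yields_empty_fixture(self):
        assert plant_table_fixture("table6", "TAG", scale=10**12) == []


class TestRounding:
    def test_half_up_not_bankers(self):
        assert round_half_up(0.005, 2) == 0.01
        assert round_half_up(2.675, 2) == 2.68

    def test_units(self):
        assert to_millions(6_515_000) == 6.52
        assert to_gbp(35_144_000_000) == 35.14

    def test_percent_from_full_precision_counts(self):
        assert percent(1_570_000, 6_920_000) == 22.7
        assert percent(0, 0) == 0.0

    def test_percent_scale_invariant(self):
        assert percent(157, 692) == percent(157 * 1000, 692 * 1000)
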