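"""Best-alignment selection, identity/coverage arithmetic and category calls."""

import itertools

import pytest

from nanoplex_qc.classify import (
    Assignment,
    BarcodeGenomeMap,
    build_synthesis,
    classify_read,
    percent_identity,
    query_coverage,
    select_best_alignment,
    stringent_filter,
)
from nanoplex_qc.errors import ConfigError, ContractError, DataError, ValidationError
from nanoplex_qc.io_formats import UNCLASSIFIED, AlignmentRecord, ReadRecord

BMAP = BarcodeGenomeMap({"barcode01": "CD3406", "barcode02": "SF2022"})


def aln(read_id="r1", matched=900, block=1000, target="CD3406", primary=True,
        read_length=1000, q_start=0, q_end=1000):
    return AlignmentRecord(
        read_id=read_id, read_length=read_length, q_start=q_start, q_end=q_end,
        target_id=target, matched_bases=matched, block_length=block, mapq=60,
        is_primary=primary,
    )


def rr(read_id="r1", barcode="barcode01", length=1000, qscore=10.0):
    return ReadRecord(read_id=read_id, length=length, mean_qscore=qscore,
                      channel=1, passes_filtering=True, barcode=barcode)


class TestBestAlignment:
    def test_single_primary_selected(self):
        a = aln()
        assert select_best_alignment([a]) is a

    def test_primary_preferred_over_better_secondary(self):
        primary = aln(matched=800)
        secondary = aln(matched=900, primary=False)
        assert select_best_alignment([secondary, primary]) is primary

    def test_identity_breaks_matched_ties(self):
        hi = aln(matched=500, block=526, target="B")  # 95.06%
        lo = aln(matched=500, block=543, target="A")  # 92.08%
        assert select_best_alignment([lo, hi]) is hi

    def test_target_breaks_full_ties_deterministically(self):
        a = aln(target="genomeB")
        b = aln(target="genomeA")
        assert select_best_alignment([a, b]).target_id == "genomeA"

    def test_selection_invariant_under_permutation(self):
        alns = [
            aln(matched=500, block=543, target="A"),
            aln(matched=500, block=526, target="B"),
            aln(matched=900, primary=False, target="C"),
            aln(matched=400, target="D"),
        ]
        results = {
            select_best_alignment(list(perm)).target_id
            for perm in itertools.permutations(alns)
        }
        assert results == {"B"}

    def test_empty_means_unmapped(self):
        assert select_best_alignment([]) is None

    def test_mixed_reads_rejected(self):
        with pytest.raises(ContractError):
            select_best_alignment([aln("r1"), aln("r2")])


class TestIdentityCoverage:
    @pytest.mark.parametrize(
        "matched,block,expected",
        [(95, 100, 95.0), (100, 100, 100.0), (4790, 5300, 90.38)],
    )
    def test_identity_is_matched_over_block(self, matched, block, expected):
        value = percent_identity(aln(matched=matched, block=block))
        assert value == pytest.approx(expected, abs=0.005)

    def test_zero_block_is_undefined(self):
        record = AlignmentRecord(
            read_id="r1", read_length=10, q_start=0, q_end=5, target_id="g",
            matched_bases=0, block_length=0, mapq=0,
        )
        with pytest.raises(DataError):
            percent_identity(record)

    @pytest.mark.parametrize(
        "q_start,q_end,read_length,expected",
        [(0, 5000, 5000, 100.0), (1000, 5000, 10_000, 40.0), (250, 4250, 5000, 80.0)],
    )
    def test_coverage_is_span_over_read_length(self, q_start, q_end, read_length, expected):
        a = aln(read_length=read_length, q_start=q_start, q_end=q_end,
                matched=1, block=q_end - q_start)
        assert query_coverage(a) == pytest.approx(expected)


class TestClassifyRead:
    def test_barcode_matching_mapped_genome_is_correct(self):
        row = classify_read(rr(), aln(target="CD3406"), BMAP)
        assert row.assignment is Assignment.CORRECT
        assert row.mapped and row.mapped_target == "CD3406"

    def test_barcode_disagreeing_with_genome_is_leaked(self):
        row = classify_read(rr(barcode="barcode01"), aln(target="SF2022"), BMAP)
        assert row.assignment is Assignment.LEAKED

    def test_no_alignment_is_unmapped(self):
        row = classify_read(rr(), None, BMAP)
        assert row.assignment is Assignment.UNMAPPED
        assert not row.mapped and row.matched_length == 0
        assert row.percent_identity is None and row.query_coverage is None

    def test_unclassified_reads_split_by_mapping_status(self):
        mapped = classify_read(rr(barcode=UNCLASSIFIED), aln(), BMAP)
        unmapped = classify_read(rr(barcode=UNCLASSIFIED), None, BMAP)
        assert mapped.assignment is Assignment.UNCLASSIFIED_MAPPED
        assert unmapped.assignment is Assignment.UNCLASSIFIED_UNMAPPED

    def test_unknown_barcode_raises_naming_it(self):
        with pytest.raises(ConfigError, match="barcode99"):
            classify_read(rr(barcode="barcode99"), aln(), BMAP)


class TestStringentFilter:
    def _row(self, length, identity, cover, mapped=True):
        span = max(1, int(round(cover / 100 * length)))
        best = (
            aln(read_length=length, q_start=0, q_end=span,
                matched=int(round(identity / 100 * span)), block=span)
            if mapped
            else None
        )
        return classify_read(rr(length=length), best, BMAP)

    def test_inclusive_boundary_kept(self):
        row = self._row(5000, 95.0, 80.0)
        assert stringent_filter([row]) == [row]

    def test_short_read_dropped_despite_quality(self):
        assert stringent_filter([self._row(4999, 99, 99)]) == []

    def test_unmapped_always_dropped(self):
        assert stringent_filter([self._row(9000, 99, 99, mapped=False)]) == []

    def test_mixed_rows_match_brute_force_predicate(self):
        specs = [
            (6000, 96, 90), (6000, 94, 90), (6000, 96, 70),
            (4000, 99, 99), (12_000, 95, 80), (5000, 90, 85),
        ]
        rows = [self._row(*s) for s in specs]
        kept = stringent_filter(rows)
        expected = [
            r for r in rows
            if r.mapped and r.length >= 5000
            and r.percent_identity >= 95 and r.query_coverage >= 80
        ]
        assert kept == expected
        assert len(kept) == 2


class TestBuildSynthesis:
    def test_summary_read_without_alignment_is_unmapped(self):
        rows = build_synthesis([rr("r1"), rr("r2")], [aln("r1")], BMAP)
        by_id = {r.read_id: r for r in rows}
        assert by_id["r1"].mapped
        assert by_id["r2"].assignment is Assignment.UNMAPPED

    def test_alignment_for_unknown_read_is_validation_error(self):
        with pytest.raises(ValidationError, match="ghost"):
            build_synthesis([rr("r1")], [aln("ghost")], BMAP)

    def test_category_partition_on_simulated_run(self, lig_synthesis):
        rows = lig_synthesis
        classified = [r for r in rows if r.classified]
        n_cat = {a: sum(1 for r in classified if r.assignment is a) for a in Assignment}
        assert n_cat[Assignment.CORRECT] + n_cat[Assignment.LEAKED] + n_cat[
            Assignment.UNMAPPED
        ] == len(classified)
        assert len(classified) + sum(1 for r in rows if not r.classified) == len(rows)
        # mapped/unmapped partition covers every read exactly once
        assert sum(r.mapped for r in rows) + sum(not r.mapped for r in rows) == len(rows)

    def test_perfect_information_limit_recovers_every_truth_label(self):
        from nanoplex_qc import default_config, simulate_run

        config = default_config(
            model="TAG", n_reads=400, seed=5,
            unclassified_rate=0.0, leakage_rate=0.0, noise_rate=0.0,
        )
        run = simulate_run(config)
        rows = build_synthesis(run.summary, run.alignments, config.barcode_map)
        assert all(r.assignment is Assignment.CORRECT for r in rows)
        truth = {t.read_id: t for t in run.truth}
        assert all(r.mapped_target == truth[r.read_id].true_genome for r in rows)
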