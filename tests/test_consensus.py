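"""Merging, RNase-R classification and bona fide logic."""

import numpy as np
import pytest

from circinventory import consensus
from circinventory.consensus import (
    CONSTANT,
    DEPLETED,
    ENRICHED,
    ConsensusRecord,
    EnrichmentParams,
    build_inventory,
    classify_rnaser,
    merge_calls,
)
from circinventory.model import (
    CircLocus,
    ClassificationError,
    LibraryMeta,
    PREDICTORS,
    PredictorCall,
)

L1 = CircLocus("chr1", 100, 500, "+")
META_1M = [
    LibraryMeta("mESC_mock", "mESC", "mock", 1_000_000),
    LibraryMeta("mESC_rnaser", "mESC", "rnaser", 1_000_000),
]


def call(locus, tool, sample, reads):
    return PredictorCall(locus, tool, sample, reads)


class TestMerge:
    def test_three_tools_one_record(self):
        calls = [call(L1, t, "mESC_mock", 5) for t in PREDICTORS]
        (rec,) = merge_calls(calls, META_1M)
        assert rec.detected_by == frozenset(PREDICTORS)
        assert rec.count("ciri2", "mESC_mock") == 5

    def test_one_bp_offset_two_records(self):
        shifted = CircLocus("chr1", 101, 500, "+")
        recs = merge_calls([call(L1, "ciri2", "mESC_mock", 1),
                            call(shifted, "ciri2", "mESC_mock", 1)], META_1M)
        assert len(recs) == 2

    def test_same_key_same_sample_counts_sum(self):
        recs = merge_calls([call(L1, "ciri2", "mESC_mock", 2),
                            call(L1, "ciri2", "mESC_mock", 3)], META_1M)
        assert recs[0].count("ciri2", "mESC_mock") == 5

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown sample"):
            merge_calls([call(L1, "ciri2", "nope", 1)], META_1M)

    def test_matches_bruteforce_grouping(self):
        """Dict-based merge agrees with O(n^2) grouping on 1,000 random calls."""
        rng = np.random.default_rng(42)
        calls = []
        for _ in range(1000):
            start = int(rng.integers(0, 40)) * 10
            locus = CircLocus(f"chr{rng.integers(1, 3)}", start,
                              start + int(rng.integers(1, 5)) * 100,
                              "+" if rng.random() < 0.5 else "-")
            calls.append(call(locus, PREDICTORS[rng.integers(3)],
                              "mESC_mock" if rng.random() < 0.5 else "mESC_rnaser",
                              int(rng.integers(0, 50))))
        merged = merge_calls(calls, META_1M)

        # brute force: linear scan comparing field tuples, no hashing
        groups = []
        for c in calls:
            for g in groups:
                g0 = g[0].locus
                if (g0.chrom == c.locus.chrom and g0.start == c.locus.start
                        and g0.end == c.locus.end and g0.strand == c.locus.strand):
                    g.append(c)
                    break
            else:
                groups.append([c])
        assert len(merged) == len(groups)
        by_locus = {r.locus: r for r in merged}
        for g in groups:
            rec = by_locus[g[0].locus]
            assert rec.detected_by == {c.predictor for c in g}
            for tool in PREDICTORS:
                for sid in ("mESC_mock", "mESC_rnaser"):
                    assert rec.count(tool, sid) == sum(
                        c.bsj_reads for c in g
                        if c.predictor == tool and c.sample_id == sid)

    def test_slop_clusters_near_identical_loci(self):
        shifted = CircLocus("chr1", 101, 500, "+")
        calls = [call(L1, "ciri2", "mESC_mock", 10),
                 call(shifted, "find_circ", "mESC_mock", 2)]
        assert len(merge_calls(calls, META_1M, slop=0)) == 2
        (rec,) = merge_calls(calls, META_1M, slop=1)
        assert rec.locus == L1  # best-supported representative wins
        assert rec.detected_by == {"ciri2", "find_circ"}


def record_with(mock_reads, rnaser_reads, tool="ciri2"):
    rec = ConsensusRecord(L1, frozenset(PREDICTORS), {})
    rec.counts[(tool, "mESC_mock")] = mock_reads
    rec.counts[(tool, "mESC_rnaser")] = rnaser_reads
    return rec


class TestClassification:
    def test_threshold_is_inclusive_at_threefold(self):
        # with totals of 1e6, normalized counts equal raw reads
        rec = record_with(1, 3)
        classify_rnaser(rec, EnrichmentParams(pseudocount=0.0), META_1M)
        assert rec.stage_class["mESC"] == ENRICHED

    def test_quarter_fold_is_depleted(self):
        rec = record_with(4, 1)
        classify_rnaser(rec, EnrichmentParams(pseudocount=0.0), META_1M)
        assert rec.stage_class["mESC"] == DEPLETED

    def test_pseudocount_guards_zero_mock(self):
        rec = record_with(0, 5)
        classify_rnaser(rec, EnrichmentParams(pseudocount=0.5), META_1M)
        assert rec.stage_class["mESC"] == ENRICHED  # (5+.5)/(0+.5) = 11

    def test_between_thresholds_is_constant(self):
        rec = record_with(2, 3)
        classify_rnaser(rec, EnrichmentParams(pseudocount=0.0), META_1M)
        assert rec.stage_class["mESC"] == CONSTANT

    def test_missing_pair_everywhere_raises(self):
        rec = record_with(1, 1)
        with pytest.raises(ClassificationError):
            classify_rnaser(rec, EnrichmentParams(),
                            [LibraryMeta("mESC_mock", "mESC", "mock", 10)])

    def test_scale_invariance(self):
        """Multiplying all counts and totals by a constant keeps classes."""
        for factor in (10, 1000):
            rec_a = record_with(7, 30)
            rec_b = record_with(7 * factor, 30 * factor)
            metas = [LibraryMeta("mESC_mock", "mESC", "mock", 1_000_000 * factor),
                     LibraryMeta("mESC_rnaser", "mESC", "rnaser", 1_000_000 * factor)]
            classify_rnaser(rec_a, EnrichmentParams(pseudocount=0.0), META_1M)
            classify_rnaser(rec_b, EnrichmentParams(pseudocount=0.0), metas)
            assert rec_a.stage_class == rec_b.stage_class

    def test_depleted_stage_vetoes_overall_enrichment(self):
        metas = META_1M + [
            LibraryMeta("NPC_mock", "NPC", "mock", 1_000_000),
            LibraryMeta("NPC_rnaser", "NPC", "rnaser", 1_000_000)]
        rec = record_with(1, 9)
        rec.counts[("ciri2", "NPC_mock")] = 9
        rec.counts[("ciri2", "NPC_rnaser")] = 1
        classify_rnaser(rec, EnrichmentParams(pseudocount=0.0), metas)
        assert rec.stage_class == {"mESC": ENRICHED, "NPC": DEPLETED}
        assert rec.overall_class == DEPLETED

    def test_pooled_scope_sums_normalized_counts(self):
        rec = record_with(1, 9)
        classify_rnaser(rec, EnrichmentParams(pseudocount=0.0, scope="pooled"),
                        META_1M)
        assert rec.overall_class == ENRICHED


class TestInventory:
    def test_bona_fide_requires_all_three_tools(self, default_dataset):
        _, _, libs = default_dataset
        two_tools = [c for tool in ("ciri2", "find_circ")
                     for c in libs.calls[tool]]
        records, _ = build_inventory(two_tools, libs.metas)
        assert not any(r.bona_fide for r in records)

    def test_bona_fide_monotone_in_fold_threshold(self, default_dataset):
        _, _, libs = default_dataset
        calls = [c for tool_calls in libs.calls.values() for c in tool_calls]
        previous = None
        for fold in (2.0, 3.0, 5.0, 10.0):
            records, _ = build_inventory(
                calls, libs.metas, EnrichmentParams(fold_threshold=fold))
            bona = {r.locus for r in records if r.bona_fide}
            if previous is not None:
                assert bona <= previous
            previous = bona

    def test_summary_reconstructs_venn_and_classes(self, default_inventory):
        records, summary = default_inventory
        assert sum(summary["venn_constant_or_enriched"].values()) \
            == summary["n_constant_or_enriched"]
        n_unclassified = sum(r.overall_class is None for r in records)
        assert sum(summary["class_counts"].values()) + n_unclassified \
            == summary["n_merged_loci"]

    def test_per_tool_depletion_ranking(self, default_inventory):
        """find_circ calls the most RNase-R-depleted loci, CIRI2 the fewest."""
        _, summary = default_inventory
        mean_depl = {tool: np.mean(list(v.values()))
                     for tool, v in summary["per_tool_depleted_fraction"].items()}
        assert mean_depl["find_circ"] > mean_depl["circexplorer2"] > mean_depl["ciri2"]

    def test_bona_fide_invariant(self, default_inventory):
        records, _ = default_inventory
        for r in records:
            if r.bona_fide:
                assert r.detected_by == frozenset(PREDICTORS)
                assert r.overall_class == ENRICHED
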