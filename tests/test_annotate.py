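"""Host-gene assignment, structural metrics and chain lifting."""

import numpy as np
import pytest

from circinventory import annotate, simdata
from circinventory.annotate import (
    FULLY_MATCHED,
    PARTIAL,
    UNMAPPED,
    GeneIndex,
    assign_host,
    homology_overlap,
    lift_locus,
    structural_report,
)
from circinventory.model import ChainAlignment, CircLocus, GeneModel

EXONS5 = ((0, 100), (200, 300), (400, 500), (600, 700), (800, 900))
PLUS = GeneModel("gplus", "chr1", "+", EXONS5)
MINUS = GeneModel("gminus", "chr1", "-", EXONS5)


class TestAssignHost:
    def test_plus_strand_two_exon_circle(self):
        ann = assign_host(CircLocus("chr1", 200, 500, "+"), GeneIndex([PLUS]))
        assert ann.host_gene == "gplus"
        assert ann.shared_splice_sites == 2
        assert ann.internal_exon_count == 2
        assert ann.flank_intron_up_len == 100   # intron (100, 200)
        assert ann.flank_intron_down_len == 100  # intron (500, 600)
        assert ann.relative_start_position == pytest.approx(0.25)

    def test_minus_strand_orientation_corrected(self):
        # transcript order is reversed: the circle's transcript-first exon is
        # the genomic exon ending at locus.end (index 2), hence (4-2)/4
        ann = assign_host(CircLocus("chr1", 200, 500, "-"), GeneIndex([MINUS]))
        assert ann.relative_start_position == pytest.approx(0.5)

    def test_minus_strand_single_exon_complement_identity(self):
        plus = assign_host(CircLocus("chr1", 200, 300, "+"), GeneIndex([PLUS]))
        minus = assign_host(CircLocus("chr1", 200, 300, "-"), GeneIndex([MINUS]))
        assert plus.relative_start_position == pytest.approx(0.25)
        assert minus.relative_start_position == pytest.approx(1 - 0.25)

    def test_off_boundary_locus_has_no_host(self):
        ann = assign_host(CircLocus("chr1", 150, 450, "+"), GeneIndex([PLUS]))
        assert ann.host_gene is None
        assert ann.shared_splice_sites == 0
        assert ann.relative_start_position is None

    def test_strand_mismatch_excluded(self):
        ann = assign_host(CircLocus("chr1", 200, 500, "-"), GeneIndex([PLUS]))
        assert ann.host_gene is None

    def test_terminal_exon_boundary_leaves_flank_missing(self):
        ann = assign_host(CircLocus("chr1", 0, 300, "+"), GeneIndex([PLUS]))
        assert ann.flank_intron_up_len is None
        assert ann.flank_intron_down_len == 100

    def test_deterministic_under_gene_order(self):
        other = GeneModel("aaa", "chr1", "+", ((200, 300), (400, 520)))
        locus = CircLocus("chr1", 200, 500, "+")
        a = assign_host(locus, GeneIndex([PLUS, other]))
        b = assign_host(locus, GeneIndex([other, PLUS]))
        assert a.host_gene == b.host_gene == "gplus"  # two shared sites beat one


@pytest.fixture(scope="module")
def annotated():
    out = {}
    for bias in (True, False):
        cfg = simdata.SimConfig(n_genes=150, n_true_circ=80, n_artifacts=20,
                                five_prime_bias=bias, seed=23)
        genes = simdata.simulate_gene_models(cfg)
        truth = simdata.simulate_truth(cfg, genes)
        anns = annotate.annotate_loci(
            [t.locus for t in truth.circ_truth if t.kind == "true_circ"], genes)
        out[bias] = structural_report(anns, genes)
    return out


class TestStructuralReport:

    def test_flanking_introns_exceed_background(self, annotated):
        rep = annotated[True]
        assert rep["median_flank_intron"] > rep["median_background_intron"]
        assert rep["flank_vs_background_rank_p"] < 0.01

    def test_five_prime_bias_detected(self, annotated):
        assert annotated[True]["median_relative_start_position"] < 0.5

    def test_uniform_null_centered(self, annotated):
        assert annotated[False]["median_relative_start_position"] \
            == pytest.approx(0.5, abs=0.08)


def chain(s_chrom="chrA", s_size=1000, t_chrom="chrB", t_size=1000,
          t_strand="+", blocks=((0, 0, 1000),), cid="1"):
    s_start = blocks[0][0]
    s_end = blocks[-1][0] + blocks[-1][2]
    t_start = blocks[0][1]
    t_end = blocks[-1][1] + blocks[-1][2]
    return ChainAlignment(cid, 1, s_chrom, s_size, s_start, s_end,
                          t_chrom, t_size, t_strand, t_start, t_end, blocks)


class TestLift:
    def test_identity_chain_is_fixed_point(self):
        ident = chain(t_chrom="chrA")
        locus = CircLocus("chrA", 100, 500, "+")
        lifted = lift_locus(locus, [ident])
        assert lifted.status == FULLY_MATCHED
        assert lifted.target == locus

    def test_endpoint_in_gap_never_fully_matched(self):
        gapped = chain(blocks=((0, 0, 100), (200, 150, 100)))
        # start 150 sits in the source gap (100..200)
        lifted = lift_locus(CircLocus("chrA", 150, 250, "+"), [gapped])
        assert lifted.status in (PARTIAL, UNMAPPED)
        assert lifted.status == PARTIAL  # the end maps, the start does not

    def test_length_preserved_through_gap_free_chain(self):
        shift = chain(blocks=((100, 400, 600),))
        locus = CircLocus("chrA", 150, 450, "-")
        lifted = lift_locus(locus, [shift])
        assert lifted.status == FULLY_MATCHED
        assert lifted.target.span == locus.span
        assert lifted.target.start == 450

    def test_minus_strand_target_arithmetic(self):
        # one 100 bp block chrA:100-200 -> chrB reversed-strand 300-400 on a
        # 500 bp target: forward coords are 500-1-q for q in 300..399
        mc = chain(t_size=500, t_strand="-", blocks=((100, 300, 100),))
        lifted = lift_locus(CircLocus("chrA", 100, 200, "+"), [mc])
        assert lifted.status == FULLY_MATCHED
        assert lifted.target == CircLocus("chrB", 100, 200, "-")

    def test_round_trip_through_inverse_chains(self):
        """Every fully matched lift through a gapped chain returns to its
        source through the inverse chain."""
        rng = np.random.default_rng(13)
        blocks, s, t = [], 0, 0
        for _ in range(6):
            size = int(rng.integers(50, 300))
            blocks.append((s, t, size))
            s += size + int(rng.integers(0, 100))
            t += size + int(rng.integers(0, 100))
        fwd = chain(blocks=tuple(blocks))
        inv = chain(s_chrom="chrB", t_chrom="chrA",
                    blocks=tuple((ts, ss, size) for ss, ts, size in blocks))
        n_full = 0
        for _ in range(200):
            start = int(rng.integers(0, s - 10))
            locus = CircLocus("chrA", start, start + int(rng.integers(5, 400)),
                              "+" if rng.random() < 0.5 else "-")
            lifted = lift_locus(locus, [fwd])
            if lifted.status != FULLY_MATCHED:
                continue
            n_full += 1
            back = lift_locus(lifted.target, [inv])
            assert back.status == FULLY_MATCHED
            assert back.target == locus
        assert n_full > 20

    def test_wrong_assembly_warns_and_unmaps(self):
        with pytest.warns(UserWarning, match="assembly"):
            lifted = annotate.lift_loci([CircLocus("chr9", 5, 50, "+")],
                                        [chain()])
        assert lifted[0].status == UNMAPPED


class TestHomologyOverlap:
    def lifts(self):
        targets = [CircLocus("chrB", 100, 200, "+"), CircLocus("chrB", 400, 600, "-")]
        return [annotate.LiftedLocus(CircLocus("chrA", 1, 2, "+"), t, FULLY_MATCHED)
                for t in targets] + [
            annotate.LiftedLocus(CircLocus("chrA", 5, 9, "+"), None, UNMAPPED)]

    def test_reference_equal_to_targets(self):
        lifts = self.lifts()[:2]
        frac, matched = homology_overlap(lifts, {l.target for l in lifts})
        assert frac == 1.0 and len(matched) == 2

    def test_empty_reference(self):
        assert homology_overlap(self.lifts(), set())[0] == 0.0

    def test_unliftable_loci_count_in_denominator(self):
        lifts = self.lifts()
        frac, _ = homology_overlap(lifts, {lifts[0].target, lifts[1].target})
        assert frac == pytest.approx(2 / 3)

    def test_slop_admits_off_by_one(self):
        lifts = self.lifts()[:1]
        ref = {CircLocus("chrB", 101, 201, "+")}
        assert homology_overlap(lifts, ref, slop=0)[0] == 0.0
        assert homology_overlap(lifts, ref, slop=2)[0] == 1.0

    def test_monotone_in_slop(self):
        lifts = self.lifts()
        ref = {CircLocus("chrB", 103, 203, "+"), CircLocus("chrB", 410, 590, "-")}
        fracs = [homology_overlap(lifts, ref, slop=s)[0] for s in (0, 3, 10, 50)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
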