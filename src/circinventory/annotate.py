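"""Host-gene assignment, structural metrics and cross-species lifting.

A gene is a host candidate when it lies on the circle's chromosome and
strand and shares at least one splice site with the backsplice junction —
the circle's start coinciding with an exon start, or its end with an exon
end. Backsplicing reuses the host's own splice sites, so opposite-strand
genes are never candidates.

Lifting maps both circle endpoints through the aligned blocks of UCSC
chains; only loci whose two endpoints land inside blocks of the *same*
chain, in preserved order, count as fully matched — the criterion used for
calling cross-species homologs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .model import ChainAlignment, CircLocus, GeneModel

FULLY_MATCHED = "fully_matched"
PARTIAL = "partial"
UNMAPPED = "unmapped"


@dataclass
class HostAnnotation:
    locus: CircLocus
    host_gene: Optional[str]
    shared_splice_sites: int
    internal_exon_count: Optional[int] = None
    flank_intron_up_len: Optional[int] = None    # genomic upstream intron, nt
    flank_intron_down_len: Optional[int] = None  # genomic downstream intron, nt
    relative_start_position: Optional[float] = None  # 0 = transcript 5' end


@dataclass(frozen=True)
class LiftedLocus:
    source: CircLocus
    target: Optional[CircLocus]
    status: str


class GeneIndex:
    """Interval index of gene models per (chromosome, strand)."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self.genes = list(genes)
        for g in self.genes:
            self._trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
                g.start, g.end, g)

    def overlapping(self, locus: CircLocus) -> List[GeneModel]:
        tree = self._trees.get((locus.chrom, locus.strand))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(locus.start, locus.end)),
                      key=lambda g: g.gene_id)


def assign_host(locus: CircLocus, genes: GeneIndex) -> HostAnnotation:
    """Pick the host gene and derive the circle's structural metrics.

    Candidates are ranked by shared splice sites (2 beats 1), then by
    overlap length with the circle, then lexically by gene id, so the
    assignment is deterministic and independent of input order.
    """
    best = None
    for g in genes.overlapping(locus):
        start_idx = next((i for i, (s, _) in enumerate(g.exons) if s == locus.start), None)
        end_idx = next((i for i, (_, e) in enumerate(g.exons) if e == locus.end), None)
        shared = int(start_idx is not None) + int(end_idx is not None)
        if shared == 0:
            continue
        overlap = min(locus.end, g.end) - max(locus.start, g.start)
        key = (-shared, -overlap, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g, start_idx, end_idx, shared)
    if best is None:
        return HostAnnotation(locus, None, 0)
    _, gene, start_idx, end_idx, shared = best
    ann = HostAnnotation(locus, gene.gene_id, shared)
    ann.internal_exon_count = sum(
        1 for (s, e) in gene.exons if s >= locus.start and e <= locus.end)
    introns = gene.introns
    if start_idx is not None and start_idx > 0:
        a, b = introns[start_idx - 1]
        ann.flank_intron_up_len = b - a
    if end_idx is not None and end_idx < gene.n_exons - 1:
        a, b = introns[end_idx]
        ann.flank_intron_down_len = b - a
    # position of the circle's transcript-first boundary exon, 0 = transcript
    # 5' end; on '-' genes that exon is the one matching the genomic end
    if gene.n_exons > 1:
        if gene.strand == "+" and start_idx is not None:
            ann.relative_start_position = start_idx / (gene.n_exons - 1)
        elif gene.strand == "-" and end_idx is not None:
            ann.relative_start_position = (gene.n_exons - 1 - end_idx) / (gene.n_exons - 1)
    return ann


def annotate_loci(loci: Iterable[CircLocus], genes: Iterable[GeneModel]
                  ) -> List[HostAnnotation]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [assign_host(loc, index) for loc in loci]


def structural_report(annotations: List[HostAnnotation],
                      genes: Iterable[GeneModel]) -> dict:
    """Flanking-intron length vs background and 5' positional-bias summary.

    The background is every intron of every gene in the annotation; the
    comparison is a one-sided Mann-Whitney rank-sum test for elongated
    flanks.
    """
    gene_list = genes.genes if isinstance(genes, GeneIndex) else list(genes)
    background = [l for g in gene_list for l in g.intron_lengths()]
    flanks = [l for a in annotations if a.host_gene
              for l in (a.flank_intron_up_len, a.flank_intron_down_len)
              if l is not None]
    positions = [a.relative_start_position for a in annotations
                 if a.relative_start_position is not None]
    if not flanks:
        raise ValueError("no hosted circle with flanking introns to report on")
    if background and flanks:
        mw = stats.mannwhitneyu(flanks, background, alternative="greater")
        rank_p = float(mw.pvalue)
    else:
        rank_p = float("nan")
    return {
        "n_hosted": sum(1 for a in annotations if a.host_gene),
        "n_unhosted": sum(1 for a in annotations if not a.host_gene),
        "median_flank_intron": float(np.median(flanks)),
        "median_background_intron": float(np.median(background)) if background else float("nan"),
        "flank_vs_background_rank_p": rank_p,
        "median_relative_start_position": (float(np.median(positions))
                                           if positions else float("nan")),
        "n_positions": len(positions),
    }


# ---------------------------------------------------------------------------
# chain lifting

def _lift_point(chain: ChainAlignment, pos: int) -> Optional[int]:
    """Map one source position through a chain's blocks.

    Returns the target position in forward-strand coordinates, or None if
    the position falls in a gap or outside the chain.
    """
    for (ss, ts, size) in chain.blocks:
        if ss <= pos < ss + size:
            qpos = ts + (pos - ss)
            if chain.t_strand == "-":
                return chain.t_size - 1 - qpos
            return qpos
    return None


def lift_locus(locus: CircLocus, chains: List[ChainAlignment]) -> LiftedLocus:
    """Lift a circle through chains; homology requires a full match.

    Both endpoints (start and end−1) must map inside aligned blocks of one
    and the same chain with order preserved; the target strand is the source
    strand composed with the chain's target strand.
    """
    relevant = [c for c in chains if c.s_chrom == locus.chrom]
    p1, p2 = locus.start, locus.end - 1
    any_endpoint = False
    for chain in relevant:
        a = _lift_point(chain, p1)
        b = _lift_point(chain, p2)
        if a is not None or b is not None:
            any_endpoint = True
        if a is None or b is None:
            continue
        t_start, t_end = (a, b + 1) if a <= b else (b, a + 1)
        if t_end <= t_start:
            continue
        strand = locus.strand if chain.t_strand == "+" else (
            "-" if locus.strand == "+" else "+")
        return LiftedLocus(locus, CircLocus(chain.t_chrom, t_start, t_end, strand),
                           FULLY_MATCHED)
    if any_endpoint:
        return LiftedLocus(locus, None, PARTIAL)
    return LiftedLocus(locus, None, UNMAPPED)


def lift_loci(loci: Iterable[CircLocus], chains: List[ChainAlignment]
              ) -> List[LiftedLocus]:
    loci = list(loci)
    chroms = {c.s_chrom for c in chains}
    if loci and not any(l.chrom in chroms for l in loci):
        warnings.warn("no locus chromosome occurs in the chain file; "
                      "are the chains for the right source assembly?")
    return [lift_locus(l, chains) for l in loci]


def homology_overlap(lifted: List[LiftedLocus], reference: Set[CircLocus],
                     slop: int = 0) -> Tuple[float, List[LiftedLocus]]:
    """Fraction of input loci whose full-match target hits the reference set.

    The denominator is *all* input loci, not only the lifted ones, so an
    unliftable circle counts against the overlap. With ``slop`` > 0 each
    endpoint may differ by up to that many bp (same chromosome and strand).
    """
    if not lifted:
        return 0.0, []
    matched = []
    for lf in lifted:
        if lf.status != FULLY_MATCHED:
            continue
        t = lf.target
        if slop == 0:
            if t in reference:
                matched.append(lf)
            continue
        for ref in reference:
            if (ref.chrom == t.chrom and ref.strand == t.strand
                    and abs(ref.start - t.start) <= slop
                    and abs(ref.end - t.end) <= slop):
                matched.append(lf)
                break
    return len(matched) / len(lifted), matched
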