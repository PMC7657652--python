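"""Core data model shared across the pipeline.

Coordinates are uniformly 0-based half-open ``[start, end)`` on the forward
genomic strand; dialects that use other conventions (CIRI2, GTF) are
converted at the parsing boundary and never afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PREDICTORS = ("find_circ", "ciri2", "circexplorer2")
STAGES = ("mESC", "NPC", "mN8")
TREATMENTS = ("mock", "rnaser")


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


class ConfigError(ValueError):
    """An invalid configuration value."""


class PlacementError(RuntimeError):
    """Synthetic circle placement could not be satisfied."""


class ClassificationError(RuntimeError):
    """RNase-R classification impossible (no usable treatment pair)."""


@dataclass(frozen=True, order=True)
class CircLocus:
    """A backsplice junction as a stranded genomic interval.

    Identity (equality/hash) is the full (chrom, start, end, strand) tuple;
    this is the primary key of the whole analysis.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def from_key(cls, key: str) -> "CircLocus":
        chrom, rest, strand = key.rsplit(":", 2)
        start, end = rest.split("-")
        return cls(chrom, int(start), int(end), strand)


@dataclass
class PredictorCall:
    """One predictor's call of one backsplice junction in one library."""

    locus: CircLocus
    predictor: str
    sample_id: str
    bsj_reads: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.bsj_reads < 0:
            raise ValueError("bsj_reads must be >= 0")


@dataclass(frozen=True)
class LibraryMeta:
    sample_id: str
    stage: str
    treatment: str
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be > 0")


@dataclass
class GeneModel:
    """An annotated gene as a sorted, non-overlapping exon chain."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # of (start, end), 0-based half-open, ascending
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        for (s, e) in exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s}, {e})")
        for (a, b) in zip(exons, exons[1:]):
            if b[0] < a[1]:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
        object.__setattr__(self, "exons", exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple:
        """Introns between consecutive exons, genomic orientation."""
        return tuple(
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])
        )

    def intron_lengths(self) -> list:
        return [b - a for a, b in self.introns]


@dataclass(frozen=True)
class JunctionQuant:
    """Backsplice and flanking linear splice-read counts for one circle/stage."""

    locus: CircLocus
    stage: str
    bsj_reads: int
    linear_up_reads: int
    linear_down_reads: int

    def __post_init__(self) -> None:
        if min(self.bsj_reads, self.linear_up_reads, self.linear_down_reads) < 0:
            raise ValueError("junction counts must be >= 0")


@dataclass(frozen=True)
class ChainAlignment:
    """One UCSC chain: a gapped block alignment from source to target assembly.

    Target (query) coordinates follow the chain convention: positions are on
    the ``t_strand`` strand, i.e. counted from the far end when ``t_strand``
    is '-'.
    """

    chain_id: str
    score: int
    s_chrom: str
    s_size: int
    s_start: int
    s_end: int
    t_chrom: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    blocks: tuple  # of (source_start, target_start, size), both ascending

    def __post_init__(self) -> None:
        prev_s = prev_t = -1
        for (ss, ts, size) in self.blocks:
            if size <= 0:
                raise ValueError(f"chain {self.chain_id}: non-positive block size")
            if ss < prev_s or ts < prev_t:
                raise ValueError(f"chain {self.chain_id}: blocks not ascending")
            prev_s, prev_t = ss + size, ts + size
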