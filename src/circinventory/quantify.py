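"""RPM expression, circular-to-linear ratios, top-N selection and >2-fold
differential calls across stages.

The expression matrix is a pandas DataFrame with one row per locus (indexed
by the locus key ``chrom:start-end:strand``) and one column per stage,
holding RPM values from the designated quantifier tool's untreated (mock)
libraries.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, List, Optional, Set

import numpy as np
import pandas as pd

from .consensus import ConsensusRecord
from .model import JunctionQuant, LibraryMeta, STAGES


def rpm(count: float, total_mapped_reads: float) -> float:
    """Reads per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    return count / total_mapped_reads * 1e6


def circ_linear_ratio(q: JunctionQuant) -> float:
    """Circular fraction of splicing: bsj / (bsj + mean(up, down)).

    Returns NaN (missing) when all three counts are zero — an undetected
    locus carries no ratio information and a 0 would bias distributions.
    """
    linear_mean = (q.linear_up_reads + q.linear_down_reads) / 2.0
    denom = q.bsj_reads + linear_mean
    if denom == 0:
        return math.nan
    return q.bsj_reads / denom


def expression_matrix(records: Iterable[ConsensusRecord], metas: List[LibraryMeta],
                      source_tool: str = "ciri2", treatment: str = "mock",
                      only_bona_fide: bool = True,
                      stages: Optional[tuple] = None) -> pd.DataFrame:
    """Loci x stages RPM matrix from the quantifier tool's libraries."""
    stages = stages or tuple(
        st for st in STAGES if any(m.stage == st for m in metas)) or tuple(
        sorted({m.stage for m in metas}))
    libs = {st: [m for m in metas if m.stage == st and m.treatment == treatment]
            for st in stages}
    for st, ms in libs.items():
        if not ms:
            raise ValueError(f"no {treatment!r} library for stage {st!r}")
    rows = {}
    for rec in records:
        if only_bona_fide and not rec.bona_fide:
            continue
        rows[rec.locus.key] = [
            rpm(sum(rec.count(source_tool, m.sample_id) for m in libs[st]),
                sum(m.total_mapped_reads for m in libs[st]))
            for st in stages]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(stages))


_RANK_STATS = {
    "max": lambda df: df.max(axis=1),
    "mean": lambda df: df.mean(axis=1),
    "sum": lambda df: df.sum(axis=1),
}


def top_n(matrix: pd.DataFrame, n: int = 100, stat: str = "max") -> pd.DataFrame:
    """Top-n rows by the chosen per-row statistic, ties broken by locus key.

    The default statistic is the maximum across stages, so stage-specific
    circles peaking in a single stage are not suppressed relative to flat
    profiles.
    """
    if stat not in _RANK_STATS:
        raise ValueError(f"unknown ranking stat {stat!r}")
    if n > len(matrix):
        warnings.warn(f"requested top {n} of {len(matrix)} rows; returning all")
        n = len(matrix)
    score = _RANK_STATS[stat](matrix)
    order = sorted(matrix.index, key=lambda k: (-score[k], k))
    return matrix.loc[order[:n]]


def differential(matrix: pd.DataFrame, fold: float = 2.0,
                 pseudocount: float = 0.1) -> Set[str]:
    """Loci whose RPM changes more than ``fold`` between any two stages.

    A locus is differential iff max over ordered stage pairs (i, j) of
    (RPM_i + pc) / (RPM_j + pc) strictly exceeds ``fold``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("differential needs >= 2 stages")
    vals = matrix.to_numpy(dtype=float) + pseudocount
    ratio = vals.max(axis=1) / vals.min(axis=1)
    return set(matrix.index[ratio > fold])


def ratio_table(quants: Iterable[JunctionQuant]) -> pd.DataFrame:
    """Per locus/stage circular-to-linear ratios (NaN where undefined)."""
    rows = [(q.locus.key, q.stage, q.bsj_reads, q.linear_up_reads,
             q.linear_down_reads, circ_linear_ratio(q)) for q in quants]
    return pd.DataFrame(rows, columns=["locus", "stage", "bsj_reads",
                                       "linear_up_reads", "linear_down_reads",
                                       "circ_linear_ratio"])
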