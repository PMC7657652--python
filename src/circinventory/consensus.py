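"""Cross-predictor merging, RNase-R response classification and the bona
fide inventory.

A locus enters the high-confidence inventory only if (i) all three
predictors called it somewhere in the dataset and (ii) its depth-normalized
backsplice reads are at least ``fold_threshold`` times higher after RNase R
treatment — the hallmark of an exonuclease-resistant, genuinely circular
species. Loci that instead lose >= 1/depletion-fold of their signal are
classified depleted and treated as linear false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from .model import (
    CircLocus,
    ClassificationError,
    LibraryMeta,
    PREDICTORS,
    PredictorCall,
)

ENRICHED = "enriched"
DEPLETED = "depleted"
CONSTANT = "constant"


@dataclass
class EnrichmentParams:
    fold_threshold: float = 3.0        # inclusive: fold >= 3 is enriched
    depletion_threshold: float = 1.0 / 3.0
    pseudocount: float = 0.5           # added on the per-million scale
    scope: str = "any_stage"           # or "pooled"

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1.0:
            raise ValueError("fold_threshold must be > 1")
        if not (0.0 < self.depletion_threshold < 1.0):
            raise ValueError("depletion_threshold must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.scope not in ("any_stage", "pooled"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass
class ConsensusRecord:
    locus: CircLocus
    detected_by: FrozenSet[str]
    counts: Dict[Tuple[str, str], int]  # (predictor, sample_id) -> summed reads
    stage_class: Dict[str, str] = field(default_factory=dict)
    overall_class: Optional[str] = None
    bona_fide: bool = False

    def count(self, predictor: str, sample_id: str) -> int:
        return self.counts.get((predictor, sample_id), 0)


def merge_calls(calls: Iterable[PredictorCall], metas: List[LibraryMeta],
                slop: int = 0) -> List[ConsensusRecord]:
    """Group calls by exact locus identity into pre-classification records.

    Same-key calls from one predictor within one sample are summed. With
    ``slop > 0`` loci on the same chromosome/strand whose starts and ends
    each differ by at most ``slop`` bp are clustered onto the
    best-supported representative before grouping (off by default; exact
    matching is the reproducible policy).
    """
    calls = list(calls)
    known = {m.sample_id for m in metas}
    for c in calls:
        if c.sample_id not in known:
            raise ValueError(f"call references unknown sample {c.sample_id!r}")
    if slop > 0:
        calls = _apply_slop(calls, slop)
    grouped: Dict[CircLocus, ConsensusRecord] = {}
    for c in calls:
        rec = grouped.get(c.locus)
        if rec is None:
            rec = ConsensusRecord(c.locus, frozenset(), {})
            grouped[c.locus] = rec
        key = (c.predictor, c.sample_id)
        rec.counts[key] = rec.counts.get(key, 0) + c.bsj_reads
        rec.detected_by = rec.detected_by | {c.predictor}
    return [grouped[k] for k in sorted(grouped)]


def _apply_slop(calls: List[PredictorCall], slop: int) -> List[PredictorCall]:
    """Cluster near-identical loci and rewrite calls onto representatives."""
    by_group: Dict[Tuple[str, str], List[CircLocus]] = {}
    support: Dict[CircLocus, int] = {}
    for c in calls:
        support[c.locus] = support.get(c.locus, 0) + c.bsj_reads
    for loc in support:
        by_group.setdefault((loc.chrom, loc.strand), []).append(loc)
    rep: Dict[CircLocus, CircLocus] = {}
    for _, loci in by_group.items():
        loci.sort()
        # single-linkage clustering along the sorted order
        clusters: List[List[CircLocus]] = []
        for loc in loci:
            placed = False
            for cl in clusters:
                if any(abs(loc.start - o.start) <= slop
                       and abs(loc.end - o.end) <= slop for o in cl):
                    cl.append(loc)
                    placed = True
                    break
            if not placed:
                clusters.append([loc])
        for cl in clusters:
            best = max(cl, key=lambda l: (support[l], l.key))
            for loc in cl:
                rep[loc] = best
    return [PredictorCall(rep[c.locus], c.predictor, c.sample_id, c.bsj_reads,
                          extras=c.extras) for c in calls]


def _stage_libraries(metas: List[LibraryMeta]) -> Dict[str, Dict[str, List[LibraryMeta]]]:
    out: Dict[str, Dict[str, List[LibraryMeta]]] = {}
    for m in metas:
        out.setdefault(m.stage, {}).setdefault(m.treatment, []).append(m)
    return out


def classify_rnaser(record: ConsensusRecord, params: EnrichmentParams,
                    metas: List[LibraryMeta], quantifier: str = "ciri2"
                    ) -> ConsensusRecord:
    """Assign per-stage and overall RNase-R response classes to one record.

    Folds are computed on per-million-normalized counts of the designated
    quantifier tool, with a pseudocount guarding zero mock counts. A stage
    with no detection by any tool in either library is skipped; a record
    with no usable stage at all raises ``ClassificationError``.
    """
    stages = _stage_libraries(metas)
    record.stage_class = {}
    usable = 0
    pooled_mock = pooled_rn = 0.0
    for stage, by_treat in stages.items():
        mocks = by_treat.get("mock", [])
        rnasers = by_treat.get("rnaser", [])
        if not mocks or not rnasers:
            continue
        usable += 1
        detected = any(
            record.count(tool, m.sample_id) > 0
            for tool in PREDICTORS for m in mocks + rnasers)
        if not detected:
            continue
        n_mock = _normalized(record, quantifier, mocks)
        n_rn = _normalized(record, quantifier, rnasers)
        pooled_mock += n_mock
        pooled_rn += n_rn
        fold = (n_rn + params.pseudocount) / (n_mock + params.pseudocount)
        record.stage_class[stage] = _classify_fold(fold, params)
    if usable == 0:
        raise ClassificationError(
            f"{record.locus.key}: no stage has both a mock and an RNase-R library")
    if params.scope == "pooled":
        if record.stage_class:
            fold = (pooled_rn + params.pseudocount) / (pooled_mock + params.pseudocount)
            record.overall_class = _classify_fold(fold, params)
        else:
            record.overall_class = None
    else:
        classes = set(record.stage_class.values())
        if not classes:
            record.overall_class = None
        elif DEPLETED in classes:
            record.overall_class = DEPLETED
        elif ENRICHED in classes:
            record.overall_class = ENRICHED
        else:
            record.overall_class = CONSTANT
    return record


def _normalized(record: ConsensusRecord, quantifier: str,
                libs: List[LibraryMeta]) -> float:
    count = sum(record.count(quantifier, m.sample_id) for m in libs)
    total = sum(m.total_mapped_reads for m in libs)
    return count / total * 1e6


def _classify_fold(fold: float, params: EnrichmentParams) -> str:
    if fold >= params.fold_threshold:
        return ENRICHED
    if fold <= params.depletion_threshold:
        return DEPLETED
    return CONSTANT


def build_inventory(calls: Iterable[PredictorCall], metas: List[LibraryMeta],
                    params: Optional[EnrichmentParams] = None,
                    quantifier: str = "ciri2", slop: int = 0
                    ) -> Tuple[List[ConsensusRecord], dict]:
    """Merge, classify and flag bona fide circles; emit a summary report.

    The report carries per-tool/per-stage call totals, per-tool depleted
    fractions, and the predictor intersection (Venn) over constant-or-
    enriched loci, mirroring how a sequencing-based inventory is summarized.
    """
    params = params or EnrichmentParams()
    records = merge_calls(calls, metas, slop=slop)
    all_three = frozenset(PREDICTORS)
    for rec in records:
        classify_rnaser(rec, params, metas, quantifier=quantifier)
        rec.bona_fide = (rec.detected_by == all_three
                         and rec.overall_class == ENRICHED)
    summary = summarize_inventory(records, metas, params)
    summary["params"] = {
        "fold_threshold": params.fold_threshold,
        "depletion_threshold": params.depletion_threshold,
        "pseudocount": params.pseudocount,
        "scope": params.scope,
        "quantifier": quantifier,
        "detected_by_scope": "union_across_stages",
        "slop": slop,
    }
    return records, summary


def summarize_inventory(records: List[ConsensusRecord],
                        metas: List[LibraryMeta],
                        params: Optional[EnrichmentParams] = None) -> dict:
    params = params or EnrichmentParams()
    stages = sorted({m.stage for m in metas})
    by_stage = _stage_libraries(metas)
    mock_by_stage = {st: by_stage.get(st, {}).get("mock", []) for st in stages}
    rn_by_stage = {st: by_stage.get(st, {}).get("rnaser", []) for st in stages}
    per_tool_stage: Dict[str, Dict[str, int]] = {p: {} for p in PREDICTORS}
    depleted_fraction: Dict[str, Dict[str, float]] = {p: {} for p in PREDICTORS}
    for tool in PREDICTORS:
        for st in stages:
            called = [r for r in records
                      if any(r.count(tool, m.sample_id) > 0 for m in mock_by_stage[st])]
            per_tool_stage[tool][st] = len(called)
            if not called or not rn_by_stage[st]:
                depleted_fraction[tool][st] = float("nan")
                continue
            # each algorithm's RNase-R response is judged on its own counts
            n_depleted = 0
            for r in called:
                fold = ((_normalized(r, tool, rn_by_stage[st]) + params.pseudocount)
                        / (_normalized(r, tool, mock_by_stage[st]) + params.pseudocount))
                n_depleted += _classify_fold(fold, params) == DEPLETED
            depleted_fraction[tool][st] = n_depleted / len(called)
    kept = [r for r in records if r.overall_class in (CONSTANT, ENRICHED)]
    venn: Dict[str, int] = {}
    for r in kept:
        key = "&".join(sorted(r.detected_by))
        venn[key] = venn.get(key, 0) + 1
    return {
        "n_merged_loci": len(records),
        "per_tool_stage_calls": per_tool_stage,
        "per_tool_depleted_fraction": depleted_fraction,
        "n_constant_or_enriched": len(kept),
        "venn_constant_or_enriched": venn,
        "n_all_three": sum(r.detected_by == frozenset(PREDICTORS) for r in kept),
        "n_bona_fide": sum(r.bona_fide for r in records),
        "class_counts": {
            cls: sum(r.overall_class == cls for r in records)
            for cls in (ENRICHED, CONSTANT, DEPLETED)},
    }


def write_inventory(records: List[ConsensusRecord], metas: List[LibraryMeta],
                    path: str) -> None:
    import pandas as pd

    sample_ids = [m.sample_id for m in metas]
    rows = []
    for r in records:
        row = {"chrom": r.locus.chrom, "start": r.locus.start,
               "end": r.locus.end, "strand": r.locus.strand,
               "detected_by": ",".join(sorted(r.detected_by)),
               "overall_class": r.overall_class or "",
               "bona_fide": int(r.bona_fide)}
        for st, cls in sorted(r.stage_class.items()):
            row[f"class_{st}"] = cls
        for tool in PREDICTORS:
            for sid in sample_ids:
                row[f"{tool}.{sid}"] = r.count(tool, sid)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
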