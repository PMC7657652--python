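"""Parsers and writers for the three predictor dialects, gene models and chains.

All parsers normalize to the internal 0-based half-open convention:

* find_circ emits BED-derived coordinates that are already half-open;
* CIRI2 reports 1-based inclusive ``circRNA_start``/``circRNA_end`` and is
  shifted at the boundary (start−1, end);
* GTF exons are 1-based inclusive and shifted the same way; BED12 is not.

Column layouts are frozen to the versions used in the analysis (CIRI2
v2.0.6, CIRCexplorer2 v2.3.3 era); upstream layouts drift between versions,
so these dialects are documented in the README rather than sniffed.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, List, Optional

import pandas as pd

from .model import (
    ChainAlignment,
    CircLocus,
    GeneModel,
    LibraryMeta,
    ParseError,
    PredictorCall,
)

FINDCIRC_MAPQ_MIN = 40  # stringent mapq cut applied to both anchor qualities

# frozen column layouts
FINDCIRC_COLS = ("chrom", "start", "end", "name", "n_reads", "strand",
                 "best_qual_left", "best_qual_right")
CIRI2_COLS = ("circRNA_ID", "chr", "circRNA_start", "circRNA_end",
              "junction_reads", "circRNA_type", "gene_id", "strand")
CE2_N_COLS = 13  # BED12 + readNumber


def _sample_from_path(path: str) -> str:
    return os.path.splitext(os.path.basename(path))[0]


def _int_field(value: str, column: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: column {column!r} is not an integer: {value!r}") from exc


def parse_findcirc(path: str, sample_id: Optional[str] = None) -> List[PredictorCall]:
    """Parse a find_circ sites table (BED-like TSV, one file per library).

    Rows carrying anchor mapping qualities below 40 are dropped; the filter
    only applies when the quality columns are present, since find_circ can be
    run with the cut applied internally (in which case it is redundant here).
    """
    sample = sample_id or _sample_from_path(path)
    calls: List[PredictorCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                missing = FINDCIRC_COLS[len(fields)]
                raise ParseError(f"line {lineno}: missing required column {missing!r}")
            chrom, start, end, name, n_reads, strand = fields[:6]
            reads = _int_field(n_reads, "n_reads", lineno)
            if reads < 0:
                raise ParseError(f"line {lineno}: negative read count {reads}")
            if len(fields) >= 8:
                qual = min(_int_field(fields[6], "best_qual_left", lineno),
                           _int_field(fields[7], "best_qual_right", lineno))
                if qual < FINDCIRC_MAPQ_MIN:
                    continue
            try:
                locus = CircLocus(chrom, _int_field(start, "start", lineno),
                                  _int_field(end, "end", lineno), strand)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            calls.append(PredictorCall(locus, "find_circ", sample, reads,
                                       extras={"name": name}))
    return calls


def write_findcirc(calls: Iterable[PredictorCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(FINDCIRC_COLS) + "\n")
        for c in calls:
            qual = c.extras.get("mapq", 40)
            fh.write("\t".join(map(str, (
                c.locus.chrom, c.locus.start, c.locus.end,
                c.extras.get("name", c.locus.key), c.bsj_reads, c.locus.strand,
                qual, qual))) + "\n")


def parse_ciri2(path: str, sample_id: Optional[str] = None) -> List[PredictorCall]:
    """Parse a CIRI2 prediction table (headered TSV, 1-based inclusive coords)."""
    sample = sample_id or _sample_from_path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    df.columns = [c.lstrip("#") for c in df.columns]
    for col in ("chr", "circRNA_start", "circRNA_end", "junction_reads", "strand"):
        if col not in df.columns:
            raise ParseError(f"CIRI2 table missing required column {col!r}")
    calls: List[PredictorCall] = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        reads = _int_field(row.junction_reads, "junction_reads", i)
        if reads < 0:
            raise ParseError(f"line {i}: negative junction_reads {reads}")
        start1 = _int_field(row.circRNA_start, "circRNA_start", i)
        end1 = _int_field(row.circRNA_end, "circRNA_end", i)
        try:
            locus = CircLocus(row.chr, start1 - 1, end1, row.strand)
        except ValueError as exc:
            raise ParseError(f"line {i}: {exc}") from exc
        extras = {}
        if hasattr(row, "circRNA_type"):
            extras["circRNA_type"] = row.circRNA_type
        if hasattr(row, "gene_id"):
            extras["gene_id"] = row.gene_id
        calls.append(PredictorCall(locus, "ciri2", sample, reads, extras=extras))
    return calls


def write_ciri2(calls: Iterable[PredictorCall], path: str) -> None:
    rows = []
    for c in calls:
        rows.append((f"{c.locus.chrom}:{c.locus.start + 1}|{c.locus.end}",
                     c.locus.chrom, c.locus.start + 1, c.locus.end, c.bsj_reads,
                     c.extras.get("circRNA_type", "exon"),
                     c.extras.get("gene_id", "n/a"), c.locus.strand))
    pd.DataFrame(rows, columns=list(CIRI2_COLS)).to_csv(path, sep="\t", index=False)


def parse_circexplorer2(path: str, sample_id: Optional[str] = None) -> List[PredictorCall]:
    """Parse a CIRCexplorer2 table (BED12-derived, 13th column = readNumber)."""
    sample = sample_id or _sample_from_path(path)
    calls: List[PredictorCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < CE2_N_COLS:
                raise ParseError(
                    f"line {lineno}: expected >= {CE2_N_COLS} columns "
                    f"(BED12 + 'readNumber'), got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: strand is required, got {strand!r}")
            reads = _int_field(fields[12], "readNumber", lineno)
            if reads < 0:
                raise ParseError(f"line {lineno}: negative readNumber {reads}")
            try:
                locus = CircLocus(chrom, _int_field(start, "start", lineno),
                                  _int_field(end, "end", lineno), strand)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            calls.append(PredictorCall(locus, "circexplorer2", sample, reads,
                                       extras={"name": name}))
    return calls


def write_circexplorer2(calls: Iterable[PredictorCall], path: str) -> None:
    with open(path, "w") as fh:
        for c in calls:
            span = c.locus.span
            fh.write("\t".join(map(str, (
                c.locus.chrom, c.locus.start, c.locus.end,
                c.extras.get("name", "circular_RNA"), 0, c.locus.strand,
                c.locus.start, c.locus.end, "0,0,0", 1, span, 0,
                c.bsj_reads))) + "\n")


PARSERS = {
    "find_circ": parse_findcirc,
    "ciri2": parse_ciri2,
    "circexplorer2": parse_circexplorer2,
}
WRITERS = {
    "find_circ": write_findcirc,
    "ciri2": write_ciri2,
    "circexplorer2": write_circexplorer2,
}


# ---------------------------------------------------------------------------
# library metadata

def parse_meta(path: str) -> List[LibraryMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "stage", "treatment", "total_mapped_reads"):
        if col not in df.columns:
            raise ParseError(f"meta table missing required column {col!r}")
    return [LibraryMeta(r.sample_id, r.stage, r.treatment, int(r.total_mapped_reads))
            for r in df.itertuples(index=False)]


def write_meta(metas: Iterable[LibraryMeta], path: str) -> None:
    pd.DataFrame(
        [(m.sample_id, m.stage, m.treatment, m.total_mapped_reads) for m in metas],
        columns=["sample_id", "stage", "treatment", "total_mapped_reads"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models

def _is_gtf(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            return len(fields) == 9 and "gene_id" in fields[8]
    return False


def _parse_gtf_genes(path: str) -> List[GeneModel]:
    import gffutils.feature

    exons: dict = {}
    spans: dict = {}
    strands: dict = {}
    chroms: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            feat = gffutils.feature.feature_from_line(line.rstrip("\n"))
            gid = feat.attributes.get("gene_id", [None])[0]
            if gid is None:
                raise ParseError("GTF feature without gene_id attribute")
            if feat.strand not in ("+", "-"):
                raise ParseError(f"gene {gid}: unknown strand {feat.strand!r}")
            if feat.featuretype == "gene":
                spans[gid] = (feat.start - 1, feat.end)
            elif feat.featuretype == "exon":
                exons.setdefault(gid, []).append((feat.start - 1, feat.end))
                strands[gid] = feat.strand
                chroms[gid] = feat.seqid
    genes = []
    for gid, ex in exons.items():
        if gid in spans:
            lo, hi = spans[gid]
            clamped = []
            for (s, e) in ex:
                if s < lo or e > hi:
                    warnings.warn(
                        f"gene {gid}: exon ({s}, {e}) outside declared span; clamped")
                    s, e = max(s, lo), min(e, hi)
                if e > s:
                    clamped.append((s, e))
            ex = clamped
        genes.append(GeneModel(gid, chroms[gid], strands[gid], _merge_exons(ex)))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _merge_exons(exons: list) -> tuple:
    """Union of (possibly isoform-redundant) exon intervals."""
    merged: list = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def _parse_bed12_genes(path: str) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"line {lineno}: BED12 requires 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: unknown strand {strand!r}")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets) or len(sizes) != int(f[9]):
                raise ParseError(f"line {lineno}: blockCount mismatch")
            exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
            genes.append(GeneModel(name, chrom, strand, _merge_exons(list(exons))))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def parse_gene_models(path: str) -> List[GeneModel]:
    """Parse gene annotation from GTF (exons grouped by gene_id) or BED12."""
    if _is_gtf(path):
        return _parse_gtf_genes(path)
    return _parse_bed12_genes(path)


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "circinventory") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.gene_id}";'
            fh.write("\t".join(map(str, (
                g.chrom, source, "gene", g.start + 1, g.end, ".", g.strand, ".",
                attr))) + "\n")
            for (s, e) in g.exons:
                fh.write("\t".join(map(str, (
                    g.chrom, source, "exon", s + 1, e, ".", g.strand, ".",
                    attr))) + "\n")


# ---------------------------------------------------------------------------
# UCSC chain files

def parse_chain(path: str) -> List[ChainAlignment]:
    """Parse a UCSC chain file into block alignments.

    The ``t`` fields of the header are the source assembly and ``q`` the
    target, as in liftOver chains (mm10ToHg19: t = mm10, q = hg19). Declared
    interval sizes are checked against the block/gap sums.
    """
    chains: List[ChainAlignment] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise ParseError(f"expected chain header, got {line!r}")
        h = line.split()
        if len(h) < 12:
            raise ParseError(f"malformed chain header: {line!r}")
        score = int(h[1])
        s_chrom, s_size, s_strand = h[2], int(h[3]), h[4]
        s_start, s_end = int(h[5]), int(h[6])
        t_chrom, t_size, t_strand = h[7], int(h[8]), h[9]
        t_start, t_end = int(h[10]), int(h[11])
        chain_id = h[12] if len(h) > 12 else str(len(chains) + 1)
        if s_strand != "+":
            raise ParseError(f"chain {chain_id}: source strand must be '+'")
        blocks = []
        src, tgt = s_start, t_start
        closed = False
        while i < n:
            row = lines[i].strip()
            i += 1
            if not row:
                break
            parts = row.split()
            size = int(parts[0])
            blocks.append((src, tgt, size))
            if len(parts) == 1:
                closed = True
                src += size
                tgt += size
                break
            if len(parts) != 3:
                raise ParseError(f"chain {chain_id}: malformed alignment line {row!r}")
            dt, dq = int(parts[1]), int(parts[2])
            src += size + dt
            tgt += size + dq
        if not closed:
            raise ParseError(f"chain {chain_id}: truncated (no terminal block)")
        if src != s_end or tgt != t_end:
            raise ParseError(
                f"chain {chain_id}: block sums ({src}, {tgt}) do not match "
                f"declared ends ({s_end}, {t_end})")
        chains.append(ChainAlignment(chain_id, score, s_chrom, s_size, s_start,
                                     s_end, t_chrom, t_size, t_strand, t_start,
                                     t_end, tuple(blocks)))
    return chains


def write_chain(chains: Iterable[ChainAlignment], path: str) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f"chain {c.score} {c.s_chrom} {c.s_size} + {c.s_start} "
                     f"{c.s_end} {c.t_chrom} {c.t_size} {c.t_strand} "
                     f"{c.t_start} {c.t_end} {c.chain_id}\n")
            for j, (ss, ts, size) in enumerate(c.blocks):
                if j + 1 < len(c.blocks):
                    ns, nt, _ = c.blocks[j + 1]
                    fh.write(f"{size}\t{ns - ss - size}\t{nt - ts - size}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# generic outputs

def write_bed6(loci: Iterable[CircLocus], path: str, scores: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            score = 0 if scores is None else scores.get(loc, 0)
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.key}\t{score}\t{loc.strand}\n")


def parse_bed6_loci(path: str) -> List[CircLocus]:
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"line {lineno}: BED6 requires 6 columns")
            loci.append(CircLocus(f[0], int(f[1]), int(f[2]), f[5]))
    return loci


def parse_junctions(path: str) -> list:
    from .model import JunctionQuant

    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ("chrom", "start", "end", "strand", "stage", "bsj_reads",
              "linear_up_reads", "linear_down_reads")
    for col in needed:
        if col not in df.columns:
            raise ParseError(f"junction table missing required column {col!r}")
    return [
        JunctionQuant(CircLocus(r.chrom, int(r.start), int(r.end), r.strand),
                      r.stage, int(r.bsj_reads), int(r.linear_up_reads),
                      int(r.linear_down_reads))
        for r in df.itertuples(index=False)
    ]


def write_junctions(quants: Iterable, path: str) -> None:
    pd.DataFrame(
        [(q.locus.chrom, q.locus.start, q.locus.end, q.locus.strand, q.stage,
          q.bsj_reads, q.linear_up_reads, q.linear_down_reads) for q in quants],
        columns=["chrom", "start", "end", "strand", "stage", "bsj_reads",
                 "linear_up_reads", "linear_down_reads"],
    ).to_csv(path, sep="\t", index=False)
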