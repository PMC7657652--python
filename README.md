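# circinventory

Tools for building **high-confidence circular RNA (circRNA) inventories**
from multi-caller backsplice-junction predictions, and for the companion
assay computations (RT-qPCR X₀ quantification, BrU pulse-chase decay
kinetics) that accompany such studies.

circRNAs are covalently closed transcripts produced by backsplicing: a
downstream 5′ splice donor joins an upstream 3′ acceptor, and reads spanning
that non-colinear backsplice junction (BSJ) are the unit of detection and
quantification. Junction callers disagree with each other and all emit false
positives, so a robust inventory combines two orthogonal filters:

1. **Consensus** — a locus must be called by all three of find_circ, CIRI2
   and CIRCexplorer2 (their *outputs* are parsed; the callers themselves are
   not re-implemented).
2. **Exonuclease resistance** — libraries are sequenced with and without
   RNase R, a 3′→5′ exoribonuclease that degrades linear RNA but spares
   circles. A locus qualifies as *bona fide* only if its depth-normalized
   BSJ reads are enriched at least 3-fold after RNase R treatment
   (fold = (RPM_RNaseR + c) / (RPM_mock + c), pseudocount c = 0.5);
   loci at ≤ 1/3 are classified depleted, i.e. linear false positives.

Around that core the package provides, as library functions and a CLI:

* parsers/writers for the three caller dialects, GTF/BED12 gene models and
  UCSC chain files — all normalized to 0-based half-open coordinates
  (`ingest`);
* merge + RNase-R classification + inventory summary (`consensus`);
* RPM expression matrices, circular-to-linear splice ratios
  `bsj / (bsj + (up + down)/2)`, top-N selection, and >2-fold differential
  calls across stages (`quantify`);
* in-repo k-means (kmeans++ + Lloyd, best-of-restarts by within-cluster sum
  of squares) for stage-profile clustering of the top-expressed circles
  (`profiles`);
* host-gene assignment (a gene sharing ≥ 1 splice site with the circle, on
  the same strand), exon/flanking-intron metrics, 5′ positional bias, and
  chain-based cross-assembly lifting where only loci with both endpoints in
  aligned blocks of one chain count as homologs (`annotate`);
* X₀ relative qPCR levels `E^(Cq_ref − Cq_target)`, log-linear decay fits
  with half-life ln2/k, BrU-IP synthesis fold changes, and the F-test-gated
  two-sample t-test convention (`kinetics`);
* a synthetic-data generator (`simdata`) that emulates the whole study —
  three differentiation stages (mESC, NPC, mN8) × two treatments, true
  circles vs. linear artifacts, five stage-expression archetypes, and
  per-caller error profiles — so every downstream stage is testable against
  a known truth set.

## Worked example

```bash
circinventory simulate --seed 7 --out data
circinventory consensus \
    --calls find_circ=data/calls/find_circ \
    --calls ciri2=data/calls/ciri2 \
    --calls circexplorer2=data/calls/circexplorer2 \
    --meta data/meta.tsv --out inv
# -> 893 merged loci, 300 bona fide
circinventory quantify --calls find_circ=data/calls/find_circ \
    --calls ciri2=data/calls/ciri2 --calls circexplorer2=data/calls/circexplorer2 \
    --meta data/meta.tsv --junctions data/junctions.tsv --top 100 --out q
# -> 300 bona fide loci, 269 differential (> 2.0-fold)
circinventory cluster --matrix q.top100.tsv --k 5 --seed 17 --out cl
# -> k=5: wcss=16.0939 after 3 iterations
```

The simulated study placed 300 true circles and 150 linear artifacts; the
consensus + 3-fold filter recovered exactly the 300 circles as bona fide
while the artifacts (RNase-R fold ≈ 0.2) were rejected. Of the bona fide
set, 269 circles change more than 2-fold between stages, and the top-100
z-scored stage profiles partition into 5 clusters with a WCSS of ≈ 16.

The same analysis is available programmatically:

```python
from circinventory import simdata, build_inventory, expression_matrix

truth, libs = simdata.simulate_dataset(simdata.SimConfig(seed=7))
calls = [c for tool in libs.calls.values() for c in tool]
records, summary = build_inventory(calls, libs.metas)
matrix = expression_matrix(records, libs.metas)   # loci x stages, RPM
```

Decay fitting and qPCR on TSV tables:

```bash
circinventory decay --series decay.tsv   # RARA  k=0.2298/h  half-life=3.02 h  r2=0.998
circinventory qpcr  --cq cq.tsv          # kd  0.2333
```

## File formats

* **find_circ**: BED-like TSV `chrom start end name n_reads strand
  [best_qual_left best_qual_right]`; rows with an anchor quality < 40 are
  dropped when the columns are present.
* **CIRI2**: headered TSV with `chr`, `circRNA_start`/`circRNA_end`
  (1-based inclusive, converted on input), `junction_reads`, `strand`.
* **CIRCexplorer2**: BED12 plus a 13th `readNumber` column.
* **meta**: TSV `sample_id stage treatment total_mapped_reads`
  (treatment ∈ `mock`, `rnaser`).
* **junctions**: TSV `chrom start end strand stage bsj_reads
  linear_up_reads linear_down_reads`.
* Gene models: GTF (exons grouped by `gene_id`) or BED12; lifting uses UCSC
  chain files.

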