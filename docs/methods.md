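# Methods

This note documents the models, conventions and numerical choices behind
`circinventory`, in the spirit of the methods documentation of packages
like statsmodels or msprime: what is computed, under which assumptions, and
where a genuinely open design point was resolved by a documented choice.

## Coordinates and identity

All genomic intervals are 0-based half-open `[start, end)` on the forward
strand. CIRI2 tables (1-based inclusive) and GTF (1-based inclusive) are
converted once, at the parsing boundary. A circRNA is identified by the
exact tuple (chromosome, start, end, strand) of its backsplice junction;
merging across callers uses this exact key. No coordinate tolerance is
applied by default because exact matching is the only fully reproducible
policy; a `slop` mode (single-linkage clustering of loci whose starts and
ends each differ by at most N bp, rewritten onto the best-supported
representative) exists for callers with known off-by-one behavior, off by
default. Chromosome names are taken verbatim; no "chr" normalization.

## Consensus inventory and RNase-R classification

Calls from find_circ, CIRI2 and CIRCexplorer2 are merged per locus;
duplicate calls within one (caller, library) are summed. The find_circ
anchor-quality filter (both anchors ≥ 40) is applied at parse time whenever
the quality columns are present; when find_circ was already run with the
cut applied internally the filter is redundant but harmless.

RNase-R response per stage is the fold
`(RPM_RNaseR + c) / (RPM_mock + c)` with pseudocount `c = 0.5` RPM
computed on per-million-normalized counts of a designated quantifier tool
(default CIRI2, since expression is quantified from its counts).
Normalization by each library's total mapped reads is required because the
mock and RNase-R libraries are sequenced separately; the raw fold would
otherwise depend on depth ratios. The classification thresholds are
fold ≥ 3 (inclusive) → *enriched*, fold ≤ 1/3 → *depleted*, otherwise
*constant*.

Two points are underdetermined by the headline "3-fold enrichment" rule and
were resolved as follows:

* **Scope.** Default `any_stage`: a locus is overall *enriched* if at least
  one stage is enriched and none is depleted; *depleted* anywhere vetoes.
  A `pooled` scope (single fold on stage-summed normalized counts) is
  available. Stages with no detection by any caller in either library are
  skipped.
* **Consensus scope.** "Detected by all three callers" is evaluated across
  the union of libraries: a locus found by different tools in different
  stages still qualifies. The summary report records both choices.

A locus is **bona fide** iff detected by all three callers and overall
enriched. The per-caller depletion fractions in the summary are computed
from each caller's *own* reported counts (they describe the caller's
RNase-R response, not the quantifier's).

## Quantification

* RPM = count / total_mapped_reads × 10⁶.
* Circular-to-linear ratio = `bsj / (bsj + (up + down)/2)` from find_circ
  style junction counts; an all-zero locus yields a missing value rather
  than 0 so ratio distributions are not deflated by undetected loci.
* Top-N selection ranks by **maximum stage RPM** (ties broken by locus key).
  Mean- or sum-ranking are available but suppress stage-specific circles
  relative to flat ones, which is the wrong default for profiles that peak
  at different stages.
* Differential loci: max over ordered stage pairs of
  `(RPM_i + 0.1) / (RPM_j + 0.1)` strictly greater than the fold cut
  (default 2). The 0.1 RPM pseudocount keeps absent-in-one-stage loci from
  producing infinite folds. No variance model is used — the criterion is a
  fold threshold by design.

## Stage-profile clustering

Rows are transformed `log2(RPM + 1)` then z-scored per row (sample sd,
ddof 1; zero-variance rows become zero vectors). Clustering raw RPM would
group by magnitude; the z-scored log profiles cluster by *shape*, which is
what stage-expression archetypes are. Distance is Euclidean.

k-means is implemented in-repo: kmeans++ seeding, Lloyd iterations, best of
50 restarts by WCSS, convergence at a relative objective change ≤ 1e-6,
maximum 300 iterations, empty clusters reseeded from the point farthest
from its centroid. The per-iteration objective is asserted non-increasing
inside the loop. Results are deterministic given a seed, and cluster labels
are canonicalized by centroid peak stage (earliest-peaking first, then
higher peak) so labellings are comparable across runs. The choice k = 5
follows the five observed archetype shapes; `wcss_curve` provides the elbow
diagnostic used to justify it.

## Host genes, structure and homology lifting

A host candidate lies on the circle's chromosome **and strand** (the
backsplice reuses the host's own splice sites, so opposite-strand
assignment would be incoherent) and shares ≥ 1 splice site: circle start =
some exon start, or circle end = some exon end. Candidates are ranked by
shared sites, then overlap length, then gene id — a total order, so
assignment is independent of input order. Reported metrics: exons fully
inside the circle; the genomic introns immediately outside the matched
boundary exons (missing at terminal exons); and the relative position of
the circle's transcript-first boundary exon, `i/(n−1)` with exon index i
counted from the transcript 5′ end (0 = 5′ end). On minus-strand genes the
transcript-first exon is the one matching the genomic end coordinate. Under
uniform placement this statistic is centered at 0.5, which is the null
against which 5′ clustering is measured.

Lifting maps both endpoints (start, end−1) through the aligned blocks of
UCSC chains. *Fully matched* requires both endpoints inside blocks of one
and the same chain with a positive-length target interval; target-strand
chains flip the locus strand and positions are converted from reversed to
forward coordinates. This both-endpoints-in-blocks criterion is stricter
than liftOver's minMatch ratio semantics and is this package's operational
definition of "fully matched"; overlap fractions depend on it and say so in
the report. Homology overlap divides by **all** input loci, so unliftable
circles count against the overlap.

## Kinetics

* X₀ relative qPCR level = `E^(Cq_ref − Cq_target)`; default efficiency
  E = 2 (the method's assumption absent a standard curve), per-amplicon
  efficiencies accepted. A target crossing threshold one cycle earlier than
  the reference is twofold more abundant.
* Decay: ordinary least squares of ln(abundance) on time; k = −slope,
  half-life = ln2/k, non-negative slopes reported as stable (infinite
  half-life) with a flag. With four timepoints (0, 3, 6, 9 h after chase
  start, the first harvested sample as origin — the absolute offset does
  not affect k) and multiplicative noise, log-linear OLS is the standard,
  stable estimator; a nonlinear one-phase fit adds no identifiable
  parameter at this design size.
* BrU-IP synthesis fold = `(IP/input) / (IP_ref/input_ref)`; invariant
  under common rescaling.
* Two-group comparison: two-sided t-test, with the pooled (equal-variance)
  form when a two-sided F test at α = 0.05 does not reject variance
  equality, Welch otherwise. Degenerate zero-variance inputs resolve by
  convention: identical constants → p = 1; distinct constants → the p → 0
  limit, flagged. Under the null with normal data the pooled t statistic is
  independent of the variance ratio, so the F gate leaves pooled p-values
  uniform (verified by simulation in the test suite).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes; it
is the acceptance surface for all recovery tests.

* **Genomes.** 500 genes over 5 chromosomes; 4–12 exons per gene; exon and
  intron lengths log-normal (medians ≈ 150 bp and ≈ 1.5 kb). Genes hosting
  a circle have the introns flanking the circularized exons multiplied by a
  factor drawn uniformly from 2–5, reproducing the elongated-flank
  signature of circRNA loci.
* **Truth.** 300 true circles on exon-boundary pairs of distinct host
  genes, placed at a transcript-relative position drawn from Beta(1.5, 3.5)
  (mode in the first third — 5′ bias; a uniform-placement switch provides
  the null control), never on terminal exons; 150 artifacts on arbitrary
  intragenic, non-boundary coordinates. Each locus follows one of five
  stage archetypes (flat, declining, NPC-transient, gradually rising,
  late switch) with a log-normal expression level; artifact levels are
  drawn lower (log-mean ln 10 vs ln 40) because low-count candidates are
  the typical caller false positives.
* **Libraries.** One mock and one RNase-R library per stage (replicates
  configurable), each of 300,000 junction reads. The mock composition is
  the expected backsplice molecules of all loci plus linear splice
  molecules at each circle's two flanking junctions (per-circle circular
  fraction Beta(2, 5), clipped to [0.05, 0.98]). RNase R is modelled
  *compositionally*: every component survives with fraction `s_circ = 0.9`
  (circular) or `s_lin = 0.02` (linear, including artifacts and flank
  reads), and the surviving pool is resequenced to the same depth. Circles
  therefore enrich because the rest of the pool is gone — the mechanism by
  which fixed-depth sequencing of a linear-depleted pool produces
  enrichment. With these defaults the expected fold is ≈ 8 for circles and
  ≈ 0.2 for artifacts; the survival fractions are not fitted to any
  dataset, they are chosen once to realize the qualitative regime the
  3-fold filter assumes. Counts are drawn by Gamma-jittering the expected
  composition (CV² = dispersion, default 0.2 — junction counts are
  overdispersed) and sampling reads multinomially at fixed depth, so
  marginals are negative-binomial-like while each library's total is
  conserved exactly.
* **Callers.** Each caller captures each junction read independently
  (binomial thinning) with probability 0.90/0.85/0.80 for circles and
  0.45/0.12/0.28 for artifacts (find_circ/CIRI2/CIRCexplorer2), calls a
  locus at ≥ 2 captured reads, and adds tool-private spurious calls
  (Poisson means 40/10/25 per library) at random coordinates. The artifact
  capture rates are ordered to reproduce the observed per-caller
  RNase-R-depletion ranking (find_circ worst, CIRI2 best). Thinning is the
  right error model here: it concentrates misses at low counts (the
  documented failure mode of junction callers) and cancels out of the
  mock/RNase-R fold, whereas per-library coin-flip detection would
  fabricate spurious enrichment and depletion from missing high-count loci.

What the generator does **not** emulate: read sequences and alignment (no
FASTQ), isoform structure within a locus, caller-specific coordinate
quirks, GC/length biases, batch effects, or biological replicates'
correlation structure. Passing the recovery tests therefore demonstrates
that the pipeline logic is correct under the assumed statistical regime,
not that the thresholds are optimal for any particular real dataset.

## Problem sizes

The test suite and the acceptance script run the full design at 450 truth
loci × 6 libraries × 3 callers (~7,000 calls), 20-seed property checks on
reduced designs (120 genes), 200-replicate kinetics recovery and a 10,000-
draw null-uniformity simulation; the complete suite finishes in well under
a minute of CPU. These sizes give every empirical assertion comfortable
Monte-Carlo margins while keeping runs instant; all statistics scale
linearly in loci × libraries.

## Known limitations

* Exact-key merging will split a true locus reported with ±1 bp by one
  caller; the `slop` mode exists but changes the reproducibility contract.
* Enrichment classification ignores count uncertainty (a hard fold
  threshold, by design); loci near the detection floor classify noisily,
  which is why recovery statistics condition on an expected-count floor.
* "Fully matched" lifting is stricter than liftOver's minMatch, so
  homology overlaps computed here are conservative relative to the original
  tool.
* The F-test gate at n = 3 has little power; it is implemented as the
  stated convention, not as a recommendation.
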