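"""Synthetic genomes, circRNA truth sets and predictor call tables.

The generator emulates the statistical structure the inventory analysis
assumes, so every downstream stage is testable without sequencing data:

* gene models with log-normal exon/intron lengths; genes hosting a circle
  get elongated introns flanking the circularized exons;
* true circles placed on exon-boundary pairs with a 5'-biased position in
  the transcript, each following one of five stage-expression archetypes
  across mESC -> NPC -> mN8;
* artifacts (linear-only false positives) on arbitrary intragenic
  coordinates;
* mock and RNase-R libraries: negative-binomial junction counts, with the
  RNase-R library modelled compositionally — molecules survive with
  fraction ``s_circ`` (circles) or ``s_lin`` (linear/artifact junctions)
  and the surviving pool is resequenced to the same depth, so circles
  enrich because the rest of the pool is gone, exactly as in a
  linear-depleted resequencing experiment;
* per-predictor call tables with tool-specific sensitivity, artifact
  pick-up rates and spurious calls, written in the exact dialects the
  ingest parsers read.

Counts are reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import ingest
from .model import (
    CircLocus,
    ConfigError,
    GeneModel,
    JunctionQuant,
    LibraryMeta,
    PlacementError,
    PredictorCall,
    STAGES,
)

# five stage-expression archetypes over (mESC, NPC, mN8): constitutive,
# stem-cell-enriched declining, NPC-transient, gradually rising, and
# neuron-switch profiles — the qualitative shapes differentiation produces
DEFAULT_ARCHETYPES: Dict[str, Tuple[float, float, float]] = {
    "flat": (1.0, 1.0, 1.0),
    "mESC_decline": (1.0, 0.4, 0.15),
    "NPC_transient": (0.2, 1.0, 0.2),
    "gradual_rise": (0.15, 0.45, 1.0),
    "mN8_switch": (0.1, 0.15, 1.0),
}


@dataclass
class PredictorProfile:
    """Error model of one caller.

    A caller sees each junction read independently: its reported count is a
    binomial thinning of the library's true junction reads (probability
    ``sensitivity`` for backsplice reads of real circles, ``artifact_rate``
    for linear artifact junctions), and a locus is called when the captured
    count reaches ``min_reads``. Low-count loci are therefore the ones a
    caller misses, matching how junction callers behave in practice.
    """

    sensitivity: float        # per-read capture probability, true circles
    artifact_rate: float      # per-read capture probability, linear artifacts
    min_reads: int = 2        # detection floor on the captured count
    n_spurious: int = 20      # mean tool-private spurious calls per library


# ordered to reproduce the observed depletion-fraction ranking:
# find_circ calls the most linear artifacts, CIRI2 the fewest
DEFAULT_PREDICTORS: Dict[str, PredictorProfile] = {
    "find_circ": PredictorProfile(0.90, 0.45, n_spurious=40),
    "ciri2": PredictorProfile(0.85, 0.12, n_spurious=10),
    "circexplorer2": PredictorProfile(0.80, 0.28, n_spurious=25),
}


@dataclass
class SimConfig:
    n_genes: int = 500
    n_chroms: int = 5
    exons_per_gene_range: Tuple[int, int] = (4, 12)
    exon_len_log_mean: float = math.log(150.0)
    exon_len_log_sd: float = 0.5
    intron_len_log_mean: float = math.log(1500.0)
    intron_len_log_sd: float = 0.8
    n_true_circ: int = 300
    n_artifacts: int = 150
    stages: Tuple[str, ...] = STAGES
    stage_profiles: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES))
    rpm_log_mean: float = math.log(40.0)
    rpm_log_sd: float = 1.0
    # artifacts sit at the low end of the count range: low-count candidates
    # are the typical false positives of junction callers
    artifact_rpm_log_mean: float = math.log(10.0)
    artifact_rpm_log_sd: float = 0.8
    depth_per_library: int = 300_000
    dispersion: float = 0.2
    s_circ: float = 0.9
    s_lin: float = 0.02
    circ_fraction_beta: Tuple[float, float] = (2.0, 5.0)
    five_prime_bias: bool = True
    position_beta: Tuple[float, float] = (1.5, 3.5)
    flank_multiplier_range: Tuple[float, float] = (2.0, 5.0)
    predictor_params: Dict[str, PredictorProfile] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTORS))
    replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.depth_per_library <= 0:
            raise ConfigError("n_genes and depth_per_library must be > 0")
        if self.n_true_circ < 0 or self.n_artifacts < 0:
            raise ConfigError("locus counts must be >= 0")
        lo, hi = self.exons_per_gene_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid exons_per_gene_range ({lo}, {hi})")
        if not (0.0 < self.s_lin <= self.s_circ <= 1.0):
            raise ConfigError("require 0 < s_lin <= s_circ <= 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if len(self.stage_profiles) == 0:
            raise ConfigError("at least one stage profile is required")
        for name, prof in self.stage_profiles.items():
            if len(prof) != len(self.stages) or min(prof) < 0 or max(prof) <= 0:
                raise ConfigError(f"profile {name!r} must be nonnegative over stages")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    def to_yaml(self, path: str) -> None:
        data = {k: v for k, v in self.__dict__.items() if k != "predictor_params"}
        data["stage_profiles"] = {k: list(v) for k, v in self.stage_profiles.items()}
        data["predictor_params"] = {
            name: {"sensitivity": p.sensitivity, "artifact_rate": p.artifact_rate,
                   "min_reads": p.min_reads, "n_spurious": p.n_spurious}
            for name, p in self.predictor_params.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["predictor_params"] = {
            name: PredictorProfile(**p) for name, p in data["predictor_params"].items()}
        data["stage_profiles"] = {k: tuple(v) for k, v in data["stage_profiles"].items()}
        for key in ("exons_per_gene_range", "circ_fraction_beta", "position_beta",
                    "flank_multiplier_range"):
            data[key] = tuple(data[key])
        data["stages"] = tuple(data["stages"])
        return cls(**data)


@dataclass(frozen=True)
class CircTruth:
    locus: CircLocus
    kind: str                      # "true_circ" | "artifact"
    host_gene: str
    archetype: str
    expected_rpm: Dict[str, float]  # relative expected abundance per stage
    circ_fraction: Optional[float]  # circular share of splicing at the locus


@dataclass
class SimTruth:
    gene_models: List[GeneModel]
    circ_truth: List[CircTruth]
    library_metas: List[LibraryMeta]
    config: SimConfig


@dataclass
class SimLibraries:
    calls: Dict[str, List[PredictorCall]]   # predictor -> calls over all samples
    junctions: List[JunctionQuant]
    metas: List[LibraryMeta]
    expected_counts: Dict[str, Dict[CircLocus, float]]  # sample_id -> bsj expectation
    sampled_counts: Dict[str, Dict[CircLocus, int]] = field(default_factory=dict)
    linear_totals: Dict[str, int] = field(default_factory=dict)  # flank reads per sample


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def _lognormal_int(rng, log_mean, log_sd, size, minimum):
    draws = np.exp(rng.normal(log_mean, log_sd, size=size))
    return np.maximum(np.rint(draws).astype(int), minimum)


def simulate_gene_models(config: SimConfig, rng: Optional[np.random.Generator] = None
                         ) -> List[GeneModel]:
    """Draw gene models; designate circle hosts and elongate their flanks.

    Hosts are pre-selected here (one circle slot per host gene) because the
    flanking-intron elongation must be baked into the gene structure before
    circles are placed; ``simulate_truth`` consumes the recorded slots.
    """
    config.validate()
    rng = rng or _rng(config, 0)
    lo, hi = config.exons_per_gene_range
    eligible: List[int] = []
    genes: List[GeneModel] = []
    cursors = {f"chr{i + 1}": 1000 for i in range(config.n_chroms)}
    chrom_names = sorted(cursors)
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % len(chrom_names)]
        n_exons = int(rng.integers(lo, hi + 1))
        exon_lens = _lognormal_int(rng, config.exon_len_log_mean,
                                   config.exon_len_log_sd, n_exons, 30)
        intron_lens = _lognormal_int(rng, config.intron_len_log_mean,
                                     config.intron_len_log_sd,
                                     max(n_exons - 1, 0), 50)
        strand = "+" if rng.random() < 0.5 else "-"
        if n_exons >= 4:
            eligible.append(gi)
        genes.append((chrom, strand, exon_lens, list(intron_lens)))
    if config.n_true_circ > 0:
        if len(eligible) < config.n_true_circ:
            raise PlacementError(
                f"cannot place {config.n_true_circ} circles: only "
                f"{len(eligible)} genes have >= 4 exons "
                f"(short by {config.n_true_circ - len(eligible)})")
        hosts = set(rng.choice(eligible, size=config.n_true_circ, replace=False).tolist())
    else:
        hosts = set()

    out: List[GeneModel] = []
    for gi, (chrom, strand, exon_lens, intron_lens) in enumerate(genes):
        n_exons = len(exon_lens)
        attrs: dict = {}
        if gi in hosts:
            # transcript-orientation relative position, mode in the first third
            rel = (rng.beta(*config.position_beta) if config.five_prime_bias
                   else rng.random())
            n_interior = n_exons - 2
            t0 = 1 + min(int(rel * n_interior), n_interior - 1)
            max_span = n_exons - 1 - t0  # keep the terminal exon outside
            span = 1 + min(int(rng.geometric(0.5)) - 1, max_span - 1) if max_span > 1 else 1
            t_idx = list(range(t0, t0 + span))
            g_idx = ([n_exons - 1 - t for t in t_idx] if strand == "-" else t_idx)
            g_start, g_end = min(g_idx), max(g_idx)
            mult = rng.uniform(*config.flank_multiplier_range)
            intron_lens[g_start - 1] = int(round(intron_lens[g_start - 1] * mult))
            intron_lens[g_end] = int(round(intron_lens[g_end] * mult))
            attrs["circ_slot"] = (g_start, g_end)
        pos = cursors[chrom]
        exons = []
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        cursors[chrom] = pos + 10_000
        out.append(GeneModel(f"gene{gi:04d}", chrom, strand, tuple(exons), attrs))
    return out


def simulate_truth(config: SimConfig, gene_models: List[GeneModel]) -> SimTruth:
    """Place true circles on host exon boundaries and artifacts anywhere intragenic."""
    config.validate()
    rng = _rng(config, 1)
    hosts = [g for g in gene_models if "circ_slot" in g.attrs]
    if len(hosts) < config.n_true_circ:
        raise PlacementError(
            f"need {config.n_true_circ} host slots, gene models provide "
            f"{len(hosts)} (short by {config.n_true_circ - len(hosts)})")
    archetype_names = sorted(config.stage_profiles)
    truth: List[CircTruth] = []

    for g in hosts[: config.n_true_circ]:
        g_start, g_end = g.attrs["circ_slot"]
        locus = CircLocus(g.chrom, g.exons[g_start][0], g.exons[g_end][1], g.strand)
        truth.append(_draw_truth(rng, config, locus, "true_circ", g.gene_id,
                                 archetype_names))

    boundary_starts = {}
    boundary_ends = {}
    for g in gene_models:
        boundary_starts.setdefault(g.chrom, set()).update(s for s, _ in g.exons)
        boundary_ends.setdefault(g.chrom, set()).update(e for _, e in g.exons)
    used = {t.locus for t in truth}
    for _ in range(config.n_artifacts):
        for _attempt in range(100):
            g = gene_models[int(rng.integers(len(gene_models)))]
            a, b = sorted(rng.integers(g.start, g.end, size=2).tolist())
            if b - a < 100:
                continue
            if a in boundary_starts.get(g.chrom, ()) or b in boundary_ends.get(g.chrom, ()):
                continue
            locus = CircLocus(g.chrom, int(a), int(b), g.strand)
            if locus in used:
                continue
            used.add(locus)
            truth.append(_draw_truth(rng, config, locus, "artifact", g.gene_id,
                                     archetype_names))
            break
        else:
            raise PlacementError("could not place an artifact locus in 100 attempts")

    metas = []
    for stage in config.stages:
        for treatment in ("mock", "rnaser"):
            for rep in range(config.replicates):
                suffix = f"_r{rep + 1}" if config.replicates > 1 else ""
                metas.append(LibraryMeta(f"{stage}_{treatment}{suffix}", stage,
                                         treatment, config.depth_per_library))
    return SimTruth(gene_models, truth, metas, config)


def _draw_truth(rng, config, locus, kind, host, archetype_names) -> CircTruth:
    name = archetype_names[int(rng.integers(len(archetype_names)))]
    profile = np.asarray(config.stage_profiles[name], dtype=float)
    if kind == "true_circ":
        level = float(np.exp(rng.normal(config.rpm_log_mean, config.rpm_log_sd)))
    else:
        level = float(np.exp(rng.normal(config.artifact_rpm_log_mean,
                                        config.artifact_rpm_log_sd)))
    expected = {st: level * p / profile.max()
                for st, p in zip(config.stages, profile)}
    frac = float(np.clip(rng.beta(*config.circ_fraction_beta), 0.05, 0.98)) \
        if kind == "true_circ" else None
    return CircTruth(locus, kind, host, name, expected, frac)


def _nb_counts(rng, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson mixture: var = mu + dispersion * mu^2."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 0:
        return rng.poisson(means)
    return rng.poisson(_gamma_jitter(rng, means, dispersion))


def _gamma_jitter(rng, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Per-component Gamma noise with mean ``means`` and CV^2 = dispersion."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 0:
        return means
    shape = 1.0 / dispersion
    out = np.zeros_like(means)
    pos = means > 0
    out[pos] = rng.gamma(shape, means[pos] * dispersion)
    return out


def simulate_libraries(truth: SimTruth, config: Optional[SimConfig] = None
                       ) -> SimLibraries:
    """Sample junction counts and emit per-predictor call tables.

    For each stage, the mock library's expected composition (backsplice
    molecules of circles and artifacts plus linear splice molecules at each
    circle's two flanking junctions) is scaled to sum to
    ``depth_per_library``. The RNase-R library multiplies every component by
    its survival fraction and renormalizes the pool back to the same depth,
    which conserves total expectation and makes resistant species enrich in
    composition.
    """
    config = config or truth.config
    config.validate()
    rng = _rng(config, 2)
    records = truth.circ_truth
    n = len(records)
    kinds = np.array([t.kind for t in records])
    is_circ = kinds == "true_circ"
    fracs = np.array([t.circ_fraction if t.circ_fraction else 1.0 for t in records])

    calls: Dict[str, List[PredictorCall]] = {p: [] for p in config.predictor_params}
    junctions: List[JunctionQuant] = []
    expected_counts: Dict[str, Dict[CircLocus, float]] = {}
    sampled_counts: Dict[str, Dict[CircLocus, int]] = {}
    linear_totals: Dict[str, int] = {}

    for stage in config.stages:
        abund = np.array([t.expected_rpm[stage] for t in records])
        # each flanking junction carries bsj * (1-c)/c linear molecules
        flank = np.where(is_circ, abund * (1.0 - fracs) / fracs, 0.0)
        mass = abund.sum() + 2.0 * flank.sum()
        scale = config.depth_per_library / mass
        mock_bsj = abund * scale
        mock_flank = flank * scale
        surv_bsj = np.where(is_circ, config.s_circ, config.s_lin)
        pool = (mock_bsj * surv_bsj).sum() + 2.0 * (mock_flank * config.s_lin).sum()
        renorm = config.depth_per_library / pool
        rnaser_bsj = mock_bsj * surv_bsj * renorm

        stage_metas = [m for m in truth.library_metas if m.stage == stage]
        for meta in stage_metas:
            exp_bsj = mock_bsj if meta.treatment == "mock" else rnaser_bsj
            exp_flank = (mock_flank if meta.treatment == "mock"
                         else mock_flank * config.s_lin * renorm)
            # gamma-jittered composition sequenced multinomially to fixed
            # depth: marginals are overdispersed, totals conserve depth
            expect = np.concatenate([exp_bsj, exp_flank, exp_flank])
            lam = _gamma_jitter(rng, expect, config.dispersion)
            drawn = rng.multinomial(config.depth_per_library, lam / lam.sum())
            counts, up, down = drawn[:n], drawn[n:2 * n], drawn[2 * n:]
            expected_counts[meta.sample_id] = {
                t.locus: float(e) for t, e in zip(records, exp_bsj)}
            sampled_counts[meta.sample_id] = {
                t.locus: int(c) for t, c in zip(records, counts)}
            linear_totals[meta.sample_id] = int(up.sum() + down.sum())
            for tool, prof in config.predictor_params.items():
                capture = np.where(is_circ, prof.sensitivity, prof.artifact_rate)
                captured = rng.binomial(counts, capture)
                for idx in np.flatnonzero(captured >= prof.min_reads):
                    calls[tool].append(PredictorCall(
                        records[idx].locus, tool, meta.sample_id,
                        int(captured[idx])))
                n_spur = int(rng.poisson(prof.n_spurious))
                for locus, cnt in _spurious_loci(rng, config, n_spur):
                    calls[tool].append(PredictorCall(locus, tool, meta.sample_id, cnt))
            if meta.treatment == "mock":
                for idx in np.flatnonzero(is_circ):
                    junctions.append(JunctionQuant(
                        records[idx].locus, stage, int(counts[idx]),
                        int(up[idx]), int(down[idx])))
    return SimLibraries(calls, junctions, list(truth.library_metas),
                        expected_counts, sampled_counts, linear_totals)


def _spurious_loci(rng, config, n_spur):
    """Tool-private junk calls on random coordinates (never shared across tools)."""
    out = []
    for _ in range(n_spur):
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        start = int(rng.integers(1_000, 5_000_000))
        length = int(np.exp(rng.normal(math.log(400.0), 0.6)))
        strand = "+" if rng.random() < 0.5 else "-"
        cnt = max(int(_nb_counts(rng, np.array([3.0]), config.dispersion)[0]), 1)
        out.append((CircLocus(chrom, start, start + max(length, 50), strand), cnt))
    return out


def simulate_dataset(config: SimConfig) -> Tuple[SimTruth, SimLibraries]:
    """Convenience: gene models -> truth -> libraries in one call."""
    genes = simulate_gene_models(config)
    truth = simulate_truth(config, genes)
    libs = simulate_libraries(truth, config)
    return truth, libs


def detection_floor_loci(truth: SimTruth, min_expected: float = 5.0) -> set:
    """True-circle loci with expected mock backsplice count above the floor.

    A circle whose expected count in its best stage stays below every tool's
    minimum-read cut cannot be recovered by any caller; recovery statistics
    condition on this set.
    """
    config = truth.config
    floor = set()
    for stage in config.stages:
        records = truth.circ_truth
        abund = np.array([t.expected_rpm[stage] for t in records])
        is_circ = np.array([t.kind == "true_circ" for t in records])
        fracs = np.array([t.circ_fraction if t.circ_fraction else 1.0 for t in records])
        flank = np.where(is_circ, abund * (1.0 - fracs) / fracs, 0.0)
        scale = config.depth_per_library / (abund.sum() + 2.0 * flank.sum())
        for t, e in zip(records, abund * scale):
            if t.kind == "true_circ" and e >= min_expected:
                floor.add(t.locus)
    return floor


# ---------------------------------------------------------------------------
# dataset writer

def write_dataset(truth: SimTruth, libs: SimLibraries, outdir: str) -> None:
    """Write call tables (per tool/sample, native dialects), meta, junctions,
    truth and config under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    by_tool_sample: Dict[str, Dict[str, list]] = {}
    for tool, tool_calls in libs.calls.items():
        for c in tool_calls:
            by_tool_sample.setdefault(tool, {}).setdefault(c.sample_id, []).append(c)
    for tool, per_sample in sorted(by_tool_sample.items()):
        tool_dir = os.path.join(outdir, "calls", tool)
        os.makedirs(tool_dir, exist_ok=True)
        for sample, sample_calls in sorted(per_sample.items()):
            sample_calls.sort(key=lambda c: c.locus)
            ingest.WRITERS[tool](sample_calls, os.path.join(tool_dir, f"{sample}.tsv"))
    ingest.write_meta(libs.metas, os.path.join(outdir, "meta.tsv"))
    ingest.write_junctions(libs.junctions, os.path.join(outdir, "junctions.tsv"))
    write_truth_table(truth, os.path.join(outdir, "truth.tsv"))
    truth.config.to_yaml(os.path.join(outdir, "config.yaml"))


def write_truth_table(truth: SimTruth, path: str) -> None:
    import pandas as pd

    rows = []
    for t in truth.circ_truth:
        row = {"chrom": t.locus.chrom, "start": t.locus.start, "end": t.locus.end,
               "strand": t.locus.strand, "kind": t.kind, "host_gene": t.host_gene,
               "archetype": t.archetype,
               "circ_fraction": "" if t.circ_fraction is None else t.circ_fraction}
        for st, v in t.expected_rpm.items():
            row[f"expected_{st}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
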