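"""End-to-end orchestration: reads → error profile → calls → hotspots.

`run_all` consumes files (SAM/BAM, FASTA, refFlat/BED12, VCF/UCSC table)
and writes the reports; `run_objects` is the same pipeline over in-memory
objects, used by the CLI stages, the simulator-driven experiments and the
tests.  Identical inputs, thresholds and seed give byte-identical output
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import annotate as ann
from . import enrichment as enr
from .calling import bh_adjust, call_snvs, score_sites
from .error_model import (ErrorProfile, build_error_profile, deduplicate,
                          pileup, region_coverage)
from .genome import Genome
from .hotspots import (classify_hotspots, gene_poisson_test, permutation_z,
                       scan_motifs, write_hotspot_report)
from .io import read_gene_models, read_known_variants, write_tracks
from .reads import read_alignments

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "run_objects"]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the method, with its published default."""

    min_depth: int = 4            # n >= 4 for a site to be scored
    fdr: float = 0.01             # genome-wide BH FDR for SNV calling
    min_ratio: float = 0.33       # k/n gate for high confidence
    min_quality: float | None = None  # raw-ASCII alt-quality gate
    quality_encoding: str = "phred+33"
    ttest_p: float = 0.05         # quality-bias gate
    window: int = 4000            # promoter window width around the TSS
    min_snvs: int = 3             # cluster-size gate
    gene_q: float = 0.005         # BH-adjusted cluster-p gate
    z_gate: float = 1.0           # motif-enrichment z gate (strict >)
    n_perm: int = 1000
    seed: int = 0
    min_mapq: int = 1             # "uniquely aligned" criterion
    enrichment_mode: str = "min-reads"
    enrichment_min_reads: int = 20
    peaks_bed: str | None = None
    allele_aware_novelty: bool = False
    window_per_transcript: bool = False

    def validate(self) -> None:
        if not 0 <= self.min_ratio <= 1:
            raise ValueError(f"min_ratio={self.min_ratio} outside [0, 1]")
        if not 0 < self.fdr <= 1:
            raise ValueError(f"fdr={self.fdr} outside (0, 1]")
        if not 0 < self.gene_q <= 1:
            raise ValueError(f"gene_q={self.gene_q} outside (0, 1]")
        if self.min_depth < 1 or self.min_snvs < 1 or self.n_perm < 1:
            raise ValueError("min_depth, min_snvs and n_perm must be >= 1")
        ann.quality_offset(self.quality_encoding)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    calls: list                       # all BH-passing SNV calls
    high_confidence: list             # subset passing the confidence gates
    windows: list
    hotspots: list
    profile: ErrorProfile
    counts: dict = field(default_factory=dict)


def _stage_counts(calls, high_conf, windows, known_flagged, hotspots):
    hc_promoter = [c for c in high_conf if c.promoter]
    hc_novel = [c for c in hc_promoter if c.novel]
    return {
        "total_snvs": len(calls),
        "high_confidence_snvs": len(high_conf),
        "enriched_promoters": sum(w.enriched for w in windows),
        "high_confidence_promoter_snvs": len(hc_promoter),
        "promoter_snvs_known_pct": round(
            100.0 * (1 - len(hc_novel) / len(hc_promoter)), 2)
            if hc_promoter else float("nan"),
        "high_confidence_novel_promoter_snvs": len(hc_novel),
        "genes_with_novel_promoter_snvs": len(
            {g for c in hc_novel for g in c.genes}),
        "hotspot_genes": sum(h.is_hotspot for h in hotspots),
    }


def run_objects(batch, genome: Genome, genes, known,
                config: PipelineConfig | None = None,
                profile: ErrorProfile | None = None) -> PipelineResult:
    """Run the full pipeline over in-memory inputs."""
    cfg = config or PipelineConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    dedup = deduplicate(batch)
    if profile is None:
        profile = build_error_profile(dedup, genome)

    chrom_lengths = {c: genome.length(c) for c in genome.chrom_names}
    windows = ann.build_windows(genes, chrom_lengths,
                                half_width=cfg.window // 2)
    genome_length = int(sum(chrom_lengths.values()))
    enr.select_enriched(windows, dedup, mode=cfg.enrichment_mode,
                        min_reads=cfg.enrichment_min_reads,
                        genome_length=genome_length,
                        peaks_bed=cfg.peaks_bed)
    enriched = [w for w in windows if w.enriched]

    scored = call_snvs(dedup, genome, windows, profile,
                       min_depth=cfg.min_depth)
    qvals = bh_adjust([c.pvalue for c in scored])
    calls = []
    for c, q in zip(scored, qvals):
        c.qvalue = float(q)
        if q <= cfg.fdr:
            calls.append(c)

    ann.annotate_calls(calls, windows, known,
                       allele_aware=cfg.allele_aware_novelty)
    high_conf = ann.confidence_filter(
        calls, min_ratio=cfg.min_ratio, min_quality=cfg.min_quality,
        min_ttest_p=cfg.ttest_p, encoding=cfg.quality_encoding)

    hc_novel_promoter = [c for c in high_conf if c.promoter and c.novel]
    calls_by_gene: dict[str, list] = {}
    for c in hc_novel_promoter:
        for g in c.genes:
            calls_by_gene.setdefault(g, []).append(c)
    per_gene_counts = {g: len(cs) for g, cs in calls_by_gene.items()}

    hotspots = []
    if per_gene_counts and enriched:
        tests = gene_poisson_test(per_gene_counts, len(enriched))
        wins_by_gene: dict[str, list] = {}
        for w in enriched:
            wins_by_gene.setdefault(w.gene_name, []).append(w)
        candidates = [t for t in tests
                      if t.k_gene >= cfg.min_snvs and t.qvalue < cfg.gene_q]
        enrichments: dict[str, dict] = {}
        for t in sorted(candidates, key=lambda t: t.gene_name):
            gene_calls = calls_by_gene[t.gene_name]
            # per-transcript mode can leave several disjoint windows per
            # gene; the permutation null uses the one holding most calls
            w = max(wins_by_gene[t.gene_name],
                    key=lambda w: sum(w.start <= c.pos < w.end
                                      for c in gene_calls))
            cov = region_coverage(dedup, w)
            w.covered_positions = (
                w.start + np.flatnonzero(cov >= cfg.min_depth))
            hits = scan_motifs(genome, w)
            positions = np.array(sorted(c.pos for c in gene_calls
                                        if w.start <= c.pos < w.end))
            enrichments[t.gene_name] = {
                cls: permutation_z(w, positions, hits, cls,
                                   n_perm=cfg.n_perm, rng=rng)
                for cls in ("RGYW", "WA")}
            mut_r = {h.mutable_pos for h in hits if h.motif_class == "RGYW"}
            mut_w = {h.mutable_pos for h in hits if h.motif_class == "WA"}
            for c in calls_by_gene[t.gene_name]:
                c.shm_context_rgyw = c.pos in mut_r
                c.shm_context_wa = c.pos in mut_w
        hotspots = classify_hotspots(
            [t for t in tests if t.k_gene >= 1], calls_by_gene, enrichments,
            min_snvs=cfg.min_snvs, max_qvalue=cfg.gene_q,
            z_gate=cfg.z_gate)

    counts = _stage_counts(calls, high_conf, windows,
                           sum(not c.novel for c in high_conf), hotspots)
    return PipelineResult(calls=calls, high_confidence=high_conf,
                          windows=windows, hotspots=hotspots,
                          profile=profile, counts=counts)


def write_call_table(calls, path) -> None:
    """TSV of SNV calls; positions are 1-based for display."""
    def fmt(x):
        return "NA" if isinstance(x, float) and np.isnan(x) else f"{x:.6g}"

    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tn\tk\tratio\tpvalue\tqvalue\t"
                 "mean_ref_quality\tmean_alt_quality\tquality_ttest_p\t"
                 "novel\thigh_confidence\tpromoter\tshm_context_rgyw\t"
                 "shm_context_wa\tgenes\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t{c.ref_base}\t{c.alt_base}\t"
                f"{c.n}\t{c.k}\t{c.ratio:.4f}\t{fmt(c.pvalue)}\t"
                f"{fmt(c.qvalue)}\t{fmt(c.mean_ref_quality)}\t"
                f"{fmt(c.mean_alt_quality)}\t{fmt(c.quality_ttest_p)}\t"
                f"{int(c.novel)}\t{int(c.high_confidence)}\t"
                f"{int(c.promoter)}\t{int(c.shm_context_rgyw)}\t"
                f"{int(c.shm_context_wa)}\t{','.join(c.genes)}\n")


def write_gene_novel_table(calls, path) -> None:
    """Per-gene list of high-confidence novel promoter SNVs
    (gene, count, 1-based positions)."""
    by_gene: dict[str, list] = {}
    for c in calls:
        if c.high_confidence and c.novel and c.promoter:
            for g in c.genes:
                by_gene.setdefault(g, []).append(c.pos + 1)
    with open(path, "w") as fh:
        fh.write("gene\tnovel_snv_count\tpositions\n")
        for gene in sorted(by_gene):
            pos = sorted(by_gene[gene])
            fh.write(f"{gene}\t{len(pos)}\t"
                     + ",".join(map(str, pos)) + "\n")


def write_windows_table(windows, path) -> None:
    """TSV of promoter windows with their enrichment status."""
    with open(path, "w") as fh:
        fh.write("gene\tchrom\tstart\tend\tstrand\ttss\tenriched\n")
        for w in sorted(windows, key=lambda w: (w.chrom, w.start)):
            fh.write(f"{w.gene_name}\t{w.chrom}\t{w.start}\t{w.end}\t"
                     f"{w.strand}\t{w.tss}\t{int(w.enriched)}\n")


def run_all(sam: str, fasta: str, genes_path: str, known_path: str,
            outdir: str, config: PipelineConfig | None = None) -> PipelineResult:
    """File-level pipeline: read inputs, run, write every report."""
    cfg = config or PipelineConfig()
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = Genome.from_fasta(fasta)
    genes = read_gene_models(genes_path,
                             per_transcript=cfg.window_per_transcript)
    known = read_known_variants(known_path)
    batch = read_alignments(sam, min_mapq=cfg.min_mapq)

    result = run_objects(batch, genome, genes, known, cfg)

    result.profile.to_tsv(outdir / "error_profile.tsv")
    write_call_table(result.calls, outdir / "snv_calls.tsv")
    write_gene_novel_table(result.high_confidence,
                           outdir / "genes_novel_snvs.tsv")
    write_windows_table(result.windows, outdir / "windows.tsv")
    write_tracks(result.high_confidence, outdir / "tracks")
    write_hotspot_report(result.hotspots, outdir / "report")
    log = {"config": {k: v for k, v in asdict(cfg).items()},
           "counts": result.counts}
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return result
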