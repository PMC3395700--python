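"""In-silico validation experiments.

Scaled-down planted-truth experiments that exercise the whole pipeline on
the synthetic fixture and measure recovery:

* :func:`snv_recovery` — plant novel SNVs and germline SNPs, run the
  pipeline, measure sensitivity/precision of the high-confidence novel
  call set and the known-flagging of planted SNPs;
* :func:`hotspot_recovery` — plant motif-context SHM hotspots against a
  background of scattered SNVs and quiet promoters, measure the hotspot
  classification's recovery and false-call rates over replicates;
* :func:`clustering_significance` — the closed-form Poisson tail for a
  3-SNV promoter cluster given experiment-level totals.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .pipeline import PipelineConfig, run_objects
from .simulate import (PlantedHotspot, PlantedScattered, SimConfig,
                       simulate_genome, simulate_reads)

__all__ = ["snv_recovery", "hotspot_recovery", "clustering_significance"]


def _known_set(sim):
    from .io import KnownVariantSet
    known = KnownVariantSet()
    for v in sim.known_variants:
        known.add(v.chrom, v.pos, v.alt)
    return known


def snv_recovery(seed: int = 0, n_genes: int = 60, n_snvs: int = 200,
                 n_snps: int = 100, mean_depth: float = 30.0,
                 allele_fraction: float = 0.5) -> dict:
    """Planted-variant recovery on the synthetic fixture.

    Returns sensitivity and precision of the high-confidence novel
    promoter SNV set against the planted truth, and the fraction of
    called planted-SNP sites flagged as known.
    """
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_snvs=n_snvs,
                    n_snps=n_snps, mean_depth=mean_depth,
                    snv_allele_fraction=allele_fraction)
    sim = simulate_genome(cfg)
    batch = simulate_reads(sim)
    result = run_objects(batch, sim.genome, sim.genes, _known_set(sim),
                         PipelineConfig(seed=seed))

    truth = {(v.chrom, v.pos, v.alt) for v in sim.manifest
             if v.kind == "snv"}
    truth_pos = {(c, p) for c, p, _ in truth}
    snp_pos = {(v.chrom, v.pos) for v in sim.known_variants}

    hc_novel = [c for c in result.high_confidence if c.novel and c.promoter]
    called = {(c.chrom, c.pos, c.alt_base) for c in hc_novel}
    tp = len(called & truth)
    sensitivity = tp / len(truth) if truth else float("nan")
    precision = (sum(1 for key in called if key[:2] in truth_pos)
                 / len(called)) if called else float("nan")

    snp_calls = [c for c in result.calls if (c.chrom, c.pos) in snp_pos]
    known_flagged = (sum(1 for c in snp_calls if not c.novel)
                     / len(snp_calls)) if snp_calls else float("nan")
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "known_flagged_fraction": known_flagged,
        "n_planted": len(truth),
        "n_called_novel": len(called),
        "n_snp_calls": len(snp_calls),
        "counts": result.counts,
    }


def hotspot_recovery(seed: int = 0, n_replicates: int = 20,
                     n_genes: int = 300, n_seeded: int = 10,
                     n_background: int = 50, mean_depth: float = 30.0,
                     shm_allele_fraction: float = 0.6) -> dict:
    """Planted-hotspot recovery over seeded replicates.

    Each replicate plants ``n_seeded`` genes with 5-8 RGYW-context SHMs
    and ``n_background`` genes with 0-2 scattered novel SNVs inside a
    universe of ``n_genes`` enriched promoters; the remaining promoters
    are covered but quiet.  Returns the fraction of seeded genes
    classified as hotspots and the hotspot rate among all non-seeded
    genes, pooled over replicates.
    """
    seed_seq = np.random.SeedSequence(seed)
    recovered = seeded_total = 0
    background_hot = background_total = 0
    per_replicate = []
    for child in seed_seq.spawn(n_replicates):
        rng = np.random.default_rng(child)
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        hotspots = [PlantedHotspot(i, int(rng.integers(5, 9)),
                                   allele_fraction=shm_allele_fraction)
                    for i in range(n_seeded)]
        scattered = [PlantedScattered(n_seeded + j, int(rng.integers(0, 3)))
                     for j in range(n_background)]
        cfg = SimConfig(seed=rep_seed, n_genes=n_genes,
                        mean_depth=mean_depth,
                        planted_hotspots=hotspots,
                        planted_scattered=scattered)
        sim = simulate_genome(cfg, rng)
        batch = simulate_reads(sim, rng)
        result = run_objects(batch, sim.genome, sim.genes, _known_set(sim),
                             PipelineConfig(seed=rep_seed))
        seeded_names = {sim.genes[h.gene_index].gene_name for h in hotspots}
        hot_names = {h.gene_name for h in result.hotspots if h.is_hotspot}
        rec = len(hot_names & seeded_names)
        bg_hot = len(hot_names - seeded_names)
        recovered += rec
        seeded_total += n_seeded
        background_hot += bg_hot
        background_total += n_genes - n_seeded
        per_replicate.append({"seeded_recovered": rec,
                              "background_hotspots": bg_hot})
    return {
        "seeded_recovery_rate": recovered / seeded_total,
        "background_hotspot_rate": background_hot / background_total,
        "n_replicates": n_replicates,
        "per_replicate": per_replicate,
    }


def clustering_significance(n_novel_snvs: int, n_enriched_promoters: int,
                            k: int = 3) -> float:
    """P(X >= k) for one promoter under uniform SNV placement.

    lambda = n_novel_snvs / n_enriched_promoters; the probability that a
    single 5' regulatory region accumulates ``k`` or more novel SNVs by
    chance.
    """
    lam = n_novel_snvs / n_enriched_promoters
    return float(stats.poisson.sf(k - 1, lam))
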