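"""Per-gene SHM hotspot statistics.

A gene is an SHM hotspot when its 5' regulatory window shows (i) an
improbable *cluster* of high-confidence novel SNVs — Poisson test against
the uniform expectation over all enriched promoters, BH-corrected — and
(ii) *motif-context enrichment*: more SNVs at AID target-motif mutable
bases (the G/C of RGYW/WRCY, or the A/T of WA/TW) than expected from the
local motif density, assessed by permutation z-score.

Gates (defaults mirror the method's published thresholds): at least 3
novel SNVs, BH-adjusted cluster p < 0.005, and z > 1 for either motif
class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotate import PromoterWindow
from .calling import SnvCall, bh_adjust
from .genome import Genome

__all__ = [
    "MotifHit", "scan_motifs", "mutable_positions",
    "GenePoissonTest", "gene_poisson_test",
    "MotifEnrichment", "permutation_z",
    "HotspotResult", "classify_hotspots", "write_hotspot_report",
]

# Forward-strand degenerate patterns; the paired pattern is the reverse
# complement, so one forward scan per pattern covers both DNA strands.
# Offsets locate the mutable base inside the match.
_MOTIFS = {
    # class RGYW: AID deaminates the C paired with the underlined G
    "RGYW": (
        (re.compile(r"(?=[AG]G[CT][AT])"), 1, "+"),   # RGYW, mutable G
        (re.compile(r"(?=[AT][AG]C[CT])"), 2, "-"),   # WRCY, mutable C
    ),
    # class WA: polymerase-eta errors at the A of WA / T of TW
    "WA": (
        (re.compile(r"(?=[AT]A)"), 1, "+"),           # WA, mutable A
        (re.compile(r"(?=T[AT])"), 0, "-"),           # TW, mutable T
    ),
}

#: Reference base allowed at a mutable position, per class and strand.
_MUTABLE_BASE = {("RGYW", "+"): "G", ("RGYW", "-"): "C",
                 ("WA", "+"): "A", ("WA", "-"): "T"}


@dataclass(frozen=True)
class MotifHit:
    """A mutable base of an AID target motif."""

    chrom: str
    mutable_pos: int
    motif_class: str   # "RGYW" or "WA"
    strand: str        # strand of the matching motif orientation


def scan_motifs(genome: Genome, window: PromoterWindow,
                flank: int = 3) -> list[MotifHit]:
    """All motif-mutable positions inside a window.

    The scanned sequence is extended by ``flank`` bases on each side so
    motifs straddling the window boundary are found; only hits whose
    mutable base lies inside the window are returned.  A position may
    carry hits of both classes but at most one hit per class.
    """
    seq_start = max(window.start - flank, 0)
    seq = genome.sequence(window.chrom, seq_start, window.end + flank)
    hits: list[MotifHit] = []
    for cls, patterns in _MOTIFS.items():
        seen: set[int] = set()
        for pattern, offset, strand in patterns:
            for m in pattern.finditer(seq):
                pos = seq_start + m.start() + offset
                if window.start <= pos < window.end and pos not in seen:
                    seen.add(pos)
                    hits.append(MotifHit(window.chrom, pos, cls, strand))
    return sorted(hits, key=lambda h: (h.motif_class, h.mutable_pos))


def mutable_positions(hits: list[MotifHit], motif_class: str) -> np.ndarray:
    return np.array(sorted({h.mutable_pos for h in hits
                            if h.motif_class == motif_class}),
                    dtype=np.int64)


@dataclass
class GenePoissonTest:
    """Clustering test for one gene's novel-SNV count."""

    gene_name: str
    k_gene: int
    lam: float
    pvalue: float
    qvalue: float = float("nan")


def gene_poisson_test(per_gene_counts: dict[str, int],
                      n_enriched_windows: int) -> list[GenePoissonTest]:
    """Poisson clustering test per gene, BH-corrected across genes.

    lambda = total novel SNVs / number of enriched windows (the expected
    count were SNVs uniform over enriched promoters); p = P(X >= k_gene).
    The BH family is the genes with at least one novel SNV.
    """
    if n_enriched_windows <= 0:
        raise ValueError("no enriched windows: the expected SNV rate is "
                         "undefined")
    total = sum(per_gene_counts.values())
    lam = total / n_enriched_windows
    tests = [GenePoissonTest(gene_name=g, k_gene=k, lam=lam,
                             pvalue=float(stats.poisson.sf(k - 1, lam))
                             if k > 0 else 1.0)
             for g, k in sorted(per_gene_counts.items())]
    family = [t for t in tests if t.k_gene >= 1]
    if family:
        qvals = bh_adjust([t.pvalue for t in family])
        for t, q in zip(family, qvals):
            t.qvalue = float(q)
    return tests


@dataclass
class MotifEnrichment:
    """Permutation enrichment of SNVs at one motif class' mutable bases."""

    motif_class: str
    obs: int
    exp: float
    sd: float
    z: float


def permutation_z(window: PromoterWindow, snv_positions,
                  motif_hits: list[MotifHit], motif_class: str,
                  n_perm: int = 1000,
                  rng: np.random.Generator | None = None,
                  seed: int | None = 0) -> MotifEnrichment:
    """Permutation z-score for motif-context SNV enrichment in a window.

    Each permutation redraws ``len(snv_positions)`` positions uniformly
    without replacement from the window's covered positions and counts how
    many land on mutable bases of the class; z = (obs - exp)/sd against
    that null.  With sd = 0: z = +inf when obs > exp, -inf when obs < exp,
    0 when equal.
    """
    snv_positions = np.asarray(snv_positions, dtype=np.int64)
    if len(snv_positions) == 0:
        raise ValueError("permutation test needs at least one SNV")
    covered = np.asarray(window.covered_positions, dtype=np.int64)
    s = len(snv_positions)
    if len(covered) < s:
        raise ValueError(
            f"window {window.gene_name} has {len(covered)} covered "
            f"positions, fewer than the {s} SNVs to permute")
    mut = mutable_positions(motif_hits, motif_class)
    obs = int(np.isin(snv_positions, mut).sum())
    if rng is None:
        rng = np.random.default_rng(seed)
    is_mut = np.isin(covered, mut)
    # vectorised sampling without replacement: rank a uniform draw per row
    u = rng.random((n_perm, len(covered)))
    picks = np.argpartition(u, s - 1, axis=1)[:, :s]
    null_counts = is_mut[picks].sum(axis=1)
    exp = float(null_counts.mean())
    sd = float(null_counts.std())
    if sd == 0.0:
        z = 0.0 if obs == exp else float("inf") if obs > exp else float("-inf")
    else:
        z = (obs - exp) / sd
    return MotifEnrichment(motif_class=motif_class, obs=obs, exp=exp,
                           sd=sd, z=float(z))


@dataclass
class HotspotResult:
    """Per-gene hotspot report row."""

    gene_name: str
    k_gene: int
    downstream_count: int
    qvalue: float
    rgyw: MotifEnrichment | None
    wa: MotifEnrichment | None
    ts: int
    tv: int
    is_hotspot: bool
    calls: list[SnvCall]


def classify_hotspots(tests: list[GenePoissonTest],
                      calls_by_gene: dict[str, list[SnvCall]],
                      enrichments: dict[str, dict[str, MotifEnrichment]],
                      min_snvs: int = 3, max_qvalue: float = 0.005,
                      z_gate: float = 1.0) -> list[HotspotResult]:
    """Combine clustering and motif statistics into hotspot calls.

    hotspot iff k_gene >= min_snvs AND qvalue < max_qvalue AND
    (z_RGYW > z_gate OR z_WA > z_gate); the z comparison is strict.
    """
    results = []
    for t in tests:
        calls = calls_by_gene.get(t.gene_name, [])
        if not calls:
            continue
        enr = enrichments.get(t.gene_name, {})
        rgyw, wa = enr.get("RGYW"), enr.get("WA")
        ts = sum(c.is_transition for c in calls)
        downstream = sum(c.downstream_of_tss for c in calls)
        cluster_ok = t.k_gene >= min_snvs and t.qvalue < max_qvalue
        z_ok = any(e is not None and e.z > z_gate for e in (rgyw, wa))
        results.append(HotspotResult(
            gene_name=t.gene_name, k_gene=t.k_gene,
            downstream_count=downstream, qvalue=t.qvalue,
            rgyw=rgyw, wa=wa, ts=ts, tv=len(calls) - ts,
            is_hotspot=bool(cluster_ok and z_ok), calls=calls))
    results.sort(key=lambda r: (r.qvalue, -r.k_gene, r.gene_name))
    return results


def _fmt(x: float) -> str:
    if np.isnan(x):
        return "NA"
    return f"{x:.6g}"


def write_hotspot_report(results: list[HotspotResult], out_prefix: str):
    """Write the per-gene hotspot table and the per-SNV location table.

    Genomic positions are written 1-based for display; the per-SNV file
    carries the motif-context flags of each variant.
    """
    from pathlib import Path

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    genes_path = Path(f"{prefix}.hotspots.tsv")
    snvs_path = Path(f"{prefix}.hotspot_snvs.tsv")
    with open(genes_path, "w") as fh:
        fh.write("gene\tsnv_number\tdownstream_of_tss\tqvalue\t"
                 "rgyw_obs\trgyw_exp\trgyw_z\twa_obs\twa_exp\twa_z\t"
                 "ts\ttv\tis_hotspot\n")
        for r in results:
            rg = r.rgyw or MotifEnrichment("RGYW", 0, float("nan"),
                                           float("nan"), float("nan"))
            wa = r.wa or MotifEnrichment("WA", 0, float("nan"),
                                         float("nan"), float("nan"))
            fh.write(f"{r.gene_name}\t{r.k_gene}({r.downstream_count})\t"
                     f"{r.downstream_count}\t{_fmt(r.qvalue)}\t"
                     f"{rg.obs}\t{_fmt(rg.exp)}\t{_fmt(rg.z)}\t"
                     f"{wa.obs}\t{_fmt(wa.exp)}\t{_fmt(wa.z)}\t"
                     f"{r.ts}\t{r.tv}\t{int(r.is_hotspot)}\n")
    with open(snvs_path, "w") as fh:
        fh.write("gene\tchrom\tpos\tref\talt\tn\tk\tratio\tqvalue\t"
                 "shm_context_rgyw\tshm_context_wa\n")
        for r in results:
            for c in sorted(r.calls, key=lambda c: (c.chrom, c.pos)):
                fh.write(f"{r.gene_name}\t{c.chrom}\t{c.pos + 1}\t"
                         f"{c.ref_base}\t{c.alt_base}\t{c.n}\t{c.k}\t"
                         f"{c.ratio:.4f}\t{_fmt(c.qvalue)}\t"
                         f"{int(c.shm_context_rgyw)}\t"
                         f"{int(c.shm_context_wa)}\n")
    return genes_path, snvs_path
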