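"""Promoter membership, novelty and confidence filtering of SNV calls.

A gene's 5' regulatory region is the 4-kb window centered on its TSS
(clipped at chromosome edges).  A call is *promoter* if it falls in an
enriched window, *novel* if absent from the known-polymorphism set, and
*high confidence* if it passes the allele-ratio, alt-quality and
quality-bias (Welch t-test) gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .calling import SnvCall
from .io import GeneModel, KnownVariantSet

__all__ = ["PromoterWindow", "build_windows", "annotate_calls",
           "confidence_filter", "quality_offset", "default_min_quality"]

#: ASCII offset of each supported FASTQ quality encoding.
_ENCODING_OFFSETS = {"phred+33": 33, "phred+64": 64}

#: Default mean alt-quality threshold on the raw ASCII scale, per encoding.
#: Both correspond to Phred >= 26.
_DEFAULT_MIN_QUALITY = {"phred+33": 59, "phred+64": 90}


def quality_offset(encoding: str) -> int:
    try:
        return _ENCODING_OFFSETS[encoding]
    except KeyError:
        raise ValueError(f"unknown quality encoding {encoding!r}; expected "
                         f"one of {sorted(_ENCODING_OFFSETS)}") from None


def default_min_quality(encoding: str) -> int:
    quality_offset(encoding)  # validate
    return _DEFAULT_MIN_QUALITY[encoding]


@dataclass
class PromoterWindow:
    """A gene's TSS-centered window ([tss-half, tss+half), clipped)."""

    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    enriched: bool = False
    covered_positions: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=np.int64))

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


def build_windows(genes: list[GeneModel], chrom_lengths: dict[str, int],
                  half_width: int = 2000) -> list[PromoterWindow]:
    """One promoter window per gene model, clipped to the chromosome.

    When several models share a gene name (per-transcript mode),
    overlapping same-gene windows are merged into one spanning window
    whose TSS is the 5'-most on the gene strand.
    """
    windows = []
    for g in genes:
        limit = chrom_lengths[g.chrom]
        windows.append(PromoterWindow(
            gene_name=g.gene_name, chrom=g.chrom, strand=g.strand,
            start=max(g.tss - half_width, 0),
            end=min(g.tss + half_width, limit), tss=g.tss))
    return _merge_same_gene(windows)


def _merge_same_gene(windows: list[PromoterWindow]) -> list[PromoterWindow]:
    windows = sorted(windows, key=lambda w: (w.gene_name, w.chrom, w.start))
    merged: list[PromoterWindow] = []
    for w in windows:
        prev = merged[-1] if merged else None
        if (prev is not None and prev.gene_name == w.gene_name
                and prev.chrom == w.chrom and w.start <= prev.end):
            prev.end = max(prev.end, w.end)
            if (w.tss < prev.tss) == (prev.strand == "+"):
                prev.tss = w.tss
        else:
            merged.append(w)
    return merged


def _window_trees(windows) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        if w.end > w.start:
            trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, w)
    return trees


def annotate_calls(calls: list[SnvCall], windows: list[PromoterWindow],
                   known: KnownVariantSet,
                   allele_aware: bool = False) -> list[SnvCall]:
    """Set promoter / novelty flags and gene assignment on calls, in place.

    ``promoter`` is set iff the position lies in an *enriched* window;
    gene assignment and TSS-relative orientation use every enriched window
    containing the call.  Novelty is a position-level dbSNP lookup unless
    ``allele_aware`` is requested.
    """
    trees = _window_trees([w for w in windows if w.enriched])
    for call in calls:
        hits = trees.get(call.chrom, IntervalTree())[call.pos]
        call.promoter = bool(hits)
        call.genes = sorted({iv.data.gene_name for iv in hits})
        if hits:
            # downstream = 3' of the TSS in gene orientation (TSS inclusive)
            w = min((iv.data for iv in hits), key=lambda w: w.gene_name)
            call.downstream_of_tss = (call.pos >= w.tss if w.strand == "+"
                                      else call.pos <= w.tss)
        if allele_aware:
            call.novel = not known.contains_allele(
                call.chrom, call.pos, call.alt_base)
        else:
            call.novel = (call.chrom, call.pos) not in known
    return calls


def _welch_p(ref_q: np.ndarray, alt_q: np.ndarray) -> float:
    """Two-sided Welch t-test p-value; NaN when undefined.

    Undefined cases — either group with < 2 observations, or zero variance
    in both groups — cannot reject quality equality.
    """
    if len(ref_q) < 2 or len(alt_q) < 2:
        return float("nan")
    if np.ptp(ref_q) == 0 and np.ptp(alt_q) == 0:
        return float("nan") if ref_q[0] == alt_q[0] else 0.0
    return float(stats.ttest_ind(ref_q, alt_q, equal_var=False).pvalue)


def confidence_filter(calls: list[SnvCall], min_ratio: float = 0.33,
                      min_quality: float | None = None,
                      min_ttest_p: float = 0.05,
                      encoding: str = "phred+33") -> list[SnvCall]:
    """Set the ``high_confidence`` flag; return the passing subset.

    Gates: allele ratio k/n >= ``min_ratio``; mean alt-supporting base
    quality on the raw ASCII scale >= ``min_quality`` (default: the
    Phred>=26 equivalent for the configured encoding — 90 for phred+64,
    59 for phred+33); Welch t-test comparing ref-read vs alt-read
    qualities with p >= ``min_ttest_p``.  When the t-test is undefined
    (k = n, or a group smaller than 2) the gate passes vacuously.
    """
    if not 0 <= min_ratio <= 1:
        raise ValueError(f"min_ratio must be in [0, 1], got {min_ratio}")
    offset = quality_offset(encoding)
    if min_quality is None:
        min_quality = _DEFAULT_MIN_QUALITY[encoding]
    passed = []
    for call in calls:
        ref_q = call.ref_qualities + offset
        alt_q = call.alt_qualities + offset
        call.mean_ref_quality = float(ref_q.mean()) if len(ref_q) else float("nan")
        call.mean_alt_quality = float(alt_q.mean()) if len(alt_q) else float("nan")
        tp = _welch_p(ref_q, alt_q)
        call.quality_ttest_p = tp
        ok = (call.ratio >= min_ratio
              and call.mean_alt_quality >= min_quality
              and (np.isnan(tp) or tp >= min_ttest_p))
        call.high_confidence = bool(ok)
        if ok:
            passed.append(call)
    return passed
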