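"""Promoter-window enrichment calls.

Downstream hotspot statistics use only mark-enriched promoter windows as
their universe (both for the per-gene expected SNV rate and for the
promoter flag on calls), so the enrichment decision defines the analysis
universe.  Three modes are offered:

* ``min-reads`` (default): at least N deduplicated reads overlap the
  window;
* ``poisson-background``: window read count exceeds the genome-wide
  expectation at a BH-adjusted Poisson tail <= 0.05;
* ``external-bed``: the window intersects a supplied peak BED.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .annotate import PromoterWindow
from .calling import bh_adjust
from .reads import ReadBatch

__all__ = ["select_enriched", "window_read_counts"]


def window_read_counts(windows: list[PromoterWindow],
                       batch: ReadBatch) -> np.ndarray:
    """Number of reads overlapping each window."""
    counts = np.zeros(len(windows), dtype=np.int64)
    ends = batch.end
    for cid, chrom in enumerate(batch.chrom_names):
        mask = batch.chrom_id == cid
        if not mask.any():
            continue
        starts_sorted = np.sort(batch.start[mask])
        ends_sorted = np.sort(ends[mask])
        for i, w in enumerate(windows):
            if w.chrom != chrom:
                continue
            n_started = np.searchsorted(starts_sorted, w.end, side="left")
            n_ended = np.searchsorted(ends_sorted, w.start, side="right")
            counts[i] = n_started - n_ended
    return counts


def _read_bed_intervals(path: str) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2])))
    return out


def select_enriched(windows: list[PromoterWindow], batch: ReadBatch | None,
                    mode: str = "min-reads", min_reads: int = 20,
                    genome_length: int | None = None,
                    peaks_bed: str | None = None,
                    alpha: float = 0.05) -> list[PromoterWindow]:
    """Set the ``enriched`` flag on each window; return the windows.

    ``poisson-background`` computes the expected per-window count as
    ``total_reads * window_length / genome_length`` and keeps windows whose
    count clears the Poisson upper tail at BH-adjusted ``alpha``.
    """
    if mode == "external-bed":
        if peaks_bed is None:
            raise ValueError("external-bed enrichment needs a peak BED file")
        peaks = _read_bed_intervals(peaks_bed)
        for w in windows:
            w.enriched = any(s < w.end and e > w.start
                             for s, e in peaks.get(w.chrom, []))
        return windows

    if batch is None:
        raise ValueError(f"{mode} enrichment needs the read batch")
    counts = window_read_counts(windows, batch)

    if mode == "min-reads":
        for w, c in zip(windows, counts):
            w.enriched = bool(c >= min_reads)
    elif mode == "poisson-background":
        if genome_length is None:
            raise ValueError("poisson-background needs the genome length")
        total = len(batch)
        pvals = np.array([
            stats.poisson.sf(c - 1, total * (w.end - w.start) / genome_length)
            if c > 0 else 1.0
            for w, c in zip(windows, counts)])
        qvals = bh_adjust(pvals)
        for w, q in zip(windows, qvals):
            w.enriched = bool(q <= alpha)
    else:
        raise ValueError(f"unknown enrichment mode {mode!r}")
    return windows
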