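"""Clonal-read deduplication, per-cycle error profile, and pileups.

The error model is the null for variant calling: for each sequencing
cycle *i* the mismatch rate

    p_i = (# reads mismatching the reference at cycle i) / (# reads of
          length > i)

is estimated over the whole deduplicated experiment, and the odds weight
``w_i = p_i / (1 - p_i)`` feeds the Poisson-Binomial significance test.
Cycle indices are mirrored for reverse-strand alignments so that the
profile reflects sequencing cycles (where Illumina error accumulates),
not genomic orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome
from .reads import ReadBatch

__all__ = ["ErrorProfile", "deduplicate", "build_error_profile",
           "PileupSite", "pileup", "region_coverage", "chrom_coverage",
           "region_entry_mask"]


@dataclass
class ErrorProfile:
    """Per-cycle mismatch rates for one sequencing experiment."""

    p: np.ndarray                # mismatch rate per cycle
    mismatch_counts: np.ndarray  # mismatching reads per cycle
    totals: np.ndarray           # reads of length > i, per cycle
    total_reads: int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        if np.any(self.p >= 1.0) or np.any(self.p < 0.0):
            raise ValueError("error profile has p_i outside [0, 1); "
                             "input alignments look corrupt")

    @property
    def w(self) -> np.ndarray:
        """Odds weights w_i = p_i / (1 - p_i)."""
        return self.p / (1.0 - self.p)

    def __len__(self) -> int:
        return len(self.p)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("cycle\tmismatches\ttotal\tp\n")
            for i in range(len(self.p)):
                fh.write(f"{i}\t{int(self.mismatch_counts[i])}\t"
                         f"{int(self.totals[i])}\t{self.p[i]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "ErrorProfile":
        rows = np.loadtxt(path, skiprows=1, ndmin=2)
        if rows.size == 0:
            raise ValueError(f"{path}: empty error profile")
        return cls(p=rows[:, 3], mismatch_counts=rows[:, 1].astype(np.int64),
                   totals=rows[:, 2].astype(np.int64),
                   total_reads=int(rows[:, 2].max()))


def deduplicate(batch: ReadBatch) -> ReadBatch:
    """Collapse clonal reads: one read per (chrom, 5' start, strand) key.

    The retained read is the one with the highest mean base quality; ties
    keep the first encountered.  Requires coordinate-sorted input.
    Idempotent.
    """
    if not batch.is_sorted():
        raise ValueError("deduplicate requires coordinate-sorted input")
    if len(batch) == 0:
        return batch
    start5 = batch.start5
    meanq = batch.mean_quality
    idx = np.arange(len(batch))
    # sort by key, then best quality first, then original order
    order = np.lexsort((idx, -meanq, batch.is_reverse.astype(np.int8),
                        start5, batch.chrom_id))
    cid, s5, rev = (batch.chrom_id[order], start5[order],
                    batch.is_reverse[order])
    new_group = np.ones(len(order), dtype=bool)
    new_group[1:] = ((cid[1:] != cid[:-1]) | (s5[1:] != s5[:-1])
                     | (rev[1:] != rev[:-1]))
    keep = np.zeros(len(batch), dtype=bool)
    keep[order[new_group]] = True
    return batch.select(keep)


def build_error_profile(batch: ReadBatch, genome: Genome) -> ErrorProfile:
    """Per-cycle mismatch rates over all (deduplicated) reads genome-wide.

    Denominator at cycle *i* is the number of reads longer than *i* bases,
    so mixed 36/50-bp experiments are handled.  Reference-N positions do
    not count as mismatches.
    """
    if len(batch) == 0:
        raise ValueError("cannot build an error profile from zero reads")
    max_len = int(batch.length.max())
    mismatch = mismatch_flags(batch, genome)
    cycles = batch.cycle()
    mm_counts = np.bincount(cycles[mismatch], minlength=max_len)
    # reads of length > i
    len_hist = np.bincount(batch.length, minlength=max_len + 1)
    totals = np.cumsum(len_hist[::-1])[::-1][1:]
    p = np.zeros(max_len)
    nz = totals > 0
    p[nz] = mm_counts[nz] / totals[nz]
    if np.any(p >= 1.0):
        bad = int(np.argmax(p >= 1.0))
        raise ValueError(
            f"mismatch rate 1.0 at cycle {bad}: every read disagrees with "
            "the reference there — wrong reference or corrupt input")
    return ErrorProfile(p=p, mismatch_counts=mm_counts, totals=totals,
                        total_reads=len(batch))


def mismatch_flags(batch: ReadBatch, genome: Genome) -> np.ndarray:
    """Per-entry reference-mismatch flags (cached on the batch)."""
    if "mismatch" not in batch._cache:
        ref = _reference_codes(batch, genome)
        batch._cache["mismatch"] = ((batch.base != ref) & (ref < 4)
                                    & (batch.base < 4))
    return batch._cache["mismatch"]


def _reference_codes(batch: ReadBatch, genome: Genome) -> np.ndarray:
    """Reference base code under every flat aligned-base entry.

    Cached on the batch (one reference genome per batch is assumed).
    """
    if "ref_codes" not in batch._cache:
        present = np.unique(batch.chrom_id)
        if len(present) == 1:
            name = batch.chrom_names[int(present[0])]
            ref = genome.codes(name)[batch.refpos]
        else:
            ref = np.empty(batch.n_bases, dtype=np.uint8)
            entry_chrom = batch.entry_chrom
            for cid in present:
                mask = entry_chrom == cid
                name = batch.chrom_names[int(cid)]
                ref[mask] = genome.codes(name)[batch.refpos[mask]]
        batch._cache["ref_codes"] = ref
    return batch._cache["ref_codes"]


@dataclass
class PileupSite:
    """Read evidence at one genomic position.

    ``k`` counts *all* non-reference reads; ``alt_base`` is the modal
    non-reference base (ties broken in A<C<G<T order) and ``alt_count``
    its read count.  ``match_cycles``/``mismatch_cycles`` record the
    sequencing-cycle index of every retained read so the caller can
    assemble the per-site Poisson-Binomial null.
    """

    chrom: str
    pos: int
    ref_base: str
    n: int
    k: int
    alt_base: str
    alt_count: int
    match_cycles: np.ndarray
    mismatch_cycles: np.ndarray
    ref_qualities: np.ndarray
    alt_qualities: np.ndarray

    @property
    def all_cycles(self) -> np.ndarray:
        return np.concatenate([self.match_cycles, self.mismatch_cycles])


_BASES = "ACGTN"


def region_entry_mask(batch: ReadBatch, regions) -> np.ndarray:
    """Boolean mask of flat entries lying inside any region.

    Uses a per-chromosome position lookup table, so overlapping regions
    are handled and the per-entry cost is one gather.
    """
    cname_idx = {c: i for i, c in enumerate(batch.chrom_names)}
    by_chrom: dict[int, list[tuple[int, int]]] = {}
    for reg in regions:
        cid = cname_idx.get(reg.chrom)
        if cid is not None and reg.end > reg.start:
            by_chrom.setdefault(cid, []).append((reg.start, reg.end))
    keep = np.zeros(batch.n_bases, dtype=bool)
    entry_chrom = batch.entry_chrom
    single = len(np.unique(batch.chrom_id)) == 1
    for cid, spans in by_chrom.items():
        cmask = None if single else entry_chrom == cid
        pos = batch.refpos if single else batch.refpos[cmask]
        if len(pos) == 0:
            continue
        hi = max(e for _, e in spans)
        table = np.zeros(hi + 1, dtype=bool)
        for s0, e0 in spans:
            table[s0:e0] = True
        inside = (pos <= hi) & table[np.minimum(pos, hi)]
        if single:
            if int(batch.chrom_id[0]) == cid:
                keep |= inside
        else:
            keep[np.flatnonzero(cmask)[inside]] = True
    return keep


def pileup(batch: ReadBatch, genome: Genome, regions,
           min_alt: int = 0, min_base_quality: int | None = None):
    """Yield one :class:`PileupSite` per covered position inside a region.

    ``regions`` is an iterable with ``chrom``/``start``/``end`` attributes
    (promoter windows).  Sites whose reference base is N are skipped.
    ``min_alt`` > 0 restricts emission to sites with at least that many
    mismatching reads (the variant-calling fast path); the default emits
    every site with n >= 1.  ``min_base_quality`` optionally drops bases
    below a quality floor before counting (default: no floor).
    """
    if len(batch) == 0:
        return
    ref_flat = _reference_codes(batch, genome)
    cycles = batch.cycle()
    entry_chrom = batch.entry_chrom

    keep = region_entry_mask(batch, regions)
    if min_base_quality is not None:
        keep &= batch.qual >= min_base_quality
    sel = np.flatnonzero(keep)
    if len(sel) == 0:
        return
    order = sel[np.lexsort((batch.refpos[sel], entry_chrom[sel]))]
    refpos = batch.refpos[order]
    chrom = entry_chrom[order]
    base = batch.base[order]
    ref = ref_flat[order]
    cyc = cycles[order]
    qual = batch.qual[order]
    mism = (base != ref) & (base < 4)

    bnd = np.flatnonzero(np.concatenate(
        [[True], (refpos[1:] != refpos[:-1]) | (chrom[1:] != chrom[:-1])]))
    bnd = np.concatenate([bnd, [len(order)]])
    if min_alt > 0:
        has_alt = np.add.reduceat(mism.astype(np.int32), bnd[:-1]) >= min_alt
    else:
        has_alt = np.ones(len(bnd) - 1, dtype=bool)

    for gi in np.flatnonzero(has_alt):
        lo, hi = bnd[gi], bnd[gi + 1]
        rb = ref[lo]
        if rb >= 4:
            continue  # reference N: no call possible
        b = base[lo:hi]
        m = mism[lo:hi]
        k = int(m.sum())
        if k < min_alt:
            continue
        counts = np.bincount(b[m], minlength=4) if k else np.zeros(4, int)
        alt_code = int(np.argmax(counts)) if k else 4
        is_ref = b == rb
        is_alt = b == alt_code if k else np.zeros(hi - lo, dtype=bool)
        yield PileupSite(
            chrom=batch.chrom_names[chrom[lo]], pos=int(refpos[lo]),
            ref_base=_BASES[rb], n=int(hi - lo), k=k,
            alt_base=_BASES[alt_code] if k else "", alt_count=int(counts[alt_code]) if k else 0,
            match_cycles=cyc[lo:hi][~m], mismatch_cycles=cyc[lo:hi][m],
            ref_qualities=qual[lo:hi][is_ref],
            alt_qualities=qual[lo:hi][is_alt])


def region_coverage(batch: ReadBatch, region) -> np.ndarray:
    """Read depth at each position of ``[region.start, region.end)``."""
    cov = chrom_coverage(batch)[region.chrom]
    out = np.zeros(region.end - region.start, dtype=np.int64)
    hi = min(region.end, len(cov))
    if hi > region.start:
        out[:hi - region.start] = cov[region.start:hi]
    return out


def chrom_coverage(batch: ReadBatch) -> dict[str, np.ndarray]:
    """Per-chromosome depth arrays (cached on the batch)."""
    if "chrom_coverage" not in batch._cache:
        out = {}
        entry_chrom = batch.entry_chrom
        for cid, name in enumerate(batch.chrom_names):
            mask = entry_chrom == cid
            out[name] = np.bincount(batch.refpos[mask])
        batch._cache["chrom_coverage"] = out
    return batch._cache["chrom_coverage"]
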