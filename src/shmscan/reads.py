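"""Aligned-read containers.

Two representations are provided:

* :class:`AlignedRead` — a per-read record mirroring what a SAM line
  carries (used at I/O boundaries and in small tests);
* :class:`ReadBatch` — a columnar, numpy-backed container holding the
  aligned, non-clipped bases of many reads as flat arrays.  All heavy
  operations (deduplication, error profiling, pileup) run on batches.

Only M/=/X-aligned bases are retained; insertions, deletions and clipped
bases never enter a batch.  Positions in read (``qpos``) are 0-based query
offsets; the *sequencing cycle* of a base is ``qpos`` for forward-strand
alignments and ``length-1-qpos`` for reverse-strand alignments, because SAM
stores reverse reads reverse-complemented to the forward genome strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam


@dataclass
class AlignedRead:
    """One aligned read: per-base tuples for aligned, non-clipped bases."""

    chrom: str
    start: int            # 0-based leftmost aligned reference position
    is_reverse: bool
    length: int           # full read length (including clipped bases)
    qpos: np.ndarray      # query offsets of aligned bases
    refpos: np.ndarray    # reference positions of aligned bases
    base: np.ndarray      # uint8 base codes
    qual: np.ndarray      # raw integer quality scores (no offset arithmetic)
    mapq: int = 60
    name: str = ""

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @property
    def end(self) -> int:
        """One past the rightmost aligned reference position."""
        return int(self.refpos.max()) + 1 if len(self.refpos) else self.start

    @property
    def start5(self) -> int:
        """5' alignment start: leftmost base for '+', rightmost for '-'."""
        return self.end - 1 if self.is_reverse else self.start

    @property
    def mean_quality(self) -> float:
        return float(self.qual.mean()) if len(self.qual) else 0.0

    @property
    def cycle(self) -> np.ndarray:
        """Sequencing-cycle index of each aligned base."""
        if self.is_reverse:
            return self.length - 1 - self.qpos
        return self.qpos.copy()


class ReadBatch:
    """Columnar store of aligned reads (single- or multi-chromosome)."""

    def __init__(self, chrom_names, chrom_id, start, is_reverse, length,
                 mapq, bounds, qpos, refpos, base, qual, names=None):
        self.chrom_names = list(chrom_names)
        self.chrom_id = np.asarray(chrom_id, dtype=np.int16)
        self.start = np.asarray(start, dtype=np.int64)
        self.is_reverse = np.asarray(is_reverse, dtype=bool)
        self.length = np.asarray(length, dtype=np.int32)
        self.mapq = np.asarray(mapq, dtype=np.int32)
        self.bounds = np.asarray(bounds, dtype=np.int64)   # (n_reads + 1,)
        # per-base columns are kept narrow: batches reach ~10^8 entries
        self.qpos = np.asarray(qpos, dtype=np.int16)
        self.refpos = np.asarray(refpos, dtype=np.int32)
        self.base = np.asarray(base, dtype=np.uint8)
        self.qual = np.asarray(qual, dtype=np.int16)
        self.names = names
        self._cache: dict = {}

    # -- basic properties -------------------------------------------------
    # Batches are treated as immutable after construction; derived arrays
    # are cached because they are repeatedly needed on multi-million-entry
    # batches.

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_bases(self) -> int:
        return len(self.refpos)

    @property
    def counts(self) -> np.ndarray:
        return np.diff(self.bounds)

    @property
    def read_index(self) -> np.ndarray:
        """Read index of each flat base entry."""
        if "read_index" not in self._cache:
            self._cache["read_index"] = np.repeat(
                np.arange(len(self), dtype=np.int32), self.counts)
        return self._cache["read_index"]

    @property
    def entry_chrom(self) -> np.ndarray:
        """Chromosome id of each flat base entry."""
        if "entry_chrom" not in self._cache:
            self._cache["entry_chrom"] = self.chrom_id[self.read_index]
        return self._cache["entry_chrom"]

    @property
    def end(self) -> np.ndarray:
        """Per-read one-past-rightmost aligned reference position."""
        out = np.zeros(len(self), dtype=np.int64)
        nz = self.counts > 0
        if nz.any():
            ends = np.maximum.reduceat(self.refpos, self.bounds[:-1][nz]) + 1
            out[nz] = ends
        out[~nz] = self.start[~nz]
        return out

    @property
    def start5(self) -> np.ndarray:
        return np.where(self.is_reverse, self.end - 1, self.start)

    @property
    def mean_quality(self) -> np.ndarray:
        out = np.zeros(len(self))
        nz = self.counts > 0
        if nz.any():
            sums = np.add.reduceat(self.qual.astype(np.float64),
                                   self.bounds[:-1][nz])
            out[nz] = sums / self.counts[nz]
        return out

    def cycle(self) -> np.ndarray:
        """Sequencing-cycle index of every flat base entry."""
        if "cycle" not in self._cache:
            ridx = self.read_index
            rev = self.is_reverse[ridx]
            self._cache["cycle"] = np.where(
                rev, self.length[ridx] - 1 - self.qpos,
                self.qpos).astype(np.int16)
        return self._cache["cycle"]

    def is_sorted(self) -> bool:
        """Coordinate-sorted: chrom blocks with non-decreasing starts."""
        if len(self) < 2:
            return True
        cid, st = self.chrom_id, self.start
        same = cid[1:] == cid[:-1]
        if np.any(same & (st[1:] < st[:-1])):
            return False
        # each chromosome forms one contiguous block
        changes = np.flatnonzero(cid[1:] != cid[:-1])
        return len(np.unique(cid[np.r_[0, changes + 1]])) == len(changes) + 1

    # -- construction -----------------------------------------------------

    @classmethod
    def from_reads(cls, reads: list[AlignedRead],
                   chrom_names: list[str] | None = None) -> "ReadBatch":
        if chrom_names is None:
            chrom_names = []
            for r in reads:
                if r.chrom not in chrom_names:
                    chrom_names.append(r.chrom)
        cidx = {c: i for i, c in enumerate(chrom_names)}
        counts = np.array([len(r.qpos) for r in reads], dtype=np.int64)
        bounds = np.concatenate([[0], np.cumsum(counts)])
        cat = (lambda key, dt: np.concatenate(
            [np.asarray(getattr(r, key), dtype=dt) for r in reads])
            if reads else np.array([], dtype=dt))
        return cls(
            chrom_names=chrom_names,
            chrom_id=[cidx[r.chrom] for r in reads],
            start=[r.start for r in reads],
            is_reverse=[r.is_reverse for r in reads],
            length=[r.length for r in reads],
            mapq=[r.mapq for r in reads],
            bounds=bounds,
            qpos=cat("qpos", np.int32),
            refpos=cat("refpos", np.int64),
            base=cat("base", np.uint8),
            qual=cat("qual", np.int16),
            names=[r.name for r in reads],
        )

    def to_reads(self) -> list[AlignedRead]:
        out = []
        for i in range(len(self)):
            lo, hi = self.bounds[i], self.bounds[i + 1]
            out.append(AlignedRead(
                chrom=self.chrom_names[self.chrom_id[i]],
                start=int(self.start[i]),
                is_reverse=bool(self.is_reverse[i]),
                length=int(self.length[i]),
                qpos=self.qpos[lo:hi].copy(),
                refpos=self.refpos[lo:hi].copy(),
                base=self.base[lo:hi].copy(),
                qual=self.qual[lo:hi].copy(),
                mapq=int(self.mapq[i]),
                name=self.names[i] if self.names else "",
            ))
        return out

    def select(self, mask: np.ndarray) -> "ReadBatch":
        """New batch with the reads where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        flat_mask = np.repeat(mask, self.counts)
        counts = self.counts[mask]
        bounds = np.concatenate([[0], np.cumsum(counts)])
        names = ([n for n, m in zip(self.names, mask) if m]
                 if self.names else None)
        return ReadBatch(
            self.chrom_names, self.chrom_id[mask], self.start[mask],
            self.is_reverse[mask], self.length[mask], self.mapq[mask],
            bounds, self.qpos[flat_mask], self.refpos[flat_mask],
            self.base[flat_mask], self.qual[flat_mask], names)


# -- SAM/BAM I/O ---------------------------------------------------------

def read_alignments(path: str, min_mapq: int = 1) -> ReadBatch:
    """Load uniquely aligned reads from a SAM/BAM file into a batch.

    Secondary, supplementary and unmapped records are dropped.  Mapping
    uniqueness is enforced as ``MAPQ >= min_mapq`` (default 1, i.e. exclude
    MAPQ-0 multi-mappers).  Only M/=/X-aligned bases are kept.
    """
    from .genome import _CODE

    mode = "rb" if str(path).endswith(".bam") else "r"
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        chrom_names = list(fh.references)
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            seq = aln.query_sequence
            if seq is None:
                continue
            quals = aln.query_qualities
            pairs = aln.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.fromiter((q for q, _ in pairs), dtype=np.int32)
            refpos = np.fromiter((r for _, r in pairs), dtype=np.int64)
            codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)][qpos]
            qual = (np.asarray(quals, dtype=np.int16)[qpos] if quals is not None
                    else np.zeros(len(qpos), dtype=np.int16))
            reads.append(AlignedRead(
                chrom=aln.reference_name, start=aln.reference_start,
                is_reverse=aln.is_reverse, length=len(seq),
                qpos=qpos, refpos=refpos, base=codes, qual=qual,
                mapq=aln.mapping_quality, name=aln.query_name))
    batch = ReadBatch.from_reads(reads, chrom_names=chrom_names or None)
    return batch


def write_sam(batch: ReadBatch, path: str,
              chrom_lengths: dict[str, int]) -> None:
    """Write a batch of ungapped alignments as a SAM file.

    Intended for the synthetic-read generator: every read must be fully
    aligned (contiguous query offsets 0..L-1), which simulated reads are.
    """
    from .genome import decode

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": int(chrom_lengths[c])}
                     for c in batch.chrom_names]}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i in range(len(batch)):
            lo, hi = batch.bounds[i], batch.bounds[i + 1]
            a = pysam.AlignedSegment(fh.header)
            a.query_name = (batch.names[i] if batch.names else f"r{i:08d}")
            a.query_sequence = decode(batch.base[lo:hi])
            a.flag = 16 if batch.is_reverse[i] else 0
            a.reference_id = int(batch.chrom_id[i])
            a.reference_start = int(batch.start[i])
            a.mapping_quality = int(batch.mapq[i])
            a.cigarstring = f"{hi - lo}M"
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in batch.qual[lo:hi]))
            fh.write(a)
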