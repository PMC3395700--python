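"""Synthetic fixture generator.

Produces a self-consistent bundle — random genome, gene models,
known-polymorphism set, and aligned ChIP-seq-like reads — with planted
germline SNPs, novel SNVs and AID-motif-context SHM hotspots, plus a
ground-truth manifest.  It emulates the data model of promoter-mark
ChIP-seq in hypermutating B cells:

* reads tile 4-kb TSS-centered windows at a configurable mean depth,
  50/50 forward/reverse, with a position-in-read (cycle) dependent error
  rate rising linearly along the read, as in Illumina sequencing;
* SHM plants sit at motif-mutable bases (the G/C of RGYW/WRCY or the
  A/T of WA/TW), are transition-biased (G→A, C→T), skew downstream of
  the TSS, and carry an elevated alternate-allele fraction (active-mark
  ChIP enriches the mutated, transcriptionally engaged allele: validated
  SHM sites in such data show alternate fractions well above 0.5);
* germline SNPs are planted at allele fraction 0.5 or 1.0 and listed in
  the known-variant file.

Base qualities are flat (no quality noise is simulated); PCR duplicates
are injected as exact copies at a configurable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import Genome, decode
from .io import GeneModel
from .reads import ReadBatch, write_sam

__all__ = ["SimConfig", "PlantedHotspot", "PlantedScattered",
           "PlantedVariant", "SimulatedData", "simulate_genome",
           "simulate_reads", "read_manifest"]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class PlantedHotspot:
    gene_index: int
    n_shm: int
    motif_class: str = "RGYW"
    allele_fraction: float = 0.6


@dataclass
class PlantedScattered:
    gene_index: int
    n_snv: int
    allele_fraction: float = 0.5


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment."""

    seed: int = 0
    n_genes: int = 20
    gene_spacing: int = 6000
    window_half: int = 2000
    chrom_name: str = "chrS"
    read_length: int = 50
    mean_depth: float = 30.0
    error_rate_start: float = 0.001   # per-cycle error at the first cycle
    error_rate_end: float = 0.01     # ... at the last cycle (linear ramp)
    gc_content: float = 0.5
    base_quality: int = 35            # flat Phred score for every base
    n_snps: int = 0                   # germline plants, listed as known
    snp_allele_fractions: tuple = (0.5, 1.0)
    n_snvs: int = 0                   # novel plants scattered over windows
    snv_allele_fraction: float = 0.5
    shm_transition_prob: float = 0.8
    shm_downstream_prob: float = 0.8
    duplicate_fraction: float = 0.03
    unenriched_gene_indices: tuple = ()
    planted_hotspots: list = field(default_factory=list)
    planted_scattered: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("error_rate_start", "error_rate_end", "gc_content",
                     "duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} outside [0, 1)")
        for name in ("snv_allele_fraction", "shm_transition_prob",
                     "shm_downstream_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if 2 * self.window_half > self.gene_spacing:
            raise ValueError("4-kb windows cannot be placed without overlap "
                             f"at spacing {self.gene_spacing}")

    @property
    def error_curve(self) -> np.ndarray:
        return np.linspace(self.error_rate_start, self.error_rate_end,
                           self.read_length)


@dataclass
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str            # "snp", "snv" or "shm"
    gene: str
    allele_fraction: float
    motif_class: str = ""


@dataclass
class SimulatedData:
    genome: Genome
    genes: list[GeneModel]
    manifest: list[PlantedVariant]
    config: SimConfig

    @property
    def known_variants(self) -> list[PlantedVariant]:
        return [v for v in self.manifest if v.kind == "snp"]

    def write_fasta(self, path):
        self.genome.write_fasta(path)

    def write_refflat(self, path):
        with open(path, "w") as fh:
            for i, g in enumerate(self.genes):
                if g.strand == "+":
                    tx_start, tx_end = g.tss, g.tss + 2000
                else:
                    tx_start, tx_end = g.tss - 1999, g.tss + 1
                fh.write(f"{g.gene_name}\tTX{i:04d}\t{g.chrom}\t{g.strand}\t"
                         f"{tx_start}\t{tx_end}\t{tx_start}\t{tx_end}\t1\t"
                         f"{tx_start},\t{tx_end},\n")

    def write_known_vcf(self, path):
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name in self.genome.chrom_names:
                fh.write(f"##contig=<ID={name},"
                         f"length={self.genome.length(name)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in sorted(self.known_variants, key=lambda v: v.pos):
                fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t"
                         f".\t.\t.\n")

    def write_manifest(self, path):
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tkind\tgene\tallele_fraction\t"
                     "motif_class\n")
            for v in sorted(self.manifest, key=lambda v: (v.chrom, v.pos)):
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.kind}\t"
                         f"{v.gene}\t{v.allele_fraction}\t{v.motif_class}\n")


def read_manifest(path) -> list[PlantedVariant]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            c, p, r, a, k, g, af, mc = line.rstrip("\n").split("\t")
            out.append(PlantedVariant(c, int(p), r, a, k, g, float(af), mc))
    return out


def _window_bounds(cfg: SimConfig, gene_index: int) -> tuple[int, int, int]:
    tss = cfg.gene_spacing * gene_index + cfg.gene_spacing // 2
    return tss - cfg.window_half, tss + cfg.window_half, tss


def simulate_genome(cfg: SimConfig,
                    rng: np.random.Generator | None = None) -> SimulatedData:
    """Random genome + gene models + planted-variant ground truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    length = cfg.gene_spacing * cfg.n_genes + cfg.gene_spacing
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    chrom = cfg.chrom_name
    genome = Genome({chrom: codes})

    genes = []
    for i in range(cfg.n_genes):
        _, _, tss = _window_bounds(cfg, i)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_name=f"GENE{i:04d}", chrom=chrom,
                               strand=strand, tss=tss,
                               transcript_ids=[f"TX{i:04d}"]))

    used: set[int] = set()
    manifest: list[PlantedVariant] = []

    def plant_random(gene_index, kind, af, alt_choice="any"):
        start, end, _ = _window_bounds(cfg, gene_index)
        for _ in range(1000):
            pos = int(rng.integers(start, end))
            if pos not in used:
                break
        else:
            raise RuntimeError("could not place variant without collision")
        used.add(pos)
        ref = _BASES[codes[pos]]
        alts = [b for b in _BASES if b != ref]
        alt = str(rng.choice(alts))
        manifest.append(PlantedVariant(chrom, pos, ref, alt, kind,
                                       genes[gene_index].gene_name, af))

    enriched = [i for i in range(cfg.n_genes)
                if i not in cfg.unenriched_gene_indices]
    for _ in range(cfg.n_snps):
        af = float(rng.choice(cfg.snp_allele_fractions))
        plant_random(int(rng.choice(enriched)), "snp", af)
    for _ in range(cfg.n_snvs):
        plant_random(int(rng.choice(enriched)), "snv",
                     cfg.snv_allele_fraction)
    for spec in cfg.planted_scattered:
        for _ in range(spec.n_snv):
            plant_random(spec.gene_index, "snv", spec.allele_fraction)

    from .annotate import PromoterWindow
    from .hotspots import mutable_positions, scan_motifs

    for spec in cfg.planted_hotspots:
        start, end, tss = _window_bounds(cfg, spec.gene_index)
        gene = genes[spec.gene_index]
        win = PromoterWindow(gene.gene_name, chrom, gene.strand,
                             start, end, tss)
        mut = mutable_positions(scan_motifs(genome, win), spec.motif_class)
        mut = np.array([p for p in mut if p not in used])
        downstream = mut >= tss if gene.strand == "+" else mut <= tss
        picked: list[int] = []
        for _ in range(spec.n_shm):
            want_down = rng.random() < cfg.shm_downstream_prob
            pool = mut[downstream] if want_down else mut[~downstream]
            pool = np.setdiff1d(pool, picked)
            if len(pool) == 0:
                pool = np.setdiff1d(mut, picked)
            if len(pool) == 0:
                raise RuntimeError(
                    f"gene {gene.gene_name}: not enough "
                    f"{spec.motif_class}-mutable positions to plant "
                    f"{spec.n_shm} SHMs")
            picked.append(int(rng.choice(pool)))
        for pos in picked:
            used.add(pos)
            ref = _BASES[codes[pos]]
            if rng.random() < cfg.shm_transition_prob:
                alt = _TRANSITION[ref]
            else:
                alt = str(rng.choice([b for b in _BASES
                                      if b not in (ref, _TRANSITION[ref])]))
            manifest.append(PlantedVariant(
                chrom, pos, ref, alt, "shm", gene.gene_name,
                spec.allele_fraction, spec.motif_class))
    return SimulatedData(genome=genome, genes=genes, manifest=manifest,
                         config=cfg)


def simulate_reads(sim: SimulatedData,
                   rng: np.random.Generator | None = None) -> ReadBatch:
    """Coordinate-sorted synthetic alignments tiling enriched windows."""
    cfg = sim.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if cfg.mean_depth <= 0 and sim.manifest:
        raise ValueError("planted variants with zero depth can never be "
                         "observed")
    chrom = cfg.chrom_name
    codes = sim.genome.codes(chrom)
    L = cfg.read_length
    curve = cfg.error_curve

    by_gene: dict[str, list[PlantedVariant]] = {}
    for v in sim.manifest:
        by_gene.setdefault(v.gene, []).append(v)

    all_starts, all_rev, all_bases = [], [], []
    for i, gene in enumerate(sim.genes):
        if i in cfg.unenriched_gene_indices:
            continue
        w_start, w_end, _ = _window_bounds(cfg, i)
        span = (w_end - w_start) + L - 1
        # mean_depth targets the *non-clonal* coverage that survives
        # deduplication: random tiling makes distinct molecules collide on
        # (5' start, strand), so the raw read count is inflated by the
        # exact occupancy correction for Poisson-thrown starts
        n_keys = 2 * span
        occupancy = cfg.mean_depth * span / (L * n_keys)
        if occupancy >= 1.0:
            raise ValueError(
                f"mean_depth {cfg.mean_depth} exceeds the maximum "
                f"non-clonal depth {L * 2:.0f} for {L}-bp reads")
        lam = -n_keys * np.log1p(-occupancy)
        n_reads = int(rng.poisson(lam))
        if n_reads == 0:
            continue
        starts = rng.integers(max(w_start - L + 1, 0),
                              min(w_end, len(codes) - L + 1),
                              size=n_reads)
        rev = rng.random(n_reads) < 0.5
        bases = codes[starts[:, None] + np.arange(L)].copy()
        for v in by_gene.get(gene.gene_name, []):
            cover = (starts <= v.pos) & (v.pos < starts + L)
            carry = cover & (rng.random(n_reads) < v.allele_fraction)
            bases[carry, v.pos - starts[carry]] = _BASES.index(v.alt)
        err_p = np.where(rev[:, None], curve[::-1][None, :], curve[None, :])
        err = rng.random((n_reads, L)) < err_p
        shift = rng.integers(1, 4, size=int(err.sum()))
        bases[err] = (bases[err] + shift) % 4
        if cfg.duplicate_fraction > 0:
            dup = rng.random(n_reads) < cfg.duplicate_fraction
            starts = np.concatenate([starts, starts[dup]])
            rev = np.concatenate([rev, rev[dup]])
            bases = np.concatenate([bases, bases[dup]])
        all_starts.append(starts)
        all_rev.append(rev)
        all_bases.append(bases)

    if not all_starts:
        starts = np.array([], dtype=np.int64)
        rev = np.array([], dtype=bool)
        bases = np.empty((0, L), dtype=np.uint8)
    else:
        starts = np.concatenate(all_starts)
        rev = np.concatenate(all_rev)
        bases = np.concatenate(all_bases)
    order = np.argsort(starts, kind="stable")
    starts, rev, bases = starts[order], rev[order], bases[order]

    n = len(starts)
    qpos = np.tile(np.arange(L, dtype=np.int16), n)
    refpos = (starts[:, None] + np.arange(L)).ravel()
    return ReadBatch(
        chrom_names=[chrom],
        chrom_id=np.zeros(n, dtype=np.int16),
        start=starts,
        is_reverse=rev,
        length=np.full(n, L, dtype=np.int32),
        mapq=np.full(n, 60, dtype=np.int32),
        bounds=np.arange(n + 1, dtype=np.int64) * L,
        qpos=qpos,
        refpos=refpos,
        base=bases.ravel(),
        qual=np.full(n * L, cfg.base_quality, dtype=np.int16),
    )


def write_bundle(sim: SimulatedData, batch: ReadBatch, outdir) -> dict:
    """Write FASTA, refFlat, known-variant VCF, SAM and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "refflat": outdir / "genes.refflat",
        "vcf": outdir / "known.vcf",
        "sam": outdir / "reads.sam",
        "manifest": outdir / "manifest.tsv",
    }
    sim.write_fasta(paths["fasta"])
    sim.write_refflat(paths["refflat"])
    sim.write_known_vcf(paths["vcf"])
    sim.write_manifest(paths["manifest"])
    write_sam(batch, paths["sam"],
              {c: sim.genome.length(c) for c in sim.genome.chrom_names})
    return paths
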