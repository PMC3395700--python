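"""Annotation and variant-set I/O.

All coordinates are normalized to the internal convention — 0-based,
half-open — at the parsing boundary.  Supported dialects:

* gene models: refFlat (11 columns) or BED12;
* known polymorphisms: VCF or a UCSC ``snpNNN`` table (detected from the
  file extension and header);
* output tracks: BED with single-base intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "GeneModel", "KnownVariantSet", "read_gene_models",
    "read_known_variants", "write_tracks",
]


@dataclass
class GeneModel:
    """A gene collapsed to one transcription start site.

    ``tss`` is the 0-based genomic coordinate of the first transcribed
    base: transcript start for '+' genes, transcript end − 1 for '−'.
    """

    gene_name: str
    chrom: str
    strand: str
    tss: int
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for "
                             f"{self.gene_name}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_name}")


class FormatError(ValueError):
    """Malformed input file."""


def _tss_from_span(strand: str, tx_start: int, tx_end: int) -> int:
    return tx_start if strand == "+" else tx_end - 1


def _collapse(records: list[GeneModel]) -> list[GeneModel]:
    """One model per gene symbol: 5'-most TSS on the gene strand."""
    by_gene: dict[str, GeneModel] = {}
    for rec in records:
        prev = by_gene.get(rec.gene_name)
        if prev is None:
            by_gene[rec.gene_name] = rec
            continue
        if prev.chrom != rec.chrom or prev.strand != rec.strand:
            raise FormatError(
                f"gene {rec.gene_name} has transcripts on different "
                "chromosomes or strands; cannot collapse to one TSS")
        upstream = (rec.tss < prev.tss if rec.strand == "+"
                    else rec.tss > prev.tss)
        if upstream:
            rec.transcript_ids = prev.transcript_ids + rec.transcript_ids
            by_gene[rec.gene_name] = rec
        else:
            prev.transcript_ids.extend(rec.transcript_ids)
    return list(by_gene.values())


def read_gene_models(path: str,
                     per_transcript: bool = False) -> list[GeneModel]:
    """Parse refFlat or BED12 gene models.

    The dialect is chosen from the extension (``.bed`` → BED12, otherwise
    refFlat).  By default multi-transcript genes collapse to one model at
    the 5'-most transcript start on the gene strand; with
    ``per_transcript`` one model per transcript is returned (window
    building later merges overlapping same-gene windows).
    """
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    records: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if is_bed:
                    if len(fields) < 6:
                        raise FormatError("BED12 needs >= 6 columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name, strand = fields[3], fields[5]
                    tx_id = name
                else:
                    if len(fields) < 6:
                        raise FormatError("refFlat needs >= 6 columns")
                    name, tx_id, chrom, strand = fields[:4]
                    start, end = int(fields[4]), int(fields[5])
                if strand not in ("+", "-"):
                    raise FormatError(f"missing or invalid strand {strand!r}")
                records.append(GeneModel(
                    gene_name=name, chrom=chrom, strand=strand,
                    tss=_tss_from_span(strand, start, end),
                    transcript_ids=[tx_id]))
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path}:{lineno}: malformed gene-model line: {exc}"
                ) from exc
    return records if per_transcript else _collapse(records)


class KnownVariantSet:
    """Known-polymorphism membership keyed by (chrom, 0-based position).

    Lookups are position-level by default; ``alleles`` retains the
    registered alternate alleles for optional allele-aware matching.
    """

    def __init__(self):
        self._alleles: dict[tuple[str, int], set[str]] = {}

    def add(self, chrom: str, pos: int, alt: str | None = None) -> None:
        key = (chrom, int(pos))
        entry = self._alleles.setdefault(key, set())
        if alt:
            entry.add(alt.upper())

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (key[0], int(key[1])) in self._alleles

    def contains_allele(self, chrom: str, pos: int, alt: str) -> bool:
        return alt.upper() in self._alleles.get((chrom, int(pos)), set())

    def __len__(self) -> int:
        return len(self._alleles)


def _read_vcf(path: Path, out: KnownVariantSet) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: VCF row has "
                                  f"{len(fields)} columns")
            chrom, pos, _, ref, alts = fields[:5]
            for alt in alts.split(","):
                # SNV-class records only; indels and symbolic alleles skipped
                if len(ref) == 1 and len(alt) == 1 and alt in "ACGTacgt":
                    out.add(chrom, int(pos) - 1, alt)


def _read_ucsc_table(path: Path, out: KnownVariantSet) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: UCSC snp table row has "
                                  f"{len(fields)} columns")
            # bin, chrom, chromStart, chromEnd, name, ..., class(idx 11)
            chrom, start, end = fields[1], int(fields[2]), int(fields[3])
            if end - start != 1:
                continue  # indel / multi-base record
            if len(fields) > 11 and fields[11] not in ("single", ""):
                continue
            alleles = fields[9].split("/") if len(fields) > 9 else []
            if alleles:
                for a in alleles:
                    if len(a) == 1 and a in "ACGTacgt":
                        out.add(chrom, start, a)
            else:
                out.add(chrom, start)


def read_known_variants(path: str) -> KnownVariantSet:
    """Load an SNV-class known-polymorphism set from VCF or a UCSC table.

    VCF positions (1-based) are shifted to 0-based; UCSC ``chromStart`` is
    already 0-based.  Indels are ignored; multi-allelic rows register all
    alternate alleles.
    """
    path = Path(path)
    out = KnownVariantSet()
    with open(path) as fh:
        head = fh.read(4096)
    if path.suffix.lower() == ".vcf" or head.startswith("##fileformat=VCF"):
        _read_vcf(path, out)
    elif path.suffix.lower() in (".txt", ".tsv") or head.count("\t") >= 3:
        _read_ucsc_table(path, out)
    else:
        raise FormatError(f"{path}: unrecognized known-variant dialect "
                          "(expected VCF or UCSC snp table)")
    return out


def write_tracks(calls, out_prefix: str) -> dict[str, Path]:
    """Write known / novel / SHM-context SNV calls as three BED tracks.

    Single-base 0-based half-open intervals; the name field is ``ref>alt``.
    A novel call in an AID-motif context appears in both the novel and the
    SHM track; known calls appear only in the known track.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {kind: Path(f"{prefix}.{kind}.bed")
             for kind in ("known", "novel", "shm")}
    handles = {kind: open(p, "w") for kind, p in paths.items()}
    try:
        for call in calls:
            line = (f"{call.chrom}\t{call.pos}\t{call.pos + 1}\t"
                    f"{call.ref_base}>{call.alt_base}\n")
            if call.novel:
                handles["novel"].write(line)
                if call.shm_context_rgyw or call.shm_context_wa:
                    handles["shm"].write(line)
            else:
                handles["known"].write(line)
    finally:
        for fh in handles.values():
            fh.close()
    return paths
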