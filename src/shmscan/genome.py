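"""Reference genome access.

Sequences are held as numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4)
so that pileup and error-profile computations can index the reference in
bulk.  FASTA files are read through :mod:`pyfaidx`; an in-memory constructor
exists for simulated genomes and tests.
"""

from __future__ import annotations

import numpy as np
import pyfaidx

_BASES = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


class Genome:
    """Chromosome-name → sequence mapping with array and string access."""

    def __init__(self, codes: dict[str, np.ndarray]):
        self._codes = codes

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Genome":
        return cls({name: encode(s.upper()) for name, s in seqs.items()})

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        fa = pyfaidx.Fasta(str(path), rebuild=True)
        return cls({name: encode(str(fa[name][:]).upper()) for name in fa.keys()})

    @property
    def chrom_names(self) -> list[str]:
        return list(self._codes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._codes

    def length(self, chrom: str) -> int:
        return len(self._codes[chrom])

    def codes(self, chrom: str) -> np.ndarray:
        return self._codes[chrom]

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice, clipped to the chromosome."""
        arr = self._codes[chrom]
        return decode(arr[max(start, 0):min(end, len(arr))])

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, arr in self._codes.items():
                fh.write(f">{name}\n")
                seq = decode(arr)
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
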