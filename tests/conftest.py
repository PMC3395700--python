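import numpy as np
import pytest

from shmscan import (Genome, PlantedHotspot, ReadBatch, SimConfig,
                     simulate_genome, simulate_reads)
from shmscan.reads import AlignedRead


def make_read(chrom="chrS", start=0, seq_codes=None, is_reverse=False,
              qual=35, length=None, mapq=60, name="r"):
    """Fully aligned ungapped read from a list of base codes."""
    seq_codes = np.asarray(seq_codes, dtype=np.uint8)
    L = length or len(seq_codes)
    qpos = np.arange(len(seq_codes), dtype=np.int32)
    return AlignedRead(chrom=chrom, start=start, is_reverse=is_reverse,
                       length=L, qpos=qpos, refpos=start + qpos,
                       base=seq_codes,
                       qual=np.full(len(seq_codes), qual, dtype=np.int16),
                       mapq=mapq, name=name)


def batch_of(reads):
    return ReadBatch.from_reads(reads)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated experiment reused by read-level tests."""
    cfg = SimConfig(seed=7, n_genes=6, mean_depth=20, n_snps=5, n_snvs=10,
                    planted_hotspots=[PlantedHotspot(0, 5)])
    sim = simulate_genome(cfg)
    batch = simulate_reads(sim)
    return sim, batch


@pytest.fixture()
def flat_genome():
    """All-A 200bp single-chromosome genome."""
    return Genome.from_dict({"chrS": "A" * 200})
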