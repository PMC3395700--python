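import numpy as np
import pytest

from shmscan import Genome, build_error_profile, deduplicate, pileup
from shmscan.annotate import PromoterWindow
from shmscan.error_model import ErrorProfile, region_coverage
from shmscan.genome import encode

from conftest import batch_of, make_read

A, C, G, T = 0, 1, 2, 3


def window(start, end, chrom="chrS", gene="G", enriched=True):
    return PromoterWindow(gene_name=gene, chrom=chrom, strand="+",
                          start=start, end=end, tss=(start + end) // 2,
                          enriched=enriched)


class TestDeduplicate:
    def test_same_start_and_strand_collapse_to_one(self):
        reads = [make_read(start=10, seq_codes=[A, C, G], name="a"),
                 make_read(start=10, seq_codes=[A, C, G], name="b")]
        assert len(deduplicate(batch_of(reads))) == 1

    def test_opposite_strands_both_retained(self):
        reads = [make_read(start=8, seq_codes=[A, A, G], is_reverse=True),
                 make_read(start=10, seq_codes=[A, C, G])]
        # reverse read 5' end = rightmost base (position 10): same 5' locus,
        # different strand
        assert len(deduplicate(batch_of(reads))) == 2

    def test_distinct_starts_all_retained(self):
        reads = [make_read(start=i, seq_codes=[A, C, G]) for i in range(5)]
        assert len(deduplicate(batch_of(reads))) == 5

    def test_highest_mean_quality_wins(self):
        reads = [make_read(start=10, seq_codes=[A, C, G], qual=20, name="lo"),
                 make_read(start=10, seq_codes=[A, C, G], qual=39, name="hi")]
        (kept,) = deduplicate(batch_of(reads)).to_reads()
        assert kept.name == "hi"

    def test_tie_keeps_first_encountered(self):
        reads = [make_read(start=10, seq_codes=[A, C, G], name="first"),
                 make_read(start=10, seq_codes=[G, C, A], name="second")]
        (kept,) = deduplicate(batch_of(reads)).to_reads()
        assert kept.name == "first"

    def test_idempotent(self):
        reads = [make_read(start=s, seq_codes=[A, C, G])
                 for s in (1, 1, 2, 5, 5, 5)]
        once = deduplicate(batch_of(reads))
        twice = deduplicate(once)
        assert len(once) == len(twice) == 3

    def test_unsorted_input_is_hard_error(self):
        reads = [make_read(start=10, seq_codes=[A]),
                 make_read(start=5, seq_codes=[A])]
        with pytest.raises(ValueError, match="sorted"):
            deduplicate(batch_of(reads))


class TestErrorProfile:
    def test_clean_reads_give_zero_rates(self, flat_genome):
        reads = [make_read(start=i, seq_codes=[A, A, A]) for i in range(10)]
        prof = build_error_profile(batch_of(reads), flat_genome)
        assert np.all(prof.p == 0) and np.all(prof.w == 0)

    def test_two_of_ten_mismatching_at_cycle_5(self, flat_genome):
        reads = []
        for i in range(10):
            codes = [A] * 8
            if i < 2:
                codes[5] = G
            reads.append(make_read(start=3 * i, seq_codes=codes))
        prof = build_error_profile(batch_of(reads), flat_genome)
        assert prof.p[5] == pytest.approx(0.2)
        assert prof.w[5] == pytest.approx(0.25)
        assert np.all(prof.p[[0, 1, 2, 3, 4, 6, 7]] == 0)

    def test_one_of_four_at_cycle_zero(self, flat_genome):
        reads = [make_read(start=4 * i, seq_codes=[A, A]) for i in range(3)]
        reads.append(make_read(start=12, seq_codes=[T, A]))
        prof = build_error_profile(batch_of(reads), flat_genome)
        assert prof.p[0] == pytest.approx(0.25)

    def test_reverse_strand_mismatch_counts_at_mirrored_cycle(
            self, flat_genome):
        # reverse-strand read of length 4 with a mismatch at query offset 0
        # was sequenced at cycle 3 (the SAM SEQ is genome-oriented)
        fwd = [make_read(start=4 * i, seq_codes=[A] * 4) for i in range(3)]
        rev = make_read(start=12, seq_codes=[G, A, A, A], is_reverse=True)
        prof = build_error_profile(batch_of(fwd + [rev]), flat_genome)
        assert prof.p[3] == pytest.approx(0.25)
        assert prof.p[0] == 0

    def test_mixed_lengths_use_per_cycle_denominators(self, flat_genome):
        long = [make_read(start=6 * i, seq_codes=[A] * 6) for i in range(2)]
        short = [make_read(start=20 + 3 * i, seq_codes=[G, A, A])
                 for i in range(2)]
        prof = build_error_profile(batch_of(long + short), flat_genome)
        assert prof.totals[0] == 4 and prof.totals[5] == 2
        assert prof.p[0] == pytest.approx(0.5)  # both short reads mismatch

    def test_zero_reads_is_hard_error(self, flat_genome):
        with pytest.raises(ValueError, match="zero reads"):
            build_error_profile(batch_of([]), flat_genome)

    def test_all_mismatching_cycle_is_hard_error(self, flat_genome):
        reads = [make_read(start=2 * i, seq_codes=[G, A]) for i in range(4)]
        with pytest.raises(ValueError, match="cycle 0"):
            build_error_profile(batch_of(reads), flat_genome)

    def test_tsv_round_trip(self, tmp_path, flat_genome):
        reads = [make_read(start=i, seq_codes=[A, A if i else G])
                 for i in range(4)]
        prof = build_error_profile(batch_of(reads), flat_genome)
        prof.to_tsv(tmp_path / "p.tsv")
        back = ErrorProfile.from_tsv(tmp_path / "p.tsv")
        np.testing.assert_allclose(back.p, prof.p)
        np.testing.assert_array_equal(back.mismatch_counts,
                                      prof.mismatch_counts)


class TestPileup:
    def test_clean_position_has_n4_k0(self, flat_genome):
        reads = [make_read(start=i, seq_codes=[A] * 10, name=f"r{i}")
                 for i in range(4)]
        sites = {s.pos: s for s in pileup(batch_of(reads), flat_genome,
                                          [window(0, 20)])}
        assert sites[5].n == 4 and sites[5].k == 0

    def test_modal_alt_base(self, flat_genome):
        seqs = [[A], [A], [G], [G], [G]]
        reads = [make_read(start=50, seq_codes=s, name=f"r{i}")
                 for i, s in enumerate(seqs)]
        batch = batch_of(reads)
        # bypass dedup concerns: all same start but pileup does not dedup
        (site,) = pileup(batch, flat_genome, [window(40, 60)], min_alt=1)
        assert (site.n, site.k, site.alt_base, site.alt_count) == (5, 3, "G", 3)

    def test_tie_broken_by_base_order(self, flat_genome):
        reads = [make_read(start=50, seq_codes=[C]),
                 make_read(start=50, seq_codes=[T])]
        (site,) = pileup(batch_of(reads), flat_genome, [window(40, 60)],
                         min_alt=1)
        assert site.alt_base == "C"

    def test_reference_n_site_is_skipped(self):
        genome = Genome.from_dict({"chrS": "AANA" * 20})
        reads = [make_read(start=0, seq_codes=encode("AAGA"))
                 for _ in range(3)]
        sites = list(pileup(batch_of(reads), genome, [window(0, 10)],
                            min_alt=1))
        assert sites == []

    def test_pileup_mismatches_subset_of_profile_mismatches(self, small_sim):
        sim, batch = small_sim
        dedup = deduplicate(batch)
        prof = build_error_profile(dedup, sim.genome)
        wins = [window(0, sim.genome.length("chrS"))]
        total_k = sum(s.k for s in pileup(dedup, sim.genome, wins,
                                          min_alt=1))
        assert total_k <= prof.mismatch_counts.sum()

    def test_quality_floor_drops_bases(self, flat_genome):
        reads = [make_read(start=50, seq_codes=[G], qual=10),
                 make_read(start=50, seq_codes=[G], qual=30),
                 make_read(start=50, seq_codes=[A], qual=30)]
        (site,) = pileup(batch_of(reads), flat_genome, [window(40, 60)],
                         min_alt=1, min_base_quality=20)
        assert (site.n, site.k) == (2, 1)


def test_region_coverage_counts_depth(flat_genome):
    reads = [make_read(start=10, seq_codes=[A] * 5),
             make_read(start=12, seq_codes=[A] * 5)]
    cov = region_coverage(batch_of(reads), window(10, 20))
    np.testing.assert_array_equal(cov, [1, 1, 2, 2, 2, 1, 1, 0, 0, 0])
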