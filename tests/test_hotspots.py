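from math import comb

import numpy as np
import pytest
from scipy import stats

from shmscan import Genome, classify_hotspots, gene_poisson_test
from shmscan.annotate import PromoterWindow
from shmscan.calling import SnvCall
from shmscan.genome import revcomp
from shmscan.hotspots import (MotifEnrichment, MotifHit, mutable_positions,
                              permutation_z, scan_motifs,
                              write_hotspot_report)


def window_over(seq, chrom="chrS", start=0, covered=None):
    win = PromoterWindow(gene_name="G", chrom=chrom, strand="+",
                         start=start, end=start + len(seq),
                         tss=start + len(seq) // 2, enriched=True)
    if covered is not None:
        win.covered_positions = np.asarray(covered)
    return win


def scan(seq, pad="AAA"):
    """Scan a sequence embedded in a neutral context."""
    genome = Genome.from_dict({"chrS": pad + seq + pad})
    win = window_over(seq, start=len(pad))
    return scan_motifs(genome, win)


class TestScanMotifs:
    def test_rgyw_mutable_g_at_offset_one(self):
        hits = [h for h in scan("AGCT") if h.motif_class == "RGYW"]
        # pad+seq = AAAAGCTAAA: A-G-C-T matches R-G-Y-W at seq offset 0
        assert any(h.mutable_pos == 4 and h.strand == "+" for h in hits)

    def test_wrcy_mutable_c_maps_to_rgyw_class(self):
        hits = [h for h in scan("AACT", pad="GGG")
                if h.motif_class == "RGYW"]
        # A-A-C-T matches W-R-C-Y; the mutable C is at seq offset 2
        assert [(h.mutable_pos, h.strand) for h in hits] == [(5, "-")]
        assert scan("AGTT", pad="GGG")  # its reverse complement has RGYW

    def test_wa_and_tw_shortest_motifs(self):
        hits = [h for h in scan("TA", pad="GGG") if h.motif_class == "WA"]
        assert {(h.mutable_pos, h.strand) for h in hits} == {
            (4, "+"),  # the A of TA (W=T)
            (3, "-"),  # the T of TW (W=A)
        }

    def test_motif_straddling_window_boundary_found(self):
        # full motif AGCT starts one base before the window
        genome = Genome.from_dict({"chrS": "GGAGCTGG"})
        win = window_over("GCTGG", start=3)
        hits = [h for h in scan_motifs(genome, win)
                if h.motif_class == "RGYW"]
        assert any(h.mutable_pos == 3 for h in hits)

    def test_n_bases_block_motifs(self):
        assert [h for h in scan("AGNT", pad="GGG")
                if h.motif_class == "RGYW"] == []

    def test_one_hit_per_class_per_position(self):
        # TAA: the middle A is the mutable A of two overlapping WA motifs
        hits = [h for h in scan("TAA", pad="GGG") if h.motif_class == "WA"]
        positions = [h.mutable_pos for h in hits]
        assert len(positions) == len(set(positions))

    @pytest.mark.parametrize("seed", range(25))
    def test_strand_symmetry_under_reverse_complement(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        rc = revcomp(seq)
        fwd = scan_motifs(Genome.from_dict({"chrS": seq}),
                          window_over(seq), flank=0)
        rev = scan_motifs(Genome.from_dict({"chrS": rc}),
                          window_over(rc), flank=0)
        L = len(seq)
        for cls in ("RGYW", "WA"):
            f = set(mutable_positions(fwd, cls))
            r = {L - 1 - p for p in mutable_positions(rev, cls)}
            assert f == r


class TestGenePoissonTest:
    def test_zero_count_gene_has_pvalue_one(self):
        (t,) = gene_poisson_test({"G": 0}, 100)
        assert t.pvalue == 1.0

    def test_closed_form_tail(self):
        tests = gene_poisson_test({"G1": 3, "G2": 1}, 40)
        lam = 4 / 40
        t = next(t for t in tests if t.gene_name == "G1")
        assert t.lam == pytest.approx(lam)
        assert t.pvalue == pytest.approx(float(stats.poisson.sf(2, lam)),
                                         rel=1e-12)
        assert t.pvalue == pytest.approx(1.5465e-4, rel=1e-3)

    def test_published_scale_cluster_probability(self):
        # 366 novel promoter SNVs over 16,418 enriched promoters: a 3-SNV
        # cluster is ~1.8e-6 improbable, far below the 0.005 gate
        (t,) = gene_poisson_test({"G": 3}, 16418)
        t.lam = 366 / 16418
        p = float(stats.poisson.sf(2, 366 / 16418))
        assert p == pytest.approx(1.8158e-6, rel=1e-3)
        assert p < 0.005

    def test_bh_family_is_genes_with_at_least_one(self):
        tests = gene_poisson_test({"A": 2, "B": 0, "C": 1}, 50)
        by = {t.gene_name: t for t in tests}
        assert np.isnan(by["B"].qvalue)
        assert by["A"].qvalue >= by["A"].pvalue

    def test_zero_enriched_windows_is_hard_error(self):
        with pytest.raises(ValueError, match="enriched"):
            gene_poisson_test({"G": 1}, 0)


def rgyw_hits(positions):
    return [MotifHit("chrS", int(p), "RGYW", "+") for p in positions]


class TestPermutationZ:
    def test_null_snvs_give_near_zero_z(self):
        win = window_over("A" * 1000, covered=np.arange(1000))
        hits = rgyw_hits(np.arange(0, 1000, 2))  # half the window mutable
        enr = permutation_z(win, [0, 1, 2, 3], hits, "RGYW",
                            n_perm=4000, seed=0)
        assert enr.obs == 2
        assert abs(enr.z) < 0.2

    def test_planted_enrichment_gives_large_z(self):
        win = window_over("A" * 4000, covered=np.arange(4000))
        hits = rgyw_hits(np.arange(400))  # 10% of covered positions
        enr = permutation_z(win, list(range(6)), hits, "RGYW",
                            n_perm=2000, seed=0)
        assert enr.obs == 6
        assert enr.exp == pytest.approx(0.6, abs=0.15)
        assert enr.z > 5

    def test_degenerate_null_gives_zero_z(self):
        win = window_over("A" * 10, covered=np.arange(10))
        enr = permutation_z(win, [0, 1], rgyw_hits(np.arange(10)), "RGYW",
                            n_perm=100, seed=0)
        assert (enr.sd, enr.z) == (0.0, 0.0)

    def test_more_snvs_than_covered_is_hard_error(self):
        win = window_over("AAAA", covered=[0, 1])
        with pytest.raises(ValueError, match="covered"):
            permutation_z(win, [0, 1, 2], [], "RGYW")

    def test_null_exceedance_rate_matches_hypergeometric(self):
        # drawing SNVs uniformly from covered positions, the z>1 rate is
        # the exact hypergeometric exceedance of the integer threshold
        N, K, s = 600, 180, 30
        win = window_over("A" * N, covered=np.arange(N))
        hits = rgyw_hits(np.arange(K))
        rng = np.random.default_rng(5)
        exceed = []
        for rep in range(250):
            snvs = rng.choice(N, size=s, replace=False)
            enr = permutation_z(win, snvs, hits, "RGYW", n_perm=500,
                                rng=np.random.default_rng(rep))
            exceed.append(enr.z > 1)
        mean = stats.hypergeom(N, K, s).mean()
        sd = stats.hypergeom(N, K, s).std()
        threshold = int(np.floor(mean + sd)) + 1
        exact = float(stats.hypergeom(N, K, s).sf(threshold - 1))
        assert abs(np.mean(exceed) - exact) < 0.08


def test_random_snv_placement_specificity_matches_exact_null():
    """SNVs placed uniformly (no motif preference) trip the z>1 gate for
    either motif class at the exact discrete-null rate — far below the
    planted-recovery regime, but well above a normal approximation
    because motif-hit counts are small integers."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    genome = Genome.from_dict({"chrS": seq})
    win = window_over(seq, covered=np.arange(4000))
    hits = scan_motifs(genome, win, flank=0)
    R = set(mutable_positions(hits, "RGYW"))
    W = set(mutable_positions(hits, "WA"))
    N, s = 4000, 6

    def threshold(K):
        hg = stats.hypergeom(N, K, s)
        return int(np.floor(hg.mean() + hg.std())) + 1

    t_r, t_w = threshold(len(R)), threshold(len(W))
    # exact joint exceedance by multivariate hypergeometric enumeration
    a, b, c = len(R - W), len(W - R), len(R & W)
    d = N - a - b - c
    total = comb(N, s)
    exact = 0.0
    for i in range(min(a, s) + 1):
        for j in range(min(b, s - i) + 1):
            for l in range(min(c, s - i - j) + 1):
                if (i + l >= t_r) or (j + l >= t_w):
                    exact += (comb(a, i) * comb(b, j) * comb(c, l)
                              * comb(d, s - i - j - l)) / total

    flagged = 0
    n_draws = 150
    for rep in range(n_draws):
        snvs = rng.choice(N, size=s, replace=False)
        zr = permutation_z(win, snvs, hits, "RGYW", n_perm=500,
                           rng=np.random.default_rng(1000 + rep)).z
        zw = permutation_z(win, snvs, hits, "WA", n_perm=500,
                           rng=np.random.default_rng(5000 + rep)).z
        flagged += (zr > 1) or (zw > 1)
    rate = flagged / n_draws
    assert abs(rate - exact) < 0.12
    assert rate < 0.6  # and far below the ~1.0 planted recovery rate


class TestClassify:
    @staticmethod
    def enr(z, cls="RGYW", obs=2):
        return MotifEnrichment(cls, obs, 0.3, 0.5, z)

    @staticmethod
    def calls(pairs, positions=None):
        return [SnvCall(chrom="chrS", pos=positions[i] if positions else i,
                        ref_base=r, alt_base=a, n=10, k=5, pvalue=1e-9,
                        downstream_of_tss=(i % 2 == 0))
                for i, (r, a) in enumerate(pairs)]

    def run_one(self, k, qvalue, z_rgyw, z_wa=-0.5):
        from shmscan.hotspots import GenePoissonTest
        t = GenePoissonTest("G", k, 0.02, qvalue / 10, qvalue=qvalue)
        calls = self.calls([("G", "A")] * k)
        (res,) = classify_hotspots(
            [t], {"G": calls},
            {"G": {"RGYW": self.enr(z_rgyw), "WA": self.enr(z_wa, "WA")}})
        return res

    def test_three_snvs_with_high_z_is_hotspot(self):
        assert self.run_one(3, 0.00108, 5.76).is_hotspot

    def test_two_snvs_never_hotspot(self):
        assert not self.run_one(2, 1e-9, 9.0).is_hotspot

    def test_many_snvs_moderate_z_is_hotspot(self):
        assert self.run_one(14, 1e-12, 3.08).is_hotspot

    def test_z_gate_is_strict(self):
        assert not self.run_one(5, 1e-9, 1.0).is_hotspot
        assert self.run_one(5, 1e-9, 1.001).is_hotspot

    def test_cluster_q_gate(self):
        assert not self.run_one(5, 0.0051, 4.0).is_hotspot

    def test_either_motif_class_can_pass(self):
        assert self.run_one(4, 1e-9, -0.5, z_wa=2.0).is_hotspot

    def test_ts_tv_and_downstream_tally(self):
        from shmscan.hotspots import GenePoissonTest
        t = GenePoissonTest("G", 3, 0.02, 1e-6, qvalue=1e-5)
        calls = self.calls([("G", "A"), ("C", "T"), ("C", "A")])
        (res,) = classify_hotspots(
            [t], {"G": calls},
            {"G": {"RGYW": self.enr(2.0), "WA": self.enr(-1.0, "WA")}})
        assert (res.ts, res.tv) == (2, 1)
        assert res.ts + res.tv == res.k_gene
        assert res.downstream_count == 2


class TestReport:
    def test_empty_results_write_headers_only(self, tmp_path):
        genes, snvs = write_hotspot_report([], tmp_path / "r")
        assert genes.read_text().startswith("gene\t")
        assert len(genes.read_text().splitlines()) == 1
        assert len(snvs.read_text().splitlines()) == 1

    def test_row_schema(self, tmp_path):
        from shmscan.hotspots import HotspotResult
        calls = TestClassify.calls([("G", "A"), ("C", "T"), ("A", "C")],
                                   positions=[10, 20, 30])
        calls[0].shm_context_rgyw = True
        res = HotspotResult(
            gene_name="G", k_gene=3, downstream_count=2, qvalue=0.001,
            rgyw=MotifEnrichment("RGYW", 2, 0.3, 0.5, 3.4),
            wa=MotifEnrichment("WA", 1, 0.9, 0.8, 0.13),
            ts=2, tv=1, is_hotspot=True, calls=calls)
        genes, snvs = write_hotspot_report([res], tmp_path / "r")
        row = genes.read_text().splitlines()[1].split("\t")
        assert row[0] == "G" and row[1] == "3(2)"
        assert row[-3:] == ["2", "1", "1"]
        snv_rows = snvs.read_text().splitlines()[1:]
        assert len(snv_rows) == 3
        first = snv_rows[0].split("\t")
        assert first[2] == "11"  # 1-based display position
        assert first[9] == "1"   # RGYW context flag
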