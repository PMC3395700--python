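"""Poisson-Binomial SNV scoring and FDR control.

At a pileup site covered by *n* reads, the mismatch count under the null
of pure sequencing error is a sum of independent, non-identical Bernoulli
trials: read *j*, whose base falls at sequencing cycle ``c_j``, mismatches
with probability ``p[c_j]`` from the experiment-wide error profile.  The
site p-value is the exact Poisson-Binomial upper tail P(S >= k).  Sites
are scored only at depth n >= 4 (configurable) and k >= 1, and the
resulting p-values are adjusted genome-wide with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .error_model import ErrorProfile, PileupSite

__all__ = ["SnvCall", "poisson_binomial_tail", "score_sites", "bh_adjust"]


def poisson_binomial_pmf(p_vec: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) variables.

    Dynamic-programming convolution in probability space (algebraically
    equivalent to the classic recursion over the odds weights
    w_i = p_i/(1-p_i), but free of the alternating-sign cancellation that
    recursion suffers at large n).
    """
    p_vec = np.asarray(p_vec, dtype=np.float64)
    if np.any((p_vec < 0) | (p_vec >= 1)):
        raise ValueError("per-trial probabilities must lie in [0, 1); "
                         "p_i = 1 makes the odds weight undefined")
    pmf = np.ones(1)
    for p in p_vec:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def poisson_binomial_tail(k: int, p_vec) -> float:
    """Exact upper tail P(S >= k) of the Poisson-Binomial distribution."""
    p_vec = np.asarray(p_vec, dtype=np.float64)
    n = len(p_vec)
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..n={n}")
    if k == 0:
        return 1.0
    pmf = poisson_binomial_pmf(p_vec)
    # sum smallest-first for an accurate tiny tail
    return float(np.sum(pmf[:k - 1:-1][::-1]))


def _tail_fast(k: int, p_vec: np.ndarray) -> float:
    """P(S >= k) via closed-form elementary symmetric polynomials for
    small k, falling back to the exact DP for larger k.

    P(S = j) = prod(1-p_i) * e_j(w);  e_j from Newton's identities on the
    power sums of w.  Exact algebra either way; the small-k branch is the
    per-site fast path (k <= 3 covers almost every error-driven site).
    """
    if k == 0:
        return 1.0
    if k > 3:
        return poisson_binomial_tail(k, p_vec)
    with np.errstate(divide="ignore"):
        log_q0 = np.sum(np.log1p(-p_vec))
    q0 = np.exp(log_q0)
    w = p_vec / (1.0 - p_vec)
    s1 = w.sum()
    cdf_terms = 1.0
    if k >= 2:
        cdf_terms += s1
    if k >= 3:
        s2 = np.dot(w, w)
        cdf_terms += (s1 * s1 - s2) / 2.0
    tail = 1.0 - q0 * cdf_terms
    # guard against cancellation: the DP is the arbiter near zero
    if tail < 1e-12:
        return poisson_binomial_tail(k, p_vec)
    return float(tail)


@dataclass
class SnvCall:
    """A candidate single-nucleotide variant with its evidence."""

    chrom: str
    pos: int               # 0-based
    ref_base: str
    alt_base: str
    n: int
    k: int                 # all non-reference reads
    pvalue: float
    qvalue: float = float("nan")
    ref_qualities: np.ndarray = field(default_factory=lambda: np.array([]))
    alt_qualities: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_ref_quality: float = float("nan")   # raw ASCII scale
    mean_alt_quality: float = float("nan")
    quality_ttest_p: float = float("nan")
    novel: bool = False
    high_confidence: bool = False
    promoter: bool = False
    shm_context_rgyw: bool = False
    shm_context_wa: bool = False
    genes: list[str] = field(default_factory=list)
    downstream_of_tss: bool = False

    @property
    def ratio(self) -> float:
        return self.k / self.n

    @property
    def is_transition(self) -> bool:
        return {self.ref_base, self.alt_base} in ({"A", "G"}, {"C", "T"})


def score_sites(sites, profile: ErrorProfile, min_depth: int = 4):
    """Score pileup sites against the error profile.

    For each site with ``n >= min_depth`` and ``k >= 1`` the null is
    assembled from the profile rates at the sequencing cycle of *every*
    overlapping read (matches and mismatches alike), so the null reflects
    where the site falls inside each read.  Sites below the depth floor or
    without variant evidence are not emitted.
    """
    p = profile.p
    n_cycles = len(p)
    calls: list[SnvCall] = []
    for site in sites:
        if site.n < min_depth or site.k == 0:
            continue
        cycles = site.all_cycles
        if cycles.max(initial=-1) >= n_cycles:
            raise ValueError(
                f"site {site.chrom}:{site.pos} has read position "
                f"{int(cycles.max())} beyond the {n_cycles}-cycle profile")
        p_vec = p[cycles]
        calls.append(SnvCall(
            chrom=site.chrom, pos=site.pos, ref_base=site.ref_base,
            alt_base=site.alt_base, n=site.n, k=site.k,
            pvalue=_tail_fast(site.k, p_vec),
            ref_qualities=np.asarray(site.ref_qualities, dtype=np.float64),
            alt_qualities=np.asarray(site.alt_qualities, dtype=np.float64)))
    return calls


def call_snvs(batch, genome, regions, profile: ErrorProfile,
              min_depth: int = 4) -> list[SnvCall]:
    """Fused pileup + scoring over a read batch (vectorised fast path).

    Produces exactly the calls of ``score_sites(pileup(batch, genome,
    regions, min_alt=1), profile, min_depth)`` — same sites, same
    p-values — but computes the per-site Poisson-Binomial tails with
    segment reductions over the flat base arrays instead of per-site
    Python, which matters on multi-million-read experiments.
    """
    from .error_model import (_reference_codes, mismatch_flags,
                              region_entry_mask)

    if len(batch) == 0:
        return []
    keep = region_entry_mask(batch, regions)
    sel = np.flatnonzero(keep)
    del keep
    if len(sel) == 0:
        return []
    ref_flat = _reference_codes(batch, genome)
    mism_flat = mismatch_flags(batch, genome)
    cyc_flat = batch.cycle()
    if int(cyc_flat.max(initial=-1)) >= len(profile):
        raise ValueError("read position beyond the error-profile length")

    # order region entries by (chrom, position); radix sort on integers
    single_chrom = len(np.unique(batch.chrom_id)) == 1
    if single_chrom:
        order = sel[np.argsort(batch.refpos[sel], kind="stable")]
    else:
        key = ((batch.entry_chrom[sel].astype(np.int64) << 32)
               | batch.refpos[sel])
        order = sel[np.argsort(key, kind="stable")]
        del key
    del sel
    refpos = batch.refpos[order]
    chrom = batch.entry_chrom[order]
    mism = mism_flat[order]

    bnd = np.flatnonzero(np.concatenate(
        [[True], (refpos[1:] != refpos[:-1]) | (chrom[1:] != chrom[:-1])]))
    n = np.diff(np.concatenate([bnd, [len(refpos)]]))
    k = np.add.reduceat(mism.astype(np.int32), bnd)
    refb = ref_flat[order[bnd]]
    valid = (n >= min_depth) & (k >= 1) & (refb < 4)
    if not valid.any():
        return []
    nv = n[valid]
    kv = k[valid]
    n_valid = int(valid.sum())
    entry_valid = np.repeat(valid, n)
    ord_valid = order[entry_valid]      # flat indices of candidate entries
    del order, entry_valid, mism

    # per-entry data restricted to candidate sites
    vbase = batch.base[ord_valid]
    vqual = batch.qual[ord_valid]
    vcyc = cyc_flat[ord_valid]
    vmism = mism_flat[ord_valid]
    del ord_valid
    vbnd = np.concatenate([[0], np.cumsum(nv)])[:-1]
    comp = np.repeat(np.arange(n_valid, dtype=np.int32), nv)

    # modal alternate base per site (ties resolved in A<C<G<T order)
    cnt = np.bincount(comp[vmism].astype(np.int64) * 4 + vbase[vmism],
                      minlength=n_valid * 4).reshape(n_valid, 4)
    alt_code = np.argmax(cnt, axis=1)

    # closed-form tails from segment power sums of the odds weights
    p_e = profile.p[vcyc]
    w_e = p_e / (1.0 - p_e)
    log_q0 = np.add.reduceat(np.log1p(-p_e), vbnd)
    s1 = np.add.reduceat(w_e, vbnd)
    s2 = np.add.reduceat(w_e * w_e, vbnd)
    cdf_terms = np.ones(n_valid)
    cdf_terms += np.where(kv >= 2, s1, 0.0)
    cdf_terms += np.where(kv >= 3, (s1 * s1 - s2) / 2.0, 0.0)
    tails = 1.0 - np.exp(log_q0) * cdf_terms
    exact = (kv > 3) | (tails < 1e-12)
    for i in np.flatnonzero(exact):
        lo = vbnd[i]
        tails[i] = poisson_binomial_tail(int(kv[i]), p_e[lo:lo + nv[i]])

    site_first = bnd[valid]
    site_chrom = chrom[site_first]
    site_pos = refpos[site_first]
    site_ref = refb[valid]
    calls = []
    for i in range(n_valid):
        lo, hi = vbnd[i], vbnd[i] + nv[i]
        seg_base = vbase[lo:hi]
        seg_qual = vqual[lo:hi]
        rb = site_ref[i]
        calls.append(SnvCall(
            chrom=batch.chrom_names[site_chrom[i]],
            pos=int(site_pos[i]),
            ref_base="ACGTN"[rb], alt_base="ACGTN"[alt_code[i]],
            n=int(nv[i]), k=int(kv[i]), pvalue=float(tails[i]),
            ref_qualities=seg_qual[seg_base == rb].astype(np.float64),
            alt_qualities=seg_qual[seg_base == alt_code[i]].astype(
                np.float64)))
    return calls


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=np.float64)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]
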