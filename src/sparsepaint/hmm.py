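"""Sparse Li & Stephens forward-backward over a set of stored matches.

The copying model treats a target haplotype as a mosaic of donor
haplotypes.  With the mutation probability taken to zero, only donors that
match the target at a SNP can carry forward probability there, so the whole
forward-backward recursion runs over the stored matches alone (roughly Q
per SNP) instead of the full panel.  Working quantities are kept normalised
per SNP with running log-normalisers, exactly reproducing the dense model's
posteriors, expected copied lengths and expected chunk counts.

Notation: ``rho[j] = exp(-lam * g[j])`` is the probability of no ancestry
switch across the gap ``g[j]`` (Morgans) between SNPs j and j+1;
``rho_tilde[j] = (1 - rho[j]) / N`` is the per-donor switch mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .panel import GeneticMap
from .pbwt import MatchSet

__all__ = [
    "HMMParams",
    "SparseForwardBackward",
    "matchset_csr",
    "forward_sparse",
    "backward_sparse",
    "posterior",
    "expected_chunk_lengths",
    "expected_chunk_counts",
    "estimate_lambda",
]

LAMBDA_FLOOR = 1e-6


@dataclass
class HMMParams:
    """Recombination scaling constant and derived per-gap switch terms."""

    lam: float
    rho: np.ndarray        # (K-1,) exp(-lam * g_j)
    rho_tilde: np.ndarray  # (K-1,) (1 - rho_j) / N
    n_donor: int

    @classmethod
    def from_map(cls, gmap: GeneticMap, lam: float, n_donor: int) -> "HMMParams":
        if lam <= 0:
            raise ValueError("lambda must be positive")
        rho = np.exp(-lam * gmap.gap_morgans)
        return cls(lam=float(lam), rho=rho, rho_tilde=(1.0 - rho) / n_donor,
                   n_donor=n_donor)


@dataclass
class SparseForwardBackward:
    """Per-SNP sparse forward/backward state in CSR layout.

    ``donors[indptr[j]:indptr[j+1]]`` are the donor haplotypes matched at
    SNP j (sorted).  ``fvals`` are normalised forward values on that
    support; ``bvals`` normalised backward values (donors matched at j+1
    take their own value, all others the scalar ``bdefault[j]``); ``logF``
    and ``logB`` are the per-SNP log-normalisers.
    """

    indptr: np.ndarray
    donors: np.ndarray
    n_donor: int
    params: HMMParams
    fvals: np.ndarray | None = None
    logF: np.ndarray | None = None
    bvals: np.ndarray | None = None
    bdefault: np.ndarray | None = None
    logB: np.ndarray | None = None

    @property
    def n_snp(self) -> int:
        return len(self.indptr) - 1


# ---------------------------------------------------------------------------
# kernels

@njit(cache=True)
def _find(donors, lo, hi, key):
    """Binary search for key in donors[lo:hi]; -1 if absent."""
    while lo < hi:
        mid = (lo + hi) // 2
        v = donors[mid]
        if v == key:
            return mid
        if v < key:
            lo = mid + 1
        else:
            hi = mid
    return -1


@njit(cache=True)
def _forward_kernel(indptr, donors, rho, rho_t, n_donor):
    K = len(indptr) - 1
    fvals = np.zeros(len(donors))
    logF = np.zeros(K)
    # first SNP: prior 1/N on the matched donors
    lo, hi = indptr[0], indptr[1]
    F = (hi - lo) / n_donor
    for p in range(lo, hi):
        fvals[p] = 1.0 / (hi - lo)
    logF[0] = np.log(F)
    for j in range(1, K):
        lo, hi = indptr[j], indptr[j + 1]
        plo, phi = indptr[j - 1], indptr[j]
        F = 0.0
        for p in range(lo, hi):
            q = _find(donors, plo, phi, donors[p])
            fprev = fvals[q] if q >= 0 else 0.0
            v = rho[j - 1] * fprev + rho_t[j - 1]
            fvals[p] = v
            F += v
        for p in range(lo, hi):
            fvals[p] /= F
        logF[j] = np.log(F)
    return fvals, logF


@njit(cache=True)
def _backward_kernel(indptr, donors, rho, rho_t, n_donor):
    K = len(indptr) - 1
    bvals = np.zeros(len(donors))
    bdef = np.zeros(K)
    logB = np.zeros(K)
    # last SNP: b = 1-vector, normalised to 1/N with normaliser N
    lo, hi = indptr[K - 1], indptr[K]
    for p in range(lo, hi):
        bvals[p] = 1.0 / n_donor
    bdef[K - 1] = 1.0 / n_donor
    logB[K - 1] = np.log(n_donor)
    for j in range(K - 2, -1, -1):
        nlo, nhi = indptr[j + 1], indptr[j + 2]
        n_next = nhi - nlo
        ctilde = 0.0
        for p in range(nlo, nhi):
            ctilde += bvals[p]
        defstar = rho_t[j] * ctilde
        B = (n_donor - n_next) * defstar
        for p in range(nlo, nhi):
            B += rho[j] * bvals[p] + defstar
        lo, hi = indptr[j], indptr[j + 1]
        for p in range(lo, hi):
            q = _find(donors, nlo, nhi, donors[p])
            if q >= 0:
                bvals[p] = (rho[j] * bvals[q] + defstar) / B
            else:
                bvals[p] = defstar / B
        bdef[j] = defstar / B
        logB[j] = np.log(B)
    return bvals, bdef, logB


@njit(cache=True)
def _posterior_kernel(indptr, fvals, bvals):
    K = len(indptr) - 1
    post = np.zeros(len(fvals))
    for j in range(K):
        lo, hi = indptr[j], indptr[j + 1]
        tot = 0.0
        for p in range(lo, hi):
            v = fvals[p] * bvals[p]
            post[p] = v
            tot += v
        for p in range(lo, hi):
            post[p] /= tot
    return post


@njit(cache=True)
def _chunk_length_kernel(indptr, donors, post, gaps, n_panel):
    K = len(indptr) - 1
    l_hat = np.zeros(n_panel)
    for j in range(K - 1):
        g = gaps[j]
        for p in range(indptr[j], indptr[j + 1]):
            l_hat[donors[p]] += 0.5 * g * post[p]
        for p in range(indptr[j + 1], indptr[j + 2]):
            l_hat[donors[p]] += 0.5 * g * post[p]
    return l_hat


@njit(cache=True)
def _chunk_count_kernel(indptr, donors, fvals, bvals, post, logF, logB, rho,
                        n_panel):
    K = len(indptr) - 1
    c_hat = np.zeros(n_panel)
    # first term: posterior at SNP 0
    for p in range(indptr[0], indptr[1]):
        c_hat[donors[p]] += post[p]
    if K == 1:
        return c_hat
    LT = logF.sum()
    LFcum = np.cumsum(logF)
    LBcum = np.zeros(K)
    LBcum[K - 1] = logB[K - 1]
    for j in range(K - 2, -1, -1):
        LBcum[j] = LBcum[j + 1] + logB[j]
    for j in range(K - 1):
        # chunk-start mass at j+1 minus continuing (no-switch) mass
        for p in range(indptr[j + 1], indptr[j + 2]):
            c_hat[donors[p]] += post[p]
        scale = np.exp(LFcum[j] + LBcum[j + 1] - LT)
        nlo, nhi = indptr[j + 1], indptr[j + 2]
        for p in range(indptr[j], indptr[j + 1]):
            q = _find(donors, nlo, nhi, donors[p])
            if q >= 0:  # matched at j+1: V = 1 in the mu -> 0 limit
                c_hat[donors[p]] -= rho[j] * fvals[p] * bvals[q] * scale
    return c_hat


# ---------------------------------------------------------------------------
# public operations


def matchset_csr(matchset: MatchSet, t: int, allowed=None):
    """Per-SNP sorted donor lists for target ``t`` in CSR form.

    ``allowed`` is an optional boolean mask over reference haplotypes; a
    donor outside it is dropped (leave-one-out pools).
    """
    m = matchset.get(t)
    ref, s, e = m["ref"], m["s"], m["e"]
    if allowed is not None:
        keep = allowed[ref]
        ref, s, e = ref[keep], s[keep], e[keep]
    K = matchset.n_snp
    counts = np.zeros(K + 1, dtype=np.int64)
    np.add.at(counts, s, 1)
    np.add.at(counts, e + 1, -1)
    cov = np.cumsum(counts[:-1])
    if np.any(cov == 0):
        raise ValueError("zero-coverage SNP: run impute_empty_positions first")
    indptr = np.zeros(K + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(cov)
    donors = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for i in range(len(ref)):
        for j in range(s[i], e[i] + 1):
            donors[fill[j]] = ref[i]
            fill[j] += 1
    for j in range(K):
        seg = donors[indptr[j]:indptr[j + 1]]
        seg.sort()
    return indptr, donors


def forward_sparse(matchset: MatchSet, gmap: GeneticMap, params: HMMParams,
                   t: int = 0, allowed=None) -> SparseForwardBackward:
    """Normalised sparse forward pass for target haplotype ``t``."""
    indptr, donors = matchset_csr(matchset, t, allowed)
    fb = SparseForwardBackward(indptr=indptr, donors=donors,
                               n_donor=params.n_donor, params=params)
    fb.fvals, fb.logF = _forward_kernel(indptr, donors, params.rho,
                                        params.rho_tilde, params.n_donor)
    return fb


def backward_sparse(matchset: MatchSet, gmap: GeneticMap, params: HMMParams,
                    t: int = 0, allowed=None,
                    fb: SparseForwardBackward | None = None) -> SparseForwardBackward:
    """Normalised sparse backward pass (reuses the forward's support)."""
    if fb is None:
        indptr, donors = matchset_csr(matchset, t, allowed)
        fb = SparseForwardBackward(indptr=indptr, donors=donors,
                                   n_donor=params.n_donor, params=params)
    fb.bvals, fb.bdefault, fb.logB = _backward_kernel(
        fb.indptr, fb.donors, params.rho, params.rho_tilde, params.n_donor)
    return fb


def run_forward_backward(matchset: MatchSet, gmap: GeneticMap, params: HMMParams,
                         t: int = 0, allowed=None) -> SparseForwardBackward:
    fb = forward_sparse(matchset, gmap, params, t, allowed)
    return backward_sparse(matchset, gmap, params, t, allowed, fb=fb)


def posterior(fb: SparseForwardBackward) -> np.ndarray:
    """Per-SNP posterior copying probabilities on the sparse support.

    Returns values aligned with ``fb.donors``; each SNP's values sum to 1.
    Haplotypes off the support have exactly zero posterior.
    """
    if fb.fvals is None or fb.bvals is None:
        raise ValueError("run forward and backward first")
    return _posterior_kernel(fb.indptr, fb.fvals, fb.bvals)


def expected_chunk_lengths(fb: SparseForwardBackward, gmap: GeneticMap,
                           n_panel: int, post=None) -> np.ndarray:
    """Expected copied length per donor haplotype, in Morgans.

    Trapezoid of the posterior over the genetic map; the per-donor values
    sum to the map length G.
    """
    if post is None:
        post = posterior(fb)
    return _chunk_length_kernel(fb.indptr, fb.donors, post,
                                gmap.gap_morgans, n_panel)


def expected_chunk_counts(fb: SparseForwardBackward, n_panel: int,
                          post=None) -> np.ndarray:
    """Expected number of copied chunks per donor haplotype.

    A chunk starts at SNP 0 or wherever the copied donor at j+1 is reached
    by an ancestry switch; continuing without recombination is subtracted
    via the cross term f_j * b_{j+1} * rho_j on donors matched at both SNPs.
    """
    if post is None:
        post = posterior(fb)
    return _chunk_count_kernel(fb.indptr, fb.donors, fb.fvals, fb.bvals, post,
                               fb.logF, fb.logB, fb.params.rho, n_panel)


# ---------------------------------------------------------------------------
# lambda estimation (Viterbi-equivalent minimum segment cover)


def _min_cover(s, e, K):
    """Size of a minimum cover of [0, K-1] by the intervals; -1 if none."""
    order = np.argsort(s)
    s, e = s[order], e[order]
    n = 0
    pos = 0
    i = 0
    count = 0
    while pos < K:
        best = -1
        while i < len(s) and s[i] <= pos:
            if e[i] > best:
                best = e[i]
            i += 1
        if best < pos:
            return -1
        count += 1
        pos = best + 1
    return count


def estimate_lambda(matchset: MatchSet, gmap: GeneticMap,
                    targets=None) -> float:
    """Estimate the recombination scaling constant from stored matches.

    With zero mutation the most probable copying path must stay inside
    matches, so the minimum number of segments covering the chromosome
    equals the Viterbi segment count; lambda* = N_break / G, averaged over
    target haplotypes, floored at a small positive value.
    """
    G = gmap.total_morgans
    if G <= 0:
        raise ValueError("map has zero genetic length")
    if targets is None:
        targets = sorted(matchset.matches.keys())
    lams = []
    for t in targets:
        m = matchset.get(t)
        if len(m["ref"]) == 0:
            raise ValueError(f"target haplotype {t} has no matches")
        n_seg = _min_cover(m["s"].copy(), m["e"].copy(), matchset.n_snp)
        if n_seg < 0:
            raise ValueError(f"target haplotype {t} cannot be covered by matches")
        lams.append((n_seg - 1) / G)
    lam = float(np.mean(lams))
    return max(lam, LAMBDA_FLOOR)
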