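"""All-vs-all painting from set-maximal matches, coancestry and components.

Instead of a copying HMM, every SNP k covered by a set-maximal match to
donor j gets the weight ``w_jk = (k - s_jk)(e_jk - k)`` — zero at the match
ends, quadratic in length at the midpoint — normalised over covering
matches into a local ancestry score ``p_jk``.  Summed over SNPs and
weighted per chromosome by ``g_i / K_i`` (map length over SNP count), the
scores aggregate into an individual-level coancestry matrix A whose rows
sum to the total map length G; haplotype components are the leading columns
of U sqrt(D) from the SVD of log10(A + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .panel import GeneticMap, HaplotypePanel
from .pbwt import MatchSet, build_pbwt, impute_empty_positions, set_maximal_matches

__all__ = [
    "pbwtpaint_scores",
    "aggregate_coancestry",
    "haplotype_components",
    "HCResult",
]


@njit(cache=True)
def _score_kernel(indptr, donors, sstart, send, n_hap):
    """Genome-wide score per donor haplotype from quadratic match weights.

    Also returns the per-slot normalised local scores p_jk.  SNPs where all
    covering weights vanish (k at every match endpoint) fall back to a
    uniform split over the covering donors.
    """
    K = len(indptr) - 1
    pvals = np.zeros(len(donors))
    p_j = np.zeros(n_hap)
    for k in range(K):
        lo, hi = indptr[k], indptr[k + 1]
        tot = 0.0
        for p in range(lo, hi):
            w = float(k - sstart[p]) * float(send[p] - k)
            pvals[p] = w
            tot += w
        if tot <= 0.0:
            u = 1.0 / (hi - lo)
            for p in range(lo, hi):
                pvals[p] = u
                p_j[donors[p]] += u
        else:
            for p in range(lo, hi):
                pvals[p] /= tot
                p_j[donors[p]] += pvals[p]
    return pvals, p_j


def _csr_with_intervals(matchset: MatchSet, t: int):
    """CSR donor lists for target t keeping each covering match's [s, e]."""
    m = matchset.get(t)
    ref, s, e = m["ref"], m["s"], m["e"]
    K = matchset.n_snp
    counts = np.zeros(K + 1, dtype=np.int64)
    np.add.at(counts, s, 1)
    np.add.at(counts, e + 1, -1)
    cov = np.cumsum(counts[:-1])
    if np.any(cov == 0):
        raise ValueError("zero-coverage SNP: impute first")
    indptr = np.zeros(K + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(cov)
    donors = np.empty(indptr[-1], dtype=np.int64)
    ss = np.empty(indptr[-1], dtype=np.int64)
    ee = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for i in range(len(ref)):
        for j in range(s[i], e[i] + 1):
            donors[fill[j]] = ref[i]
            ss[fill[j]] = s[i]
            ee[fill[j]] = e[i]
            fill[j] += 1
    return indptr, donors, ss, ee


def pbwtpaint_scores(panel: HaplotypePanel, gmap: GeneticMap,
                     matchset: MatchSet | None = None) -> np.ndarray:
    """Genome-wide copied-length scores between all haplotypes.

    Returns a dense (n_hap, n_hap) matrix: row = recipient haplotype,
    column = donor haplotype, entries in Morgans; each row sums to the
    chromosome's map length.  Self and sibling-haplotype donations are
    excluded (matches to the own individual are dropped).
    """
    if matchset is None:
        index = build_pbwt(panel)
        matchset = set_maximal_matches(index)
    matchset = impute_empty_positions(matchset, gmap)
    K = panel.n_snp
    weight = gmap.total_morgans / K  # g_i / K_i per-SNP chunk length
    n_hap = panel.n_hap
    scores = np.zeros((n_hap, n_hap))
    for t in range(n_hap):
        indptr, donors, ss, ee = _csr_with_intervals(matchset, t)
        _, p_j = _score_kernel(indptr, donors, ss, ee, n_hap)
        scores[t] = p_j * weight
    return scores


def aggregate_coancestry(per_chrom_scores, per_chrom_maps=None) -> np.ndarray:
    """Individual-level coancestry matrix A summed over chromosomes.

    Haplotype scores are averaged into individuals (the two recipient rows
    averaged, donor columns summed per individual), preserving the
    row-sum = G invariant.  All chromosomes must cover the same individual
    set.
    """
    A = None
    for scores in per_chrom_scores:
        n_hap = scores.shape[0]
        if n_hap % 2:
            raise ValueError("haplotype count must be even")
        n_ind = n_hap // 2
        by_donor = scores.reshape(n_hap, n_ind, 2).sum(axis=2)
        by_ind = 0.5 * (by_donor[0::2] + by_donor[1::2])
        if A is None:
            A = by_ind
        elif A.shape != by_ind.shape:
            raise ValueError("chromosomes cover different individual sets")
        else:
            A = A + by_ind
    np.fill_diagonal(A, 0.0)
    return A


@dataclass
class HCResult:
    """Haplotype components: leading columns of U sqrt(D)."""

    components: np.ndarray       # (n_ind, n_comp)
    singular_values: np.ndarray  # descending


def haplotype_components(A: np.ndarray, n_comp: int = 150) -> HCResult:
    """Truncated SVD of log10(A + 1); components are U sqrt(D).

    Column signs are fixed so each column's largest-magnitude entry is
    positive.  If ``n_comp`` exceeds the feasible rank, the available
    columns are returned with a warning.
    """
    if np.any(A < 0):
        raise ValueError("coancestry matrix must be non-negative")
    L = np.log10(A + 1.0)
    n = min(L.shape)
    if n_comp >= n - 1:
        if n_comp > n:
            import warnings

            warnings.warn(f"n_comp reduced to rank bound {n}")
        U, sv, _ = np.linalg.svd(L, full_matrices=False)
        U, sv = U[:, :min(n_comp, n)], sv[:min(n_comp, n)]
    else:
        from scipy.sparse.linalg import svds

        U, sv, _ = svds(L, k=n_comp)
        order = np.argsort(sv)[::-1]
        U, sv = U[:, order], sv[order]
    comps = U * np.sqrt(sv)
    flip = np.sign(comps[np.argmax(np.abs(comps), axis=0),
                         np.arange(comps.shape[1])])
    flip[flip == 0] = 1.0
    return HCResult(components=comps * flip, singular_values=sv)
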