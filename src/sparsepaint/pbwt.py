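"""Positional Burrows-Wheeler transform and the match queries painters need.

The PBWT keeps, at every SNP column, the haplotypes sorted by reversed
prefix together with divergence values (the start of the match between
sorted neighbours).  From one linear sweep we extract:

* all maximal matches of length >= L between two haplotype sets
  (:func:`long_matches`),
* set-maximal matches — matches no other haplotype exceeds at that locus —
  for all-vs-all painting (:func:`set_maximal_matches`),
* the two-stage "at least Q longest matches per SNP" selection that drives
  the sparse copying HMM (:func:`report_q_longest_matches`).

Match intervals ``[s, e]`` are inclusive at both ends, SNP indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .panel import GeneticMap, HaplotypePanel

__all__ = [
    "PBWTIndex",
    "MatchSet",
    "build_pbwt",
    "long_matches",
    "set_maximal_matches",
    "report_q_longest_matches",
    "impute_empty_positions",
]


# ---------------------------------------------------------------------------
# kernels

@njit(cache=True)
def _build_arrays(alleles):
    """Prefix (a) and divergence (d) arrays for all K+1 columns.

    a[k] sorts haplotypes by reversed prefix over sites [0, k); d[k][i] is
    the start of the match between a[k][i] and a[k][i-1] (d = k means no
    match).
    """
    M, K = alleles.shape
    a = np.empty((K + 1, M), dtype=np.int32)
    d = np.empty((K + 1, M), dtype=np.int32)
    for i in range(M):
        a[0, i] = i
        d[0, i] = 0
    tmp_a = np.empty(M, dtype=np.int32)
    tmp_d = np.empty(M, dtype=np.int32)
    for k in range(K):
        u = 0
        v = 0
        p = k + 1
        q = k + 1
        for i in range(M):
            h = a[k, i]
            dd = d[k, i]
            if dd > p:
                p = dd
            if dd > q:
                q = dd
            if alleles[h, k] == 0:
                a[k + 1, u] = h
                d[k + 1, u] = p
                p = 0
                u += 1
            else:
                tmp_a[v] = h
                tmp_d[v] = q
                q = 0
                v += 1
        for i in range(v):
            a[k + 1, u + i] = tmp_a[i]
            d[k + 1, u + i] = tmp_d[i]
    return a, d


@njit(cache=True)
def _long_matches_kernel(alleles, a, d, L, group, cross_only):
    """All maximal matches of length >= L; pairs emitted once.

    When ``cross_only`` is true only pairs from different groups are kept
    (merged-panel between-set query).  Output rows: (hap1, hap2, s, e).
    """
    M, K = alleles.shape
    cap = 1024
    out = np.empty((cap, 4), dtype=np.int64)
    n = 0
    for k in range(L, K + 1):
        thresh = k - L
        i0 = 0
        for i in range(1, M + 1):
            if i == M or d[k, i] > thresh:
                if i - i0 >= 2:
                    # block [i0, i): every pair matches over >= L sites
                    for jj in range(i0 + 1, i):
                        hj = a[k, jj]
                        dmax = d[k, jj]
                        for ii in range(jj - 1, i0 - 1, -1):
                            hi = a[k, ii]
                            if ii < jj - 1 and d[k, ii + 1] > dmax:
                                dmax = d[k, ii + 1]
                            terminate = (k == K) or (alleles[hi, k] != alleles[hj, k])
                            if terminate and k - dmax >= L:
                                if (not cross_only) or (group[hi] != group[hj]):
                                    if n == cap:
                                        cap *= 2
                                        new = np.empty((cap, 4), dtype=np.int64)
                                        new[:n] = out[:n]
                                        out = new
                                    out[n, 0] = hi
                                    out[n, 1] = hj
                                    out[n, 2] = dmax
                                    out[n, 3] = k - 1
                                    n += 1
                i0 = i
    return out[:n]


@njit(cache=True)
def _set_maximal_kernel(alleles, a, d):
    """Within-panel set-maximal matches, self excluded.

    For every column the algorithm walks the groups of sorted neighbours
    holding the longest match with each haplotype; if any member of the
    group carries the same allele at the column the match extends and
    nothing is reported for that haplotype there.  Output rows:
    (target, ref, s, e).
    """
    M, K = alleles.shape
    cap = 1024
    out = np.empty((cap, 4), dtype=np.int64)
    n = 0
    for k in range(1, K + 1):
        for i in range(M):
            di = d[k, i] if i > 0 else k          # sentinel: no neighbour above
            di1 = d[k, i + 1] if i + 1 < M else k  # sentinel: no neighbour below
            if di >= k and di1 >= k:
                continue  # no match at all ending here
            t = a[k, i]
            skip = False
            m = i - 1
            if di <= di1:
                # group above holds a longest match (start di)
                while m >= 0 and d[k, m + 1] <= di:
                    if k < K and alleles[a[k, m], k] == alleles[t, k]:
                        skip = True
                        break
                    m -= 1
            if skip:
                continue
            nn = i + 1
            if di1 <= di:
                while nn < M and d[k, nn] <= di1:
                    if k < K and alleles[a[k, nn], k] == alleles[t, k]:
                        skip = True
                        break
                    nn += 1
            if skip:
                continue
            if di <= di1 and di < k:
                for j in range(m + 1, i):
                    if n == cap:
                        cap *= 2
                        new = np.empty((cap, 4), dtype=np.int64)
                        new[:n] = out[:n]
                        out = new
                    out[n, 0] = t
                    out[n, 1] = a[k, j]
                    out[n, 2] = di
                    out[n, 3] = k - 1
                    n += 1
            if di1 <= di and di1 < k:
                for j in range(i + 1, nn):
                    if n == cap:
                        cap *= 2
                        new = np.empty((cap, 4), dtype=np.int64)
                        new[:n] = out[:n]
                        out = new
                    out[n, 0] = t
                    out[n, 1] = a[k, j]
                    out[n, 2] = di1
                    out[n, 3] = k - 1
                    n += 1
    return out[:n]


@njit(cache=True)
def _greedy_stage2(s_arr, e_arr, order, Q, K):
    """Greedily keep matches (in the given order) while some covered SNP
    still has fewer than Q kept matches."""
    counts = np.zeros(K, dtype=np.int64)
    keep = np.zeros(len(order), dtype=np.bool_)
    n_short = K  # SNPs with < Q kept matches
    for oi in range(len(order)):
        if n_short == 0:
            break
        m = order[oi]
        s = s_arr[m]
        e = e_arr[m]
        needed = False
        for kk in range(s, e + 1):
            if counts[kk] < Q:
                needed = True
                break
        if needed:
            keep[m] = True
            for kk in range(s, e + 1):
                counts[kk] += 1
                if counts[kk] == Q:
                    n_short -= 1
    return keep


# ---------------------------------------------------------------------------
# containers


@dataclass
class PBWTIndex:
    """Per-column positional prefix and divergence arrays over a panel."""

    panel: HaplotypePanel
    prefix: np.ndarray      # (K+1, M) int32
    divergence: np.ndarray  # (K+1, M) int32


@dataclass
class MatchSet:
    """Sparse maximal-match intervals per target haplotype.

    ``matches[t]`` is a dict of equal-length arrays ``ref``, ``s``, ``e``,
    ``imputed`` for target haplotype ``t``.
    """

    n_snp: int
    n_ref: int
    n_target: int
    matches: dict = field(default_factory=dict)
    Q: int | None = None
    L_min: int | None = None
    L_0: int | None = None

    @staticmethod
    def _empty():
        return {
            "ref": np.empty(0, dtype=np.int64),
            "s": np.empty(0, dtype=np.int64),
            "e": np.empty(0, dtype=np.int64),
            "imputed": np.empty(0, dtype=bool),
        }

    def get(self, t):
        return self.matches.get(t, self._empty())

    def add(self, t, ref, s, e, imputed=None):
        ref = np.asarray(ref, dtype=np.int64)
        s = np.asarray(s, dtype=np.int64)
        e = np.asarray(e, dtype=np.int64)
        if imputed is None:
            imputed = np.zeros(len(ref), dtype=bool)
        cur = self.matches.get(t)
        if cur is None:
            self.matches[t] = {"ref": ref, "s": s, "e": e, "imputed": imputed}
        else:
            for key, arr in (("ref", ref), ("s", s), ("e", e), ("imputed", imputed)):
                cur[key] = np.concatenate([cur[key], arr])

    def coverage(self, t) -> np.ndarray:
        """Number of stored matches covering each SNP for target ``t``."""
        m = self.get(t)
        diff = np.zeros(self.n_snp + 1, dtype=np.int64)
        np.add.at(diff, m["s"], 1)
        np.add.at(diff, m["e"] + 1, -1)
        return np.cumsum(diff[:-1])

    def total_matches(self) -> int:
        return sum(len(m["ref"]) for m in self.matches.values())


# ---------------------------------------------------------------------------
# public operations


def build_pbwt(panel: HaplotypePanel) -> PBWTIndex:
    """Build positional prefix and divergence arrays for a panel."""
    if panel.n_hap == 0 or panel.n_snp == 0:
        raise ValueError("cannot build a PBWT over an empty panel")
    a, d = _build_arrays(panel.alleles)
    return PBWTIndex(panel=panel, prefix=a, divergence=d)


def _merged_long_matches(ref_panel, target_panel, L):
    """All maximal matches >= L SNPs between target and reference haplotypes.

    Returns (target_hap, ref_hap, s, e) arrays with target/ref indices in
    their own panels.  Implemented as one sweep over the merged panel with
    donor/recipient flags; within-set pairs are discarded.
    """
    n_ref = ref_panel.n_hap
    same = target_panel is ref_panel
    if same:
        merged = ref_panel.alleles
        group = np.zeros(n_ref, dtype=np.int64)
        cross_only = False
    else:
        merged = np.vstack([ref_panel.alleles, target_panel.alleles])
        group = np.concatenate([
            np.zeros(n_ref, dtype=np.int64),
            np.ones(target_panel.n_hap, dtype=np.int64),
        ])
        cross_only = True
    a, d = _build_arrays(merged)
    raw = _long_matches_kernel(merged, a, d, L, group, cross_only)
    if len(raw) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, z, z
    h1, h2, s, e = raw[:, 0], raw[:, 1], raw[:, 2], raw[:, 3]
    if same:
        # emit both orientations, self pairs impossible
        tgt = np.concatenate([h1, h2])
        ref = np.concatenate([h2, h1])
        s = np.concatenate([s, s])
        e = np.concatenate([e, e])
        return tgt, ref, s, e
    # orient: target index is the flagged haplotype
    is1 = group[h1] == 1
    tgt = np.where(is1, h1, h2) - n_ref
    ref = np.where(is1, h2, h1)
    return tgt, ref, s, e


def long_matches(index: PBWTIndex, target_panel: HaplotypePanel | None, L: int) -> MatchSet:
    """Every maximal match of length >= L SNPs between targets and the panel.

    With ``target_panel is None`` (or the panel itself) matches are reported
    within the panel, both orientations, self excluded.
    """
    ref_panel = index.panel
    if L < 1:
        raise ValueError("L must be >= 1")
    if target_panel is None:
        target_panel = ref_panel
    if L > ref_panel.n_snp:
        import warnings

        warnings.warn("L exceeds the number of SNPs; no matches possible")
        return MatchSet(n_snp=ref_panel.n_snp, n_ref=ref_panel.n_hap,
                        n_target=target_panel.n_hap)
    tgt, ref, s, e = _merged_long_matches(ref_panel, target_panel, L)
    ms = MatchSet(n_snp=ref_panel.n_snp, n_ref=ref_panel.n_hap,
                  n_target=target_panel.n_hap, L_min=L)
    for t in np.unique(tgt):
        sel = tgt == t
        ms.add(int(t), ref[sel], s[sel], e[sel])
    return ms


def _filter_set_maximal(ref, s, e):
    """Keep matches not strictly contained in another match's interval."""
    order = np.lexsort((-e, s))
    ref, s, e = ref[order], s[order], e[order]
    keep = np.zeros(len(ref), dtype=bool)
    best_e_before = -1  # max e among strictly earlier starts
    i = 0
    while i < len(ref):
        j = i
        while j < len(ref) and s[j] == s[i]:
            j += 1
        emax = e[i]  # sorted desc within the group
        for t in range(i, j):
            if e[t] == emax and e[t] > best_e_before:
                keep[t] = True
        best_e_before = max(best_e_before, emax)
        i = j
    return ref[keep], s[keep], e[keep]


def set_maximal_matches(index: PBWTIndex, target_panel: HaplotypePanel | None = None,
                        exclude_same_individual: bool = True) -> MatchSet:
    """Set-maximal matches: longest matches at each locus per target.

    All-vs-all (``target_panel`` omitted) uses the PBWT neighbour sweep with
    self-matches excluded; with ``exclude_same_individual`` the sibling
    haplotype of the same individual is also removed.  A separate target
    panel is handled by direct enumeration of maximal matches followed by a
    containment filter (small-panel path).
    """
    ref_panel = index.panel
    if target_panel is None or target_panel is ref_panel:
        raw = _set_maximal_kernel(ref_panel.alleles, index.prefix, index.divergence)
        ms = MatchSet(n_snp=ref_panel.n_snp, n_ref=ref_panel.n_hap,
                      n_target=ref_panel.n_hap)
        if len(raw) == 0:
            return ms
        tgt, ref, s, e = raw[:, 0], raw[:, 1], raw[:, 2], raw[:, 3]
        if exclude_same_individual:
            sel = (tgt // 2) != (ref // 2)
            tgt, ref, s, e = tgt[sel], ref[sel], s[sel], e[sel]
        for t in np.unique(tgt):
            m = tgt == t
            ms.add(int(t), ref[m], s[m], e[m])
        return ms
    # target-vs-reference: enumerate maximal matches then containment-filter
    ms = MatchSet(n_snp=ref_panel.n_snp, n_ref=ref_panel.n_hap,
                  n_target=target_panel.n_hap)
    X = ref_panel.alleles
    K = ref_panel.n_snp
    for t in range(target_panel.n_hap):
        y = target_panel.alleles[t]
        eq = X == y  # (N, K)
        padded = np.zeros((X.shape[0], K + 2), dtype=bool)
        padded[:, 1:-1] = eq
        d = np.diff(padded.astype(np.int8), axis=1)
        ref_idx, starts = np.nonzero(d == 1)
        _, ends = np.nonzero(d == -1)
        ends = ends - 1
        if len(ref_idx) == 0:
            continue
        r, s, e = _filter_set_maximal(ref_idx.astype(np.int64),
                                      starts.astype(np.int64),
                                      ends.astype(np.int64))
        ms.add(t, r, s, e)
    return ms


def default_L0(K: int, L_min: int) -> int:
    """Starting length for the halving search: 2^ceil(log2(K/16)), >= L_min."""
    L0 = 1 << max(0, int(np.ceil(np.log2(max(K / 16.0, 1.0)))))
    return max(L0, L_min)


def report_q_longest_matches(index: PBWTIndex, target_panel: HaplotypePanel | None,
                             gmap: GeneticMap, Q: int = 10, L_min: int = 20,
                             L_0: int | None = None) -> MatchSet:
    """Keep at least the Q longest matches (>= L_min SNPs) at every SNP.

    Stage 1 lowers a length threshold from L_0 by halving (floored at
    L_min), storing matches whose length falls in the current bin and which
    cover some SNP that still has fewer than Q stored matches.  Stage 2
    sorts the stored candidates by descending genetic length and greedily
    keeps a match iff some SNP it covers still has fewer than Q kept
    matches.  SNPs may end with fewer than Q (or zero) matches; see
    :func:`impute_empty_positions`.
    """
    ref_panel = index.panel
    if target_panel is None:
        target_panel = ref_panel
    K = ref_panel.n_snp
    if Q < 1 or L_min < 1:
        raise ValueError("Q and L_min must be >= 1")
    if L_0 is None:
        L_0 = default_L0(K, L_min)
    if L_0 < L_min:
        raise ValueError("L_0 must be >= L_min")
    L_eff = min(L_min, K)
    tgt_all, ref_all, s_all, e_all = _merged_long_matches(ref_panel, target_panel, L_eff)
    cm = gmap.cm
    ms = MatchSet(n_snp=K, n_ref=ref_panel.n_hap, n_target=target_panel.n_hap,
                  Q=Q, L_min=L_min, L_0=L_0)
    for t in range(target_panel.n_hap):
        sel = tgt_all == t
        if not np.any(sel):
            continue
        ref, s, e = ref_all[sel], s_all[sel], e_all[sel]
        lens = e - s + 1
        # --- stage 1: staged storage by halving length threshold
        stored = np.zeros(len(ref), dtype=bool)
        diff = np.zeros(K + 1, dtype=np.int64)

        def _store(idx):
            stored[idx] = True
            np.add.at(diff, s[idx], 1)
            np.add.at(diff, e[idx] + 1, -1)

        _store(np.nonzero(lens >= L_0)[0])
        L_prev = L_0
        Lq = max(L_0 // 2, L_min)
        while L_prev > L_min:
            counts = np.cumsum(diff[:-1])
            r = counts < Q
            if not np.any(r):
                break
            rcum = np.concatenate([[0], np.cumsum(r)])
            cand = np.nonzero((~stored) & (lens >= Lq) & (lens < L_prev))[0]
            if len(cand):
                covers_r = (rcum[e[cand] + 1] - rcum[s[cand]]) > 0
                _store(cand[covers_r])
            L_prev = Lq
            Lq = max(Lq // 2, L_min)
        cand_idx = np.nonzero(stored)[0]
        # --- stage 2: greedy cover by descending genetic length
        len_cm = cm[e[cand_idx]] - cm[s[cand_idx]]
        order = np.lexsort((s[cand_idx], ref[cand_idx], -lens[cand_idx], -len_cm))
        keep = _greedy_stage2(s[cand_idx], e[cand_idx],
                              order.astype(np.int64), Q, K)
        kept = cand_idx[keep]
        ms.add(t, ref[kept], s[kept], e[kept])
    return ms


def impute_empty_positions(matchset: MatchSet, gmap: GeneticMap) -> MatchSet:
    """Give every zero-coverage SNP the donors of its nearest covered SNP.

    Nearest is in genetic distance, ties broken to the left.  Contiguous
    empty runs sharing a source yield single merged pseudo-matches flagged
    imputed (excluded from chunk-count accounting downstream).  Raises if a
    target haplotype has no matches anywhere.
    """
    K = matchset.n_snp
    cm = gmap.cm
    out = MatchSet(n_snp=K, n_ref=matchset.n_ref, n_target=matchset.n_target,
                   Q=matchset.Q, L_min=matchset.L_min, L_0=matchset.L_0)
    for t in range(matchset.n_target):
        m = matchset.get(t)
        if len(m["ref"]) == 0:
            raise ValueError(f"target haplotype {t} has no matches on this chromosome")
        out.add(t, m["ref"], m["s"], m["e"], m["imputed"])
        cov = matchset.coverage(t)
        empty = np.nonzero(cov == 0)[0]
        if len(empty) == 0:
            continue
        covered = np.nonzero(cov > 0)[0]
        # nearest covered SNP in cM, tie -> left
        pos = np.searchsorted(cm[covered], cm[empty])
        left = np.clip(pos - 1, 0, len(covered) - 1)
        right = np.clip(pos, 0, len(covered) - 1)
        dl = np.abs(cm[empty] - cm[covered[left]])
        dr = np.abs(cm[covered[right]] - cm[empty])
        src = np.where(dl <= dr, covered[left], covered[right])
        # group consecutive empty SNPs with a common source
        brk = np.nonzero((np.diff(empty) != 1) | (np.diff(src) != 0))[0] + 1
        for grp in np.split(np.arange(len(empty)), brk):
            k0, k1 = empty[grp[0]], empty[grp[-1]]
            c = src[grp[0]]
            covering = (m["s"] <= c) & (m["e"] >= c)
            refs = np.unique(m["ref"][covering])
            out.add(t, refs, np.full(len(refs), k0), np.full(len(refs), k1),
                    np.ones(len(refs), dtype=bool))
    return out
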