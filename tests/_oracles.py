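"""Independent oracles: brute-force enumeration and dense-model references.

Everything here is deliberately naive (quadratic scans, dense matrices,
explicit sorts) and shares no code with the package's sparse paths.
"""

import numpy as np


def enumerate_maximal_matches(X, Y=None):
    """All maximal match triples by direct pairwise run scanning.

    Within X (Y is None): set of (i, j, s, e) with i < j.
    Between X rows (targets) and Y rows (refs): set of (i, j, s, e).
    """
    def runs(a, b, i, j, acc):
        eq = a == b
        K = len(eq)
        s = None
        for k in range(K + 1):
            if k < K and eq[k]:
                if s is None:
                    s = k
            elif s is not None:
                acc.add((i, j, s, k - 1))
                s = None

    out = set()
    if Y is None:
        for i in range(X.shape[0]):
            for j in range(i + 1, X.shape[0]):
                runs(X[i], X[j], i, j, out)
    else:
        for i in range(X.shape[0]):
            for j in range(Y.shape[0]):
                runs(X[i], Y[j], i, j, out)
    return out


def set_maximal_oracle(X, exclude_same_individual=False):
    """Per-target set-maximal matches: maximal matches not strictly
    contained in another match of the same target."""
    per = {}
    for (i, j, s, e) in enumerate_maximal_matches(X):
        per.setdefault(i, []).append((j, s, e))
        per.setdefault(j, []).append((i, s, e))
    out = set()
    for t, ms in per.items():
        if exclude_same_individual:
            ms = [(r, s, e) for (r, s, e) in ms if r // 2 != t // 2]
        for (r, s, e) in ms:
            contained = any(s2 <= s and e2 >= e and (s2 < s or e2 > e)
                            for (_r2, s2, e2) in ms)
            if not contained:
                out.add((t, r, s, e))
    return out


def greedy_q_longest_oracle(matches, cm, Q, K):
    """Greedy cover over ALL maximal matches >= L_min, sorted by
    (genetic length desc, SNP length desc, ref asc, start asc)."""
    def key(m):
        r, s, e = m
        return (-(cm[e] - cm[s]), -(e - s + 1), r, s)

    counts = np.zeros(K, dtype=int)
    kept = []
    for (r, s, e) in sorted(matches, key=key):
        if np.any(counts[s:e + 1] < Q):
            kept.append((r, s, e))
            counts[s:e + 1] += 1
    return set(kept)


def min_cover_dp(intervals, K):
    """Minimum number of intervals covering [0, K-1] by dynamic programming.

    cover[k] = fewest intervals covering [0, k]; returns -1 if impossible.
    """
    INF = 10 ** 9
    best = np.full(K + 1, INF, dtype=np.int64)  # best[k]: cover of [0, k-1]
    best[0] = 0
    for k in range(K):
        if best[k] == INF:
            continue
        for (s, e) in intervals:
            if s <= k <= e:
                if best[k] + 1 < best[e + 1]:
                    best[e + 1] = best[k] + 1
    return int(best[K]) if best[K] < INF else -1


def dense_li_stephens(X, y, gaps, lam, mu=1e-9):
    """Dense scaled Li & Stephens forward-backward.

    Returns (posterior (K, N), expected lengths (N,), expected counts (N,)).
    """
    N, K = X.shape
    m = (X == y[None, :]).astype(float)
    v = np.where(m == 1, 1 - mu, mu)
    rho = np.exp(-lam * gaps)
    rhot = (1 - rho) / N
    fhat = np.zeros((K, N))
    logcf = np.zeros(K)
    f = v[:, 0] / N
    s = f.sum()
    fhat[0] = f / s
    logcf[0] = np.log(s)
    for j in range(1, K):
        f = v[:, j] * (rho[j - 1] * fhat[j - 1] + rhot[j - 1])
        s = f.sum()
        fhat[j] = f / s
        logcf[j] = logcf[j - 1] + np.log(s)
    bhat = np.zeros((K, N))
    logcb = np.zeros(K)
    b = np.ones(N)
    s = b.sum()
    bhat[K - 1] = b / s
    logcb[K - 1] = np.log(s)
    for j in range(K - 2, -1, -1):
        d = v[:, j + 1] * bhat[j + 1]
        b = rho[j] * d + rhot[j] * d.sum()
        s = b.sum()
        bhat[j] = b / s
        logcb[j] = logcb[j + 1] + np.log(s)
    post = fhat * bhat
    post /= post.sum(axis=1, keepdims=True)
    l_hat = np.zeros(N)
    for j in range(K - 1):
        l_hat += 0.5 * gaps[j] * (post[j] + post[j + 1])
    logPr = logcf[K - 1]
    c_hat = np.exp(logcf[0] + logcb[0] - logPr) * fhat[0] * bhat[0]
    for j in range(K - 1):
        c_hat += (np.exp(logcf[j + 1] + logcb[j + 1] - logPr)
                  * fhat[j + 1] * bhat[j + 1])
        c_hat -= (np.exp(logcf[j] + logcb[j + 1] - logPr)
                  * fhat[j] * bhat[j + 1] * v[:, j + 1] * rho[j])
    return post, l_hat, c_hat


def sparse_posterior_to_dense(fb, post, N):
    """Expand a sparse per-SNP posterior into a (K, N) matrix."""
    K = fb.n_snp
    P = np.zeros((K, N))
    for j in range(K):
        lo, hi = fb.indptr[j], fb.indptr[j + 1]
        P[j, fb.donors[lo:hi]] = post[lo:hi]
    return P


def mosaic_target(rng, X, n_seg):
    """Target haplotype stitched from panel rows: matched at every SNP."""
    K = X.shape[1]
    bnds = np.sort(rng.choice(np.arange(1, K), size=n_seg - 1, replace=False))
    y = np.empty(K, dtype=np.uint8)
    for seg in np.split(np.arange(K), bnds):
        y[seg] = X[rng.integers(0, X.shape[0])][seg]
    return y
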