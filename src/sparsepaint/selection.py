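"""Ancestry-based selection statistics: LDA, LDAS and AAS with QC.

LDA (linkage disequilibrium of ancestry) between SNPs j and l compares the
per-haplotype total-variation distance between the two local ancestry
vectors against its expectation when haplotypes are paired at random:
``LDA = (D_null - D_obs) / D_null``.  The null mean is computed exactly as
a U-statistic over all ordered haplotype pairs rather than by permutation.

LDAS integrates LDA over a +/- X cM window around each SNP treating LDA as
piecewise linear in genetic distance, with step-function upper and lower
bounds whose difference bounds the integration error; windows truncated by
a chromosome end are reflected.  Low LDAS — unusually short ancestry
haplotypes — flags recent positive selection.

AAS (ancestry anomaly score) is the squared z-score of a SNP's mean
ancestry profile against the genome-wide mean, summed over ancestries and
calibrated against a method-of-moments Gamma fit.

These statistic definitions are reconstructions consistent with the stated
properties (range, null behaviour, Gamma-like tail) of the originals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sstats

__all__ = [
    "AncestryField",
    "LDASTrack",
    "AASTrack",
    "lda_pair",
    "ldas",
    "ldas_qc",
    "ldas_pvalues",
    "aas",
    "classify_signals",
]

DENSITY_BINS = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])


@dataclass
class AncestryField:
    """Per-haplotype, per-SNP ancestry probabilities plus the genetic map.

    ``probs`` has shape (n_hap, n_pop, K); each haplotype's vector at a SNP
    is non-negative and sums to 1.  ``cm`` are the SNP genetic positions.
    """

    probs: np.ndarray
    cm: np.ndarray
    pops: list | None = None
    chrom_length_cm: float | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] != len(self.cm):
            raise ValueError("probs must be (n_hap, n_pop, K) matching cm")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-4) or np.any(self.probs < -1e-12):
            raise ValueError("ancestry vectors must be non-negative, sum to 1")

    @property
    def n_hap(self):
        return self.probs.shape[0]

    @property
    def n_pop(self):
        return self.probs.shape[1]

    @property
    def n_snp(self):
        return self.probs.shape[2]


@dataclass
class LDASTrack:
    """Per-SNP LDAS with bounds, error, QC flags and p-values."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    density_counts: np.ndarray | None = None


@dataclass
class AASTrack:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    gamma_shape: float = np.nan
    gamma_scale: float = np.nan
    mean_ancestry: np.ndarray | None = None


# ---------------------------------------------------------------------------
# LDA

def _prepare(field_: AncestryField):
    t = np.ascontiguousarray(field_.probs.transpose(2, 1, 0))  # (K, n_pop, n)
    srt = np.sort(t, axis=2)
    cums = np.cumsum(srt, axis=2)
    return t, srt, cums


@njit(cache=True)
def _lda_pair_kernel(tprobs, srt, cums, j, l):
    K, n_pop, n = tprobs.shape
    dobs_sum = 0.0
    for i in range(n):
        s = 0.0
        for a in range(n_pop):
            s += abs(tprobs[j, a, i] - tprobs[l, a, i])
        dobs_sum += 0.5 * s
    cross = 0.0
    for a in range(n_pop):
        toty = cums[l, a, n - 1]
        ii = 0
        for idx in range(n):
            xv = srt[j, a, idx]
            while ii < n and srt[l, a, ii] <= xv:
                ii += 1
            pre = cums[l, a, ii - 1] if ii > 0 else 0.0
            cross += xv * ii - pre + (toty - pre) - xv * (n - ii)
    cross *= 0.5
    dobs = dobs_sum / n
    dnull = (cross - dobs_sum) / (n * (n - 1.0))
    if dnull <= 0.0:
        return 0.0
    return (dnull - dobs) / dnull


def lda_pair(field_: AncestryField, j: int, l: int) -> float:
    """LDA between SNPs j and l (exact all-pairs null)."""
    if field_.n_hap < 2:
        raise ValueError("LDA needs at least 2 haplotypes")
    t, srt, cums = _prepare(field_)
    return float(_lda_pair_kernel(t, srt, cums, j, l))


# ---------------------------------------------------------------------------
# LDAS integration

@njit(cache=True)
def _integrate(g, v, A, B):
    """Piecewise-linear integral with step-function bounds over [A, B].

    ``g``/``v`` are SNP positions and LDA values covering [A, B] as far as
    the chromosome allows; beyond the outermost point the point estimate
    and the upper bound extend the boundary value flat while the lower
    bound takes zero (chromosome-end convention).  Returns (est, up, lo).
    """
    est = 0.0
    up = 0.0
    lo = 0.0
    if B <= A:
        return est, up, lo
    m = len(g)
    if g[0] > A:
        w = min(g[0], B) - A
        if w > 0:
            est += v[0] * w
            up += v[0] * w
    if g[m - 1] < B:
        w = B - max(g[m - 1], A)
        if w > 0:
            est += v[m - 1] * w
            up += v[m - 1] * w
    for i in range(m - 1):
        x0 = g[i]
        x1 = g[i + 1]
        if x1 <= A or x0 >= B:
            continue
        c0 = x0 if x0 > A else A
        c1 = x1 if x1 < B else B
        if c1 <= c0:
            continue
        if x1 > x0:
            y0 = v[i] + (v[i + 1] - v[i]) * (c0 - x0) / (x1 - x0)
            y1 = v[i] + (v[i + 1] - v[i]) * (c1 - x0) / (x1 - x0)
        else:
            y0 = v[i]
            y1 = v[i + 1]
        w = c1 - c0
        est += 0.5 * (y0 + y1) * w
        hiv = v[i] if v[i] > v[i + 1] else v[i + 1]
        lov = v[i] if v[i] < v[i + 1] else v[i + 1]
        up += hiv * w
        lo += lov * w
    return est, up, lo


@njit(cache=True)
def _ldas_kernel(tprobs, srt, cums, cm, X, L):
    """LDAS, upper and lower bound per SNP; cm shifted to chromosome start 0."""
    K = tprobs.shape[0]
    out = np.empty((K, 3))
    for j in range(K):
        gj = cm[j]
        # window SNPs within X, plus one flank either side for interpolation
        lo_i = np.searchsorted(cm, gj - X)
        hi_i = np.searchsorted(cm, gj + X, side="right") - 1
        lo_f = lo_i - 1 if lo_i > 0 else 0
        hi_f = hi_i + 1 if hi_i < K - 1 else K - 1
        m = hi_f - lo_f + 1
        g = np.empty(m)
        v = np.empty(m)
        for t in range(m):
            l = lo_f + t
            g[t] = cm[l]
            v[t] = 1.0 if l == j else _lda_pair_kernel(tprobs, srt, cums, j, l)
        A = gj - X if gj - X > 0.0 else 0.0
        B = gj + X if gj + X < L else L
        est, up, lov = _integrate(g, v, A, B)
        # lower bound: zero LDA at true chromosome ends inside the window
        if gj < X:
            e2, u2, l2 = _integrate(g, v, 2.0 * gj, gj + X if gj + X < L else L)
            est += e2
            up += u2
            lov += l2
        if gj > L - X:
            e2, u2, l2 = _integrate(g, v, gj - X if gj - X > 0.0 else 0.0,
                                    2.0 * gj - L)
            est += e2
            up += u2
            lov += l2
        out[j, 0] = est
        out[j, 1] = up
        out[j, 2] = lov
    return out


def _density_counts(cm, bins=DENSITY_BINS):
    """n_m(j): SNPs at distance (m-0.5, m] cM from each SNP, both sides."""
    K = len(cm)
    counts = np.zeros((K, len(bins)), dtype=np.int64)
    for bi, m in enumerate(bins):
        lo, hi = m - 0.5, m
        # right side: cm_j + lo < cm_l <= cm_j + hi ; left mirrored
        r = (np.searchsorted(cm, cm + hi, side="right")
             - np.searchsorted(cm, cm + lo, side="right"))
        lft = (np.searchsorted(cm, cm - lo, side="left")
               - np.searchsorted(cm, cm - hi, side="left"))
        counts[:, bi] = r + lft
    return counts


def ldas(field_: AncestryField, X: float = 4.0) -> LDASTrack:
    """LDAS with upper/lower bounds for every SNP of the chromosome."""
    if field_.n_hap < 2:
        raise ValueError("LDAS needs at least 2 haplotypes")
    t, srt, cums = _prepare(field_)
    cm0 = field_.cm[0]
    cm = field_.cm - cm0
    L = (field_.chrom_length_cm - cm0 if field_.chrom_length_cm is not None
         else cm[-1])
    res = _ldas_kernel(t, srt, cums, cm, float(X), float(L))
    df = pd.DataFrame({
        "cm": field_.cm,
        "ldas": res[:, 0],
        "ldas_upper": res[:, 1],
        "ldas_lower": res[:, 2],
    })
    df["ldas_error"] = df["ldas_upper"] - df["ldas_lower"]
    return LDASTrack(table=df, density_counts=_density_counts(cm))


def ldas_qc(track: LDASTrack, delta: float = 0.3, theta: int = 10) -> LDASTrack:
    """QC flags: relative error below delta and enough SNPs in every
    half-cM distance bin out to 3 cM."""
    df = track.table
    mean_ldas = df["ldas"].mean()
    df["ldas_error_norm"] = df["ldas_error"] / mean_ldas
    dens_ok = (track.density_counts >= theta).all(axis=1)
    df["qc_pass"] = (df["ldas_error_norm"] < delta) & dens_ok
    return track


def ldas_pvalues(track: LDASTrack) -> LDASTrack:
    """Lower-tail normal p-values for low LDAS among QC-passing SNPs."""
    df = track.table
    if "qc_pass" not in df:
        raise ValueError("run ldas_qc first")
    passing = df.loc[df["qc_pass"], "ldas"]
    sd = passing.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("LDAS has zero variance among QC-passing SNPs")
    z = (df["ldas"] - passing.mean()) / sd
    df["p_low"] = sstats.norm.cdf(z)
    df.loc[~df["qc_pass"], "p_low"] = np.nan
    return track


# ---------------------------------------------------------------------------
# AAS

def aas(field_: AncestryField) -> AASTrack:
    """Ancestry anomaly score per SNP with Gamma-calibrated p-values."""
    if field_.n_pop < 2:
        raise ValueError("AAS needs at least 2 populations")
    pbar = field_.probs.mean(axis=0)  # (n_pop, K)
    mu = pbar.mean(axis=1)
    sd = pbar.std(axis=1, ddof=0)
    keep = sd > 1e-12  # tolerance: constant tracks carry only float noise
    if not keep.all():
        warnings.warn("dropping zero-variance ancestries from AAS")
    z = (pbar[keep] - mu[keep, None]) / sd[keep, None]
    score = (z ** 2).sum(axis=0)
    m, v = score.mean(), score.var(ddof=0)
    if v > 0 and m > 0:
        shape = m * m / v
        scale = v / m
        pvals = sstats.gamma.sf(score, a=shape, scale=scale)
    else:
        shape = scale = np.nan
        pvals = np.ones_like(score)
    df = pd.DataFrame({"cm": field_.cm, "aas": score, "p_aas": pvals})
    return AASTrack(table=df, gamma_shape=float(shape),
                    gamma_scale=float(scale), mean_ancestry=pbar)


# ---------------------------------------------------------------------------
# shared / cohort-specific classification

def classify_signals(pvalues: dict, candidate: float, shared: float,
                     specific: float) -> np.ndarray:
    """Label SNPs as 'shared', 'specific' or '' across cohorts.

    A SNP is a candidate when any cohort reaches ``candidate``; it is
    shared when every non-candidate cohort reaches ``shared`` and
    cohort-specific when every non-candidate cohort stays above
    ``specific``; otherwise it is left unlabelled.  LDAS uses
    (1e-6, 0.05, 0.1); AAS uses (1e-50, 1e-10, 1e-5).
    """
    if len(pvalues) < 2:
        raise ValueError("classification needs >= 2 cohorts")
    P = np.vstack([np.asarray(v, dtype=np.float64) for v in pvalues.values()])
    cand = P <= candidate
    any_cand = cand.any(axis=0)
    labels = np.full(P.shape[1], "", dtype=object)
    others = np.ma.masked_array(P, mask=cand)
    all_shared = (others <= shared).all(axis=0).filled(True)
    all_specific = (others > specific).all(axis=0).filled(True)
    labels[any_cand & all_shared] = "shared"
    labels[any_cand & ~all_shared & all_specific] = "specific"
    return labels
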