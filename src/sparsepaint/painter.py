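"""Painting orchestration: match finding, HMM runs and aggregation.

Three modes mirror the painting use cases:

* ``tvr`` — target-vs-reference: paint target haplotypes against a labelled
  reference panel (local ancestry inference); optional leave-one-out drops
  one designated individual per reference population so target and
  reference individuals receive exchangeable paintings.
* ``rvr`` — reference-vs-reference: each reference individual is painted
  against the panel minus itself minus one designated individual from every
  other population (palette construction for admixture estimation).
* ``ava`` — all-vs-all with only the individual itself left out.

The designated left-out individual per population is the one with the
lowest individual index, for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import (HMMParams, estimate_lambda, expected_chunk_counts,
                  expected_chunk_lengths, posterior, run_forward_backward)
from .panel import GeneticMap, HaplotypePanel
from .pbwt import (MatchSet, build_pbwt, default_L0, impute_empty_positions,
                   report_q_longest_matches)

__all__ = ["PaintingResult", "paint_targets", "dosage_tracks"]


@dataclass
class PaintingResult:
    """Aggregated output of one painting run.

    ``pop_probs[t, a, j]`` is the posterior probability that target
    haplotype ``t`` copies from population ``a`` at SNP ``j`` (columns sum
    to 1).  ``chunk_lengths``/``chunk_counts`` are per donor haplotype;
    ``pop_chunk_lengths`` aggregates lengths into donor populations.
    """

    pops: list
    lam: float
    chunk_lengths: np.ndarray          # (n_target_hap, n_ref_hap)
    chunk_counts: np.ndarray           # (n_target_hap, n_ref_hap)
    pop_chunk_lengths: np.ndarray      # (n_target_hap, n_pop)
    pop_probs: np.ndarray | None = None  # (n_target_hap, n_pop, K) float32
    target_sample_ids: list = field(default_factory=list)

    @property
    def n_target_hap(self) -> int:
        return self.chunk_lengths.shape[0]


def _designated_excluded(panel: HaplotypePanel) -> dict:
    """Lowest individual index per population (deterministic leave-one-out)."""
    first = {}
    for i in range(panel.n_ind):
        pop = panel.pop_label[i]
        if pop not in first:
            first[pop] = i
    return first


def _hap_pop_matrix(panel: HaplotypePanel, pops: list) -> np.ndarray:
    """(n_hap, n_pop) one-hot matrix mapping donor haplotypes to populations."""
    idx = {p: a for a, p in enumerate(pops)}
    M = np.zeros((panel.n_hap, len(pops)))
    for h in range(panel.n_hap):
        M[h, idx[panel.pop_of_hap(h)]] = 1.0
    return M


def _allowed_masks(ref_panel: HaplotypePanel, mode: str,
                   leave_one_out: bool, n_target_hap: int):
    """Per-target boolean donor masks over reference haplotypes (or one
    shared mask when identical for all targets)."""
    n_hap = ref_panel.n_hap
    if mode == "tvr":
        mask = np.ones(n_hap, dtype=bool)
        if leave_one_out:
            for ind in _designated_excluded(ref_panel).values():
                mask[2 * ind] = mask[2 * ind + 1] = False
            for pop in ref_panel.populations():
                if sum(mask[2 * i] for i in range(ref_panel.n_ind)
                       if ref_panel.pop_label[i] == pop) == 0:
                    raise ValueError(f"population {pop} has no donors left")
        return [mask] * n_target_hap
    if mode == "ava":
        masks = []
        for t in range(n_target_hap):
            mask = np.ones(n_hap, dtype=bool)
            ind = t // 2
            mask[2 * ind] = mask[2 * ind + 1] = False
            masks.append(mask)
        return masks
    if mode == "rvr":
        for pop in ref_panel.populations():
            n_in_pop = sum(1 for i in range(ref_panel.n_ind)
                           if ref_panel.pop_label[i] == pop)
            if n_in_pop < 2:
                raise ValueError(
                    f"population {pop} has a single individual; "
                    "reference-vs-reference painting needs >= 2")
        designated = _designated_excluded(ref_panel)
        masks = []
        for t in range(n_target_hap):
            own = t // 2
            own_pop = ref_panel.pop_label[own]
            mask = np.ones(n_hap, dtype=bool)
            mask[2 * own] = mask[2 * own + 1] = False
            for pop, ind in designated.items():
                if pop != own_pop:
                    mask[2 * ind] = mask[2 * ind + 1] = False
            if not mask.any():
                raise ValueError("leave-one-out emptied the donor pool")
            masks.append(mask)
        return masks
    raise ValueError(f"unknown mode {mode!r}")


def paint_targets(ref_panel: HaplotypePanel, target_panel: HaplotypePanel | None,
                  gmap: GeneticMap, mode: str = "tvr", Q: int = 10,
                  L_min: int = 20, L_0: int | None = None,
                  lam: float | None = None, leave_one_out: bool = False,
                  store_pop_probs: bool = True,
                  matchset: MatchSet | None = None) -> PaintingResult:
    """Paint target haplotypes and aggregate to populations.

    Orchestrates match finding (Q longest matches per SNP), imputation of
    matchless positions, lambda estimation when ``lam`` is None, the sparse
    forward-backward, and population aggregation.  An externally computed
    ``matchset`` (e.g. set-maximal matches) can be injected instead of the
    default query.
    """
    if ref_panel.pop_label is None:
        raise ValueError("reference panel needs population labels")
    if mode in ("rvr", "ava") or target_panel is None:
        target_panel = ref_panel
    pops = ref_panel.populations()
    K = ref_panel.n_snp
    if matchset is None:
        index = build_pbwt(ref_panel)
        same = target_panel is ref_panel
        matchset = report_q_longest_matches(
            index, None if same else target_panel, gmap, Q=Q, L_min=L_min,
            L_0=L_0 if L_0 is not None else default_L0(K, L_min))
    n_t = target_panel.n_hap
    masks = _allowed_masks(ref_panel, mode, leave_one_out, n_t)
    # matchsets restricted to allowed donors, then imputed per target
    restricted = MatchSet(n_snp=K, n_ref=ref_panel.n_hap, n_target=n_t,
                          Q=matchset.Q, L_min=matchset.L_min, L_0=matchset.L_0)
    for t in range(n_t):
        m = matchset.get(t)
        keep = masks[t][m["ref"]]
        restricted.add(t, m["ref"][keep], m["s"][keep], m["e"][keep],
                       m["imputed"][keep])
    imputed = impute_empty_positions(restricted, gmap)
    if lam is None:
        lam = estimate_lambda(imputed, gmap)
    hap2pop = _hap_pop_matrix(ref_panel, pops)
    chunk_lengths = np.zeros((n_t, ref_panel.n_hap))
    chunk_counts = np.zeros((n_t, ref_panel.n_hap))
    pop_probs = (np.zeros((n_t, len(pops), K), dtype=np.float32)
                 if store_pop_probs else None)
    for t in range(n_t):
        n_donor = int(masks[t].sum())
        params = HMMParams.from_map(gmap, lam, n_donor)
        fb = run_forward_backward(imputed, gmap, params, t)
        post = posterior(fb)
        chunk_lengths[t] = expected_chunk_lengths(fb, gmap, ref_panel.n_hap,
                                                  post=post)
        chunk_counts[t] = expected_chunk_counts(fb, ref_panel.n_hap, post=post)
        if store_pop_probs:
            dense = np.zeros((len(pops), K), dtype=np.float64)
            pop_of = hap2pop.argmax(axis=1)
            for j in range(K):
                lo, hi = fb.indptr[j], fb.indptr[j + 1]
                np.add.at(dense[:, j], pop_of[fb.donors[lo:hi]], post[lo:hi])
            pop_probs[t] = dense.astype(np.float32)
    pop_chunk_lengths = chunk_lengths @ hap2pop
    return PaintingResult(
        pops=pops, lam=float(lam), chunk_lengths=chunk_lengths,
        chunk_counts=chunk_counts, pop_chunk_lengths=pop_chunk_lengths,
        pop_probs=pop_probs,
        target_sample_ids=list(target_panel.sample_ids))


def dosage_tracks(result: PaintingResult) -> np.ndarray:
    """Per-individual ancestry dosage: mean of the two haplotype tracks.

    Returns (n_ind, n_pop, K); values lie in [0, 1].
    """
    if result.pop_probs is None:
        raise ValueError("painting was run without storing probabilities")
    probs = result.pop_probs
    return 0.5 * (probs[0::2] + probs[1::2])
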