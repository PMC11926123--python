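"""Reference palettes and non-negative least squares admixture estimation.

The palette is an n_pop x n_pop matrix whose row a is the mean per-individual
copied-length profile (over donor populations) of recipients from population
a under reference-vs-reference leave-one-out painting.  Any individual's
copied-length vector b is then decomposed as a non-negative mixture of
palette rows by minimising ||P^T x - b||_2 subject to x >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _nnls

from .painter import PaintingResult, paint_targets
from .panel import GeneticMap, HaplotypePanel

__all__ = ["Palette", "AdmixtureEstimate", "build_palette", "nnls_admixture",
           "individual_chunk_lengths"]


@dataclass
class Palette:
    """Mean expected copied length per recipient (row) x donor (column) pop."""

    pops: list
    A_pal: np.ndarray  # (n_pop, n_pop), entries >= 0, rows sum to G


@dataclass
class AdmixtureEstimate:
    """NNLS coefficients per individual, raw and normalised to sum 1."""

    pops: list
    x_raw: np.ndarray
    x: np.ndarray
    residual: float


def individual_chunk_lengths(result: PaintingResult) -> np.ndarray:
    """Per-individual copied length by donor population: the average of the
    individual's two haplotype profiles, so each row sums to G."""
    per_hap = result.pop_chunk_lengths
    return 0.5 * (per_hap[0::2] + per_hap[1::2])


def build_palette(ref_panel: HaplotypePanel, gmap: GeneticMap, Q: int = 10,
                  L_min: int = 20, lam: float | None = None,
                  result: PaintingResult | None = None):
    """Palette from reference-vs-reference leave-one-out painting.

    Returns ``(Palette, per_individual_b)`` where the second element is the
    (n_ind, n_pop) copied-length matrix of the reference individuals
    themselves (average of their two haplotypes), reusable as NNLS targets.
    """
    if result is None:
        result = paint_targets(ref_panel, None, gmap, mode="rvr", Q=Q,
                               L_min=L_min, lam=lam, store_pop_probs=False)
    pops = result.pops
    per_hap = result.pop_chunk_lengths  # rows sum to G
    b_ind = 0.5 * (per_hap[0::2] + per_hap[1::2])
    pal = np.zeros((len(pops), len(pops)))
    for a, pop in enumerate(pops):
        rows = [i for i in range(ref_panel.n_ind)
                if ref_panel.pop_label[i] == pop]
        if len(rows) < 2:
            raise ValueError(f"population {pop} needs >= 2 individuals")
        pal[a] = b_ind[rows].mean(axis=0)
    return Palette(pops=pops, A_pal=pal), b_ind


def nnls_admixture(palette: Palette, b: np.ndarray) -> AdmixtureEstimate:
    """Describe an individual as a non-negative mixture of palette rows.

    ``b`` is the individual's expected copied length per donor population;
    solves min ||P^T x - b||_2, x >= 0 with the standard active-set solver,
    which is deterministic for fixed input order.
    """
    b = np.asarray(b, dtype=np.float64)
    if b.shape != (len(palette.pops),):
        raise ValueError("b must have one entry per population")
    if not np.any(b > 0):
        raise ValueError("all-zero chunk length vector")
    x, res = _nnls(palette.A_pal.T, b)
    tot = x.sum()
    if tot <= 0:
        raise ValueError("NNLS returned the zero vector")
    return AdmixtureEstimate(pops=palette.pops, x_raw=x, x=x / tot,
                             residual=float(res))
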