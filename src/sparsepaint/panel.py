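"""Core in-memory containers: haplotype panels and genetic maps.

A :class:`HaplotypePanel` holds ``2N`` phased binary haplotypes over ``K``
biallelic SNPs (rows = haplotypes, columns = SNPs), together with sample
metadata and optional population labels.  A :class:`GeneticMap` holds the
cumulative genetic position (cM) of every SNP and derived per-gap distances
in Morgans, which parameterise the copying model's switch probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes with sample/population metadata.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    positions : ndarray of int, shape (K,)
        Physical bp positions, strictly increasing.
    alleles : ndarray of uint8, shape (2N, K)
        0 = reference allele, 1 = alternate.  Haplotypes ``2i`` and
        ``2i + 1`` belong to individual ``i``.
    sample_ids : list of str, length N
    pop_label : dict mapping individual index -> population name, optional
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_ids: list
    pop_label: dict | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (diploid panel)")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("row count must equal 2 * number of samples")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("column count must equal number of positions")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be binary (0/1)")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_ind(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_snp(self) -> int:
        return self.alleles.shape[1]

    def hap_owner(self, hap: int) -> int:
        """Individual index owning haplotype ``hap``."""
        return hap // 2

    def populations(self) -> list:
        """Sorted distinct population names (requires labels)."""
        if self.pop_label is None:
            raise ValueError("panel has no population labels")
        return sorted(set(self.pop_label.values()))

    def pop_of_hap(self, hap: int) -> str:
        return self.pop_label[hap // 2]

    def subset_individuals(self, ind_idx) -> "HaplotypePanel":
        """New panel restricted to the given individual indices (order kept)."""
        ind_idx = np.asarray(ind_idx, dtype=np.int64)
        hap_idx = np.empty(2 * len(ind_idx), dtype=np.int64)
        hap_idx[0::2] = 2 * ind_idx
        hap_idx[1::2] = 2 * ind_idx + 1
        labels = None
        if self.pop_label is not None:
            labels = {new: self.pop_label[old] for new, old in enumerate(ind_idx)}
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions,
            alleles=self.alleles[hap_idx],
            sample_ids=[self.sample_ids[i] for i in ind_idx],
            pop_label=labels,
        )

    def concat_haplotypes(self, other: "HaplotypePanel") -> "HaplotypePanel":
        """Stack another panel's haplotypes below this one (same SNPs)."""
        if not np.array_equal(self.positions, other.positions):
            raise ValueError("panels must share identical SNP positions")
        labels = None
        if self.pop_label is not None and other.pop_label is not None:
            labels = dict(self.pop_label)
            for i, lab in other.pop_label.items():
                labels[self.n_ind + i] = lab
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions,
            alleles=np.vstack([self.alleles, other.alleles]),
            sample_ids=list(self.sample_ids) + list(other.sample_ids),
            pop_label=labels,
        )


@dataclass
class GeneticMap:
    """Cumulative genetic positions for a panel's SNPs.

    ``cm[j]`` is the genetic position of SNP ``j`` in centiMorgans;
    ``gap_morgans[j] = (cm[j+1] - cm[j]) / 100`` is the distance between
    adjacent SNPs in Morgans (length K - 1).
    """

    cm: np.ndarray
    chrom_length_cm: float | None = None
    gap_morgans: np.ndarray = field(init=False)

    def __post_init__(self):
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if len(self.cm) > 1 and np.any(np.diff(self.cm) < 0):
            raise ValueError("cm positions must be non-decreasing")
        self.gap_morgans = np.diff(self.cm) / 100.0
        if self.chrom_length_cm is None:
            self.chrom_length_cm = float(self.cm[-1]) if len(self.cm) else 0.0

    @property
    def total_morgans(self) -> float:
        """G: total genetic length spanned by the SNPs, in Morgans."""
        return float(self.gap_morgans.sum())


def interpolate_cm(positions, anchor_bp, anchor_cm) -> np.ndarray:
    """Linear interpolation of genetic position at ``positions``.

    Beyond the outermost anchors the map is extrapolated flat (constant cM).
    """
    positions = np.asarray(positions, dtype=np.float64)
    anchor_bp = np.asarray(anchor_bp, dtype=np.float64)
    anchor_cm = np.asarray(anchor_cm, dtype=np.float64)
    if len(anchor_bp) < 1:
        raise ValueError("genetic map needs at least one anchor point")
    return np.interp(positions, anchor_bp, anchor_cm)
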