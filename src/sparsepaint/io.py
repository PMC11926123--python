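"""Readers and writers for the standard text formats.

Supported inputs: ChromoPainter-style "phase" files, phased VCF, 2- or
3-column genetic map text, and 2-column population label files.  Outputs are
tab-separated probability / chunk tables, gzip-compressed when the path ends
with ``.gz``.  Missing data is not supported: the copying model assumes
complete phased binary haplotypes, and strict mode is the default.
"""

from __future__ import annotations

import gzip
import io as _io

import numpy as np
import pandas as pd

from .panel import GeneticMap, HaplotypePanel, interpolate_cm

__all__ = [
    "read_phase",
    "write_phase",
    "read_vcf",
    "read_genetic_map",
    "read_labels",
    "write_painting",
    "write_chunks",
    "read_painting",
]


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_genetic_map(path):
    """Parse a genetic map file into (bp, cM) anchor arrays.

    Accepts 2-column ``bp  cumulative_cM`` files or plink 3-column
    ``bp  rate  cumulative_cM`` maps (the rate column is ignored).  A header
    line is skipped if the first field is not numeric.
    """
    bp, cm = [], []
    with _open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            try:
                float(parts[0])
            except ValueError:
                continue  # header
            if len(parts) >= 3:
                bp.append(float(parts[0]))
                cm.append(float(parts[2]))
            elif len(parts) == 2:
                bp.append(float(parts[0]))
                cm.append(float(parts[1]))
            else:
                raise ValueError(f"malformed genetic map line: {line!r}")
    bp = np.asarray(bp)
    cm = np.asarray(cm)
    order = np.argsort(bp)
    return bp[order], cm[order]


def _map_for_positions(positions, map_path) -> GeneticMap:
    anchor_bp, anchor_cm = read_genetic_map(map_path)
    return GeneticMap(cm=interpolate_cm(positions, anchor_bp, anchor_cm))


def read_phase(path, map_path=None, chrom="1", sample_ids=None):
    """Read a ChromoPainter phase file.

    Layout: a haplotype-count line, a SNP-count line, a positions line
    prefixed ``P``, then one 0/1 string per haplotype.

    Returns ``(HaplotypePanel, GeneticMap | None)``; the map is interpolated
    linearly between anchor points of ``map_path`` when given.
    """
    with _open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n_hap = int(lines[0].split()[0])
    n_snp = int(lines[1].split()[0])
    pos_line = lines[2].split()
    if pos_line[0] != "P":
        raise ValueError("phase file positions line must start with 'P'")
    positions = np.asarray(pos_line[1:], dtype=np.int64)
    if len(positions) != n_snp:
        raise ValueError("position count disagrees with SNP count header")
    if len(positions) > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("phase file positions must be strictly ascending")
    hap_lines = lines[3 : 3 + n_hap]
    if len(hap_lines) != n_hap:
        raise ValueError("fewer haplotype rows than declared in header")
    alleles = np.empty((n_hap, n_snp), dtype=np.uint8)
    for i, hl in enumerate(hap_lines):
        row = np.frombuffer(hl.strip().encode(), dtype=np.uint8) - ord("0")
        if len(row) != n_snp or row.max(initial=0) > 1:
            raise ValueError(f"haplotype row {i} is not a {n_snp}-length 0/1 string")
        alleles[i] = row
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(n_hap // 2)]
    panel = HaplotypePanel(chrom=chrom, positions=positions, alleles=alleles,
                           sample_ids=sample_ids)
    gmap = _map_for_positions(positions, map_path) if map_path is not None else None
    return panel, gmap


def write_phase(panel: HaplotypePanel, path):
    """Write a panel in ChromoPainter phase format."""
    with _open(path, "wt") as fh:
        fh.write(f"{panel.n_hap}\n{panel.n_snp}\n")
        fh.write("P " + " ".join(str(p) for p in panel.positions) + "\n")
        for row in panel.alleles:
            fh.write("".join("01"[v] for v in row) + "\n")


def read_vcf(path, map_path=None, strict=True):
    """Read phased biallelic SNPs from a VCF via cyvcf2.

    Haplotype rows follow sample order: haplotypes ``2i`` and ``2i+1`` belong
    to sample ``i``.  Unphased or multiallelic records raise in strict mode
    and are skipped in lenient mode; missing genotypes always raise in strict
    mode.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    positions, rows, chrom = [], [], None
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if strict:
                raise ValueError(f"non-biallelic-SNP record at {var.CHROM}:{var.POS}")
            continue
        gts = np.asarray(var.genotype.array())
        # columns: allele_a, allele_b, phased flag
        if np.any(gts[:, :2] < 0):
            if strict:
                raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
            continue
        if np.any(gts[:, 2] == 0):
            if strict:
                raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
            continue
        chrom = var.CHROM
        positions.append(var.POS)
        rows.append(gts[:, :2].astype(np.uint8))
    if not rows:
        raise ValueError("no usable records in VCF")
    alleles = np.stack(rows, axis=-1).reshape(2 * len(sample_ids), len(positions))
    panel = HaplotypePanel(chrom=chrom or "1", positions=np.asarray(positions),
                           alleles=alleles, sample_ids=sample_ids)
    gmap = _map_for_positions(panel.positions, map_path) if map_path is not None else None
    return panel, gmap


def read_labels(path) -> dict:
    """Read a 2-column ``sample_id  population`` TSV into a dict."""
    out = {}
    with _open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].lower() in {"sample", "id", "#sample"}:
                continue
            if len(parts) < 2:
                raise ValueError(f"label line needs two columns: {line!r}")
            out[parts[0]] = parts[1]
    return out


def attach_labels(panel: HaplotypePanel, labels: dict) -> None:
    """Set ``panel.pop_label`` from a sample_id -> population mapping.

    Phase files carry no sample names; when none of the panel's (generated)
    ids appear in the label file but the file lists exactly one label per
    individual, labels are assigned in file order.
    """
    missing = [s for s in panel.sample_ids if s not in labels]
    if missing:
        if len(missing) == panel.n_ind and len(labels) == panel.n_ind:
            panel.sample_ids = list(labels.keys())
            panel.pop_label = dict(enumerate(labels.values()))
            return
        raise ValueError(f"samples without population label: {missing[:5]}")
    panel.pop_label = {i: labels[s] for i, s in enumerate(panel.sample_ids)}


def write_painting(probs, path, colnames, positions=None, precision=4):
    """Write a per-SNP probability table (rows = SNPs, columns = populations).

    Row sums must be 1 within 1e-6 before rounding.  Gzip if the path ends
    with ``.gz``.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[1] != len(colnames):
        raise ValueError("probs must be (n_snp, n_pop) matching colnames")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"row {bad} sums to {sums[bad]:.8f}, not 1")
    fmt = f"%.{precision}f"
    with _open(path, "wt") as fh:
        header = list(colnames)
        if positions is not None:
            header = ["pos"] + header
        fh.write("\t".join(header) + "\n")
        for j in range(probs.shape[0]):
            cells = [fmt % v for v in probs[j]]
            if positions is not None:
                cells = [str(positions[j])] + cells
            fh.write("\t".join(cells) + "\n")


def read_painting(path):
    """Read back a probability table written by :func:`write_painting`."""
    df = pd.read_csv(path, sep="\t")
    return df


def write_chunks(table, path, precision=4):
    """Write a chunk-length / chunk-count summary DataFrame as TSV."""
    df = pd.DataFrame(table)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format=f"%.{precision}f")
    with _open(path, "wt") as fh:
        fh.write(buf.getvalue())
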