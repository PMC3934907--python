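"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity by exhaustive linear
scans or enumeration, independent of the indexed implementations they
are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from chiptarget.annotation_io import GeneRecord, GenomeAnnotation, tss_of
from chiptarget.peak_model import Peak, PeakSet


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_nearest_tss(genes, chrom, start, end):
    """Linear-scan nearest TSS to the interval [start, end): (ids, distance)."""
    best = None
    winners = []
    for g in genes:
        if g.chrom != chrom:
            continue
        p = tss_of(g)
        if start <= p < end:
            d = 0
        elif p < start:
            d = start - p
        else:
            d = p - (end - 1)
        if best is None or d < best:
            best, winners = d, [g.gene_id]
        elif d == best:
            winners.append(g.gene_id)
    return sorted(winners), best


def brute_assign(genes, peak):
    """All-pairs overlap/gap scan for one peak: (status, [(gene_id, distance)])."""
    overlaps = [
        g.gene_id
        for g in genes
        if g.chrom == peak.chrom and g.start < peak.end and peak.start < g.end
    ]
    if overlaps:
        return "GENE_OVERLAP", sorted((gid, 0) for gid in overlaps)
    best, winners = None, []
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        if g.end <= peak.start:
            gap = peak.start - g.end
        else:
            gap = g.start - peak.end
        if best is None or gap < best:
            best, winners = gap, [g.gene_id]
        elif gap == best:
            winners.append(g.gene_id)
    return "GENE_CLOSE", sorted((gid, best) for gid in winners)


def random_annotation(rng, n_genes=200, n_chroms=3, span=100_000):
    genes = []
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(n_chroms)) + 1}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 2_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"g{i:04d}", f"g{i:04d}", chrom, start, start + length, strand))
    return GenomeAnnotation(genes=genes)


def random_peaks(rng, n_peaks=500, n_chroms=3, span=100_000):
    peaks = []
    for i in range(n_peaks):
        chrom = f"chr{int(rng.integers(n_chroms)) + 1}"
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, 3_000))
        peaks.append(
            Peak(
                f"pk{i:04d}",
                chrom,
                start,
                start + width,
                float(rng.uniform(0, 650)),
                float(rng.uniform(0.5, 60)),
            )
        )
    return PeakSet(peaks=peaks)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_annotation():
    """Two chromosomes, four genes, both strands."""
    return GenomeAnnotation(
        genes=[
            GeneRecord("gA", "alpha", "2L", 100, 400, "+"),
            GeneRecord("gB", "beta", "2L", 1_000, 1_600, "-"),
            GeneRecord("gC", "gamma", "2L", 5_000, 5_500, "+"),
            GeneRecord("gD", "delta", "3R", 200, 900, "+"),
        ]
    )
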