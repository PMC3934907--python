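"""Peak-to-gene assignment and nearest-TSS distance profiles.

A peak that intersects one or more gene spans (any partial overlap of
the half-open intervals) is assigned to every gene it overlaps with
status ``GENE_OVERLAP`` and gene distance 0.  A peak overlapping no gene
is assigned to the gene(s) minimising the gap between the peak edge and
the gene edge, with status ``GENE_CLOSE``; on an exact distance tie all
tied genes are assigned, ordered by gene_id.  Strand plays no role in
overlap or gap; it only places the TSS.

Every assignment also carries the nearest TSS and its distance, which is
measured from the nearest peak edge (0 when the TSS falls inside the
peak) and is independent of the assigned gene -- the nearest TSS may
belong to a different gene.

Degenerate case: a gene abutting a peak (gene end == peak start) has gap
0 under the half-open convention and is reported as GENE_CLOSE with
distance 0 rather than as an overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .annotation_io import GenomeAnnotation, TSSIndex, build_tss_index
from .peak_model import Peak, PeakSet

logger = logging.getLogger(__name__)

GENE_OVERLAP = "GENE_OVERLAP"
GENE_CLOSE = "GENE_CLOSE"

DEFAULT_BIN_EDGES = (0, 1_000, 5_000, 10_000, 20_000)

__all__ = [
    "Assignment",
    "DistanceProfile",
    "GENE_OVERLAP",
    "GENE_CLOSE",
    "DEFAULT_BIN_EDGES",
    "assign_peaks_to_genes",
    "tss_distance",
    "distance_profile",
    "summarize_gene_status",
    "read_peak_table",
    "write_assignments_bed",
    "plot_distance_profile",
]


@dataclass(frozen=True)
class Assignment:
    """One peak-gene link plus the peak's nearest-TSS annotation."""

    peak_id: str
    gene_id: str
    status: str  # GENE_OVERLAP or GENE_CLOSE
    gene_distance: int  # bp; 0 for overlaps
    tss_gene_id: str
    tss_distance: int  # bp from nearest peak edge; 0 if TSS inside peak

    def __post_init__(self):
        if self.status not in (GENE_OVERLAP, GENE_CLOSE):
            raise ValueError(f"unknown assignment status {self.status!r}")
        if self.status == GENE_OVERLAP and self.gene_distance != 0:
            raise ValueError("GENE_OVERLAP assignments must have gene_distance 0")
        if self.gene_distance < 0 or self.tss_distance < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class DistanceProfile:
    """Histogram of nearest-TSS distances over half-open bins."""

    bin_edges: tuple  # finite lower edges; last bin is [edges[-1], inf)
    counts: np.ndarray
    fractions: np.ndarray

    def labels(self) -> list[str]:
        edges = list(self.bin_edges)
        out = []
        for lo, hi in zip(edges, edges[1:]):
            out.append(f"[{lo},{hi})")
        out.append(f">={edges[-1]}")
        return out

    def as_rows(self) -> list[tuple[str, int, float]]:
        return [
            (label, int(c), float(f))
            for label, c, f in zip(self.labels(), self.counts, self.fractions)
        ]


def _chrom_gene_arrays(annotation: GenomeAnnotation):
    """Per-chromosome interval tree plus edge arrays for nearest-gap queries."""
    out = {}
    for chrom, genes in annotation.by_chrom().items():
        tree = IntervalTree()
        for g in genes:
            tree.addi(g.start, g.end, g.gene_id)
        by_end = sorted((g.end, g.gene_id) for g in genes)
        by_start = sorted((g.start, g.gene_id) for g in genes)
        ends = np.array([e for e, _ in by_end], dtype=np.int64)
        starts = np.array([s for s, _ in by_start], dtype=np.int64)
        out[chrom] = (tree, ends, [gid for _, gid in by_end], starts, [gid for _, gid in by_start])
    return out


def assign_peaks_to_genes(
    peaks: PeakSet | Iterable[Peak],
    annotation: GenomeAnnotation,
    tss_index: TSSIndex | None = None,
) -> list[Assignment]:
    """Assign every peak to its overlapping gene(s), or else the nearest gene.

    Peaks on chromosomes absent from the annotation cannot be assigned;
    they are excluded with a logged warning.
    """
    if tss_index is None:
        tss_index = build_tss_index(annotation)
    chrom_data = _chrom_gene_arrays(annotation)
    assignments: list[Assignment] = []
    skipped = 0
    for peak in peaks:
        data = chrom_data.get(peak.chrom)
        if data is None:
            logger.warning(
                "peak %s on chromosome %r absent from annotation; excluded",
                peak.peak_id,
                peak.chrom,
            )
            skipped += 1
            continue
        tree, ends, end_ids, starts, start_ids = data
        tss_ids, tss_d = tss_index.nearest_to_interval(peak.chrom, peak.start, peak.end)
        tss_gene = tss_ids[0]
        hits = tree.overlap(peak.start, peak.end)
        if hits:
            for gid in sorted(iv.data for iv in hits):
                assignments.append(
                    Assignment(peak.peak_id, gid, GENE_OVERLAP, 0, tss_gene, tss_d)
                )
            continue
        # No overlap: nearest gene edge on either side (half-open gap).
        candidates: list[tuple[int, str, int]] = []  # (gap, side, boundary)
        j = int(np.searchsorted(ends, peak.start, "right")) - 1
        if j >= 0:
            candidates.append((peak.start - int(ends[j]), "L", int(ends[j])))
        j = int(np.searchsorted(starts, peak.end, "left"))
        if j < len(starts):
            candidates.append((int(starts[j]) - peak.end, "R", int(starts[j])))
        best = min(g for g, _, _ in candidates)
        winners: set[str] = set()
        for gap, side, boundary in candidates:
            if gap != best:
                continue
            if side == "L":
                a = int(np.searchsorted(ends, boundary, "left"))
                b = int(np.searchsorted(ends, boundary, "right"))
                winners.update(end_ids[a:b])
            else:
                a = int(np.searchsorted(starts, boundary, "left"))
                b = int(np.searchsorted(starts, boundary, "right"))
                winners.update(start_ids[a:b])
        for gid in sorted(winners):
            assignments.append(
                Assignment(peak.peak_id, gid, GENE_CLOSE, best, tss_gene, tss_d)
            )
    if skipped:
        logger.warning("%d peak(s) excluded (chromosome not annotated)", skipped)
    return assignments


def tss_distance(peak: Peak, tss_index: TSSIndex) -> tuple[str, int]:
    """Nearest TSS to a peak: (gene_id, distance from nearest peak edge).

    Distance is 0 if any TSS position p satisfies start <= p < end; on a
    tie the gene with the lexicographically smallest gene_id is returned.
    """
    if tss_index.n_genes == 0:
        raise ValueError("empty TSS index")
    ids, d = tss_index.nearest_to_interval(peak.chrom, peak.start, peak.end)
    return ids[0], d


def distance_profile(
    assignments: Iterable[Assignment],
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> DistanceProfile:
    """Bin each peak's unique nearest-TSS distance into half-open bins.

    Bins are [e0,e1), [e1,e2), ..., [e_last, inf): a distance equal to an
    edge falls into the upper bin (1,000 bp lands in the 1-5 kb bin).
    """
    dists: dict[str, int] = {}
    for a in assignments:
        dists[a.peak_id] = a.tss_distance
    values = np.array(sorted(dists.values()), dtype=float)
    edges = list(bin_edges) + [np.inf]
    counts, _ = np.histogram(values, bins=edges)
    total = counts.sum()
    fractions = counts / total if total else np.zeros_like(counts, dtype=float)
    return DistanceProfile(
        bin_edges=tuple(bin_edges), counts=counts.astype(int), fractions=fractions
    )


def summarize_gene_status(assignments: Iterable[Assignment]) -> tuple[float, float, int]:
    """(fraction of peaks with >=1 overlap, intergenic fraction, distinct genes).

    A peak overlapping several genes counts once in the overlap fraction
    but contributes each gene to the distinct-gene tally.
    """
    assignments = list(assignments)
    peak_ids = {a.peak_id for a in assignments}
    if not peak_ids:
        raise ValueError("no assignments to summarise")
    overlap_peaks = {a.peak_id for a in assignments if a.status == GENE_OVERLAP}
    genes = {a.gene_id for a in assignments}
    frac_overlap = len(overlap_peaks) / len(peak_ids)
    return frac_overlap, 1.0 - frac_overlap, len(genes)


def read_peak_table(path) -> list[Assignment]:
    """Read assignments back from an annotated peak table (write_peak_table)."""
    path = Path(path)
    assignments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        required = {"GENE", "GENE_STATUS", "GENE_DIS", "TSS_GENE", "TSS_DIS", "INDEX"}
        missing = required - set(col)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            assignments.append(
                Assignment(
                    peak_id=f"index_{f[col['INDEX']]}",
                    gene_id=f[col["GENE"]],
                    status=f[col["GENE_STATUS"]],
                    gene_distance=int(f[col["GENE_DIS"]]),
                    tss_gene_id=f[col["TSS_GENE"]],
                    tss_distance=int(f[col["TSS_DIS"]]),
                )
            )
    return assignments


def write_assignments_bed(peaks: PeakSet, assignments: Iterable[Assignment], path) -> None:
    """Export peak-gene links as BED6 with the gene in the name field."""
    by_id = peaks.by_id()
    with open(Path(path), "w") as fh:
        for a in assignments:
            p = by_id[a.peak_id]
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{a.gene_id}\t"
                f"{min(1000, int(round(p.score)))}\t.\n"
            )


def plot_distance_profile(profile: DistanceProfile, path) -> None:
    """Bar chart of the nearest-TSS distance distribution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    labels = profile.labels()
    ax.bar(range(len(labels)), 100 * profile.fractions, color="#4878a8")
    ax.set_xticks(range(len(labels)), labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("% of peaks")
    ax.set_xlabel("distance to nearest TSS (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
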