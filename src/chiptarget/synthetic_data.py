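"""Synthetic genomes, peaks, sequences, and expression responses.

Every generator is a pure function of its configuration (which carries
the seed), so repeated runs are byte-identical.  The defaults emulate a
eye-disc-scale transcription-factor ChIP experiment: ~7,566 peaks of
mean width ~1 kb with a strong TSS-proximal placement bias (52.4% of
peaks within 1 kb of a TSS), 84.7% of peaks overlapping a gene, peak
scores spanning 50-650 on the -10*log10 P scale, a planted degenerate
binding motif, and two expression contrasts with 460 loss-responders,
444 gain-responders and a 94-gene overlap that classify into 468
positive, 290 negative and 52 ambiguous targets.

Placement geometry is deliberately sparse (intergenic gaps larger than
the largest simulated TSS distance plus the widest peak), so each
peak's realised nearest-TSS distance and intragenic status equal the
planted ones exactly; parameter-recovery tests then only fight binomial
sampling noise, not placement collisions.  The response table satisfies
its marginal and category targets by construction rather than by
rejection sampling, so the count arithmetic is reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation_io import GeneRecord, GenomeAnnotation, tss_of, write_gene_annotation
from .motif_scan import IUPACMotif, expand_iupac, reverse_complement, write_fasta
from .peak_model import Peak, PeakSet, write_peaks
from .regulatory_classifier import (
    GAIN,
    LOSS,
    DOWN,
    UP,
    ProbeResponse,
    write_expression_table,
    write_probe_table,
    write_term_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "FeasibilityError",
    "CapacityError",
    "simulate_annotation",
    "simulate_peaks",
    "simulate_sequences",
    "simulate_response_table",
    "simulate_expression",
    "simulate_term_map",
    "simulate_all",
    "response_cells",
]


class FeasibilityError(ValueError):
    """The requested marginal/category targets cannot be realised."""


class CapacityError(ValueError):
    """Genes cannot be placed within the configured chromosome length."""


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic data.

    The response/category defaults are the printed marginals of the
    emulated experiment; geometry defaults keep genes far enough apart
    that planted TSS distances are realised exactly (see module
    docstring).
    """

    seed: int = 0
    # genome / annotation
    n_chroms: int = 4
    chrom_length: int = 44_000_000
    n_genes: int = 1_200
    gene_length_range: tuple[int, int] = (1_000, 60_000)
    # gap_lo must exceed 2 * max_tss_distance + peak width so that a peak
    # placed upstream of a gene is never closer to the neighbouring TSS
    intergenic_gap_range: tuple[int, int] = (95_000, 140_000)
    overlap_fraction: float = 0.0
    # peaks
    n_peaks: int = 7_566
    peak_width_mean: float = 1_000.0
    peak_width_sd: float = 250.0
    min_peak_width: int = 100
    # 52.4% < 1 kb, 78.9% <= 10 kb and 10.8% > 20 kb pin four bins; the
    # 10-20 kb bin takes the remaining 10.3% so the vector sums to 1.
    tss_bin_targets: tuple[float, ...] = (0.524, 0.167, 0.098, 0.103, 0.108)
    bin_edges: tuple[int, ...] = (0, 1_000, 5_000, 10_000, 20_000)
    max_tss_distance: int = 45_000
    frac_intragenic: float = 0.847
    score_range: tuple[float, float] = (50.0, 650.0)
    fold_range: tuple[float, float] = (3.0, 60.0)
    # sequences
    planted_motifs: tuple[tuple[str, str, float], ...] = (("So", "AGATAC", 0.4),)
    # expression response
    response_marginals: tuple[int, int, int] = (460, 444, 94)  # loss, gain, both
    category_targets: tuple[int, int, int] = (468, 290, 52)  # pos, neg, amb
    pos_breakdown: tuple[int, int, int] | None = (257, 244, 33)  # loss, gain, both
    neg_breakdown: tuple[int, int, int] | None = (151, 149, 10)
    allow_dual_direction: bool = True
    n_nonpeak_responders: int = 90
    n_decoy_probes: int = 40
    # expression levels / terms
    expression_log10_range: tuple[float, float] = (-1.0, 3.0)
    frac_novel: float = 0.5
    n_terms: int = 20
    term_size_range: tuple[int, int] = (10, 60)

    def __post_init__(self):
        if abs(sum(self.tss_bin_targets) - 1.0) > 1e-9:
            raise FeasibilityError("tss_bin_targets must sum to 1")
        if len(self.tss_bin_targets) != len(self.bin_edges):
            raise FeasibilityError("one bin target per bin edge is required")
        n_loss, n_gain, n_both = self.response_marginals
        if n_both > min(n_loss, n_gain):
            raise FeasibilityError("n_both cannot exceed min(n_loss, n_gain)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        kwargs = {}
        for key, value in data.items():
            if isinstance(value, list):
                value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
            kwargs[key] = value
        return cls(**kwargs)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _chrom_names(n: int) -> list[str]:
    base = ["2L", "2R", "3L", "3R", "X", "4"]
    if n <= len(base):
        return base[:n]
    return base + [f"scf{i}" for i in range(1, n - len(base) + 1)]


def _log_uniform_int(rng, lo: int, hi: int) -> int:
    return int(round(10 ** rng.uniform(math.log10(lo), math.log10(hi))))


def simulate_annotation(config: SyntheticConfig) -> tuple[GenomeAnnotation, dict]:
    """Place genes sequentially with random intergenic gaps.

    Genes are non-overlapping by default; ``overlap_fraction`` nests an
    extra gene inside the previous one to exercise multi-gene peak
    assignment (this breaks the sparse-geometry guarantee, so leave it
    at 0 for parameter-recovery runs).  Raises :class:`CapacityError`
    when the requested genes do not fit.
    """
    rng = _rng(config, 11)
    gap_lo, gap_hi = config.intergenic_gap_range
    len_lo, len_hi = config.gene_length_range
    chroms = _chrom_names(config.n_chroms)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneRecord] = []
    overlapping_pairs: list[tuple[str, str]] = []
    idx = 0
    for chrom, count in zip(chroms, per_chrom):
        pos = int(rng.integers(gap_lo, gap_hi))
        placed = 0
        while placed < count:
            length = _log_uniform_int(rng, len_lo, len_hi)
            end = pos + length
            if end + gap_lo > config.chrom_length:
                raise CapacityError(
                    f"cannot place {count} genes on {chrom} of length "
                    f"{config.chrom_length}; {placed} placed"
                )
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            host = GeneRecord(f"g{idx:05d}", f"gene{idx}", chrom, pos, end, strand)
            genes.append(host)
            placed += 1
            if placed < count and rng.random() < config.overlap_fraction and length >= 400:
                # nested partner gene to create a multi-gene locus
                idx += 1
                nstart = pos + int(rng.integers(0, length // 2))
                nlen = int(rng.integers(200, max(201, length // 2)))
                nested = GeneRecord(
                    f"g{idx:05d}",
                    f"gene{idx}",
                    chrom,
                    nstart,
                    min(nstart + nlen, end),
                    "+" if rng.random() < 0.5 else "-",
                )
                genes.append(nested)
                overlapping_pairs.append((host.gene_id, nested.gene_id))
                placed += 1
            pos = end + int(rng.integers(gap_lo, gap_hi))
    annotation = GenomeAnnotation(
        genes=genes, chrom_sizes={c: config.chrom_length for c in chroms}
    )
    truth = {
        "n_genes": len(genes),
        "overlapping_pairs": overlapping_pairs,
        "strand_counts": {
            "+": sum(1 for g in genes if g.strand == "+"),
            "-": sum(1 for g in genes if g.strand == "-"),
        },
    }
    return annotation, truth


def simulate_peaks(
    annotation: GenomeAnnotation, config: SyntheticConfig
) -> tuple[PeakSet, dict]:
    """Draw a TSS-distance bin and intragenic flag per peak, then realise them.

    For an intragenic peak the nearest edge is placed ``d`` bp into the
    gene body from its TSS (d = 0 covers the TSS); for an intergenic
    peak the same distance is realised on the upstream side, outside
    the gene.  With the default sparse geometry the realised
    nearest-TSS distance equals the drawn ``d`` exactly.
    """
    rng = _rng(config, 22)
    genes = sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    lengths = np.array([g.length for g in genes])
    targets = np.asarray(config.tss_bin_targets, dtype=float)
    targets = targets / targets.sum()
    edges = list(config.bin_edges) + [config.max_tss_distance]
    eligible_by_bin = [np.flatnonzero(lengths > lo + 1) for lo in edges[:-1]]
    for b, eligible in enumerate(eligible_by_bin):
        if config.frac_intragenic > 0 and targets[b] > 0 and eligible.size == 0:
            raise FeasibilityError(
                f"no gene long enough for an intragenic peak in bin {b} "
                f"(needs length > {edges[b] + 1})"
            )
    peaks: list[Peak] = []
    truth_rows = []
    s_lo, s_hi = config.score_range
    f_lo, f_hi = config.fold_range
    for i in range(config.n_peaks):
        b = int(rng.choice(len(targets), p=targets))
        intragenic = bool(rng.random() < config.frac_intragenic)
        width = max(config.min_peak_width, int(round(rng.normal(config.peak_width_mean, config.peak_width_sd))))
        lo, hi = edges[b], edges[b + 1]
        if intragenic:
            cand = eligible_by_bin[b]
            gi = int(cand[rng.integers(cand.size)])
            gene = genes[gi]
            d_hi = min(hi, gene.length - 1)
            d = int(rng.integers(lo, d_hi)) if d_hi > lo else lo
            tss = tss_of(gene)
            if d == 0:
                offset = int(rng.integers(0, width))
                start = tss - offset
            elif gene.strand == "+":
                start = tss + d
            else:
                start = tss - d + 1 - width
            end = start + width
        else:
            gi = int(rng.integers(len(genes)))
            gene = genes[gi]
            d = int(rng.integers(max(lo, 1), hi))
            tss = tss_of(gene)
            if gene.strand == "+":
                end = tss - d + 1
                start = end - width
            else:
                start = tss + d
                end = start + width
        score = 10 ** rng.uniform(math.log10(s_lo), math.log10(s_hi))
        fold = 10 ** rng.uniform(math.log10(f_lo), math.log10(f_hi))
        peak_id = f"pk{i + 1:05d}"
        peaks.append(
            Peak(peak_id, gene.chrom, int(start), int(end), float(score), float(fold))
        )
        truth_rows.append(
            {
                "peak_id": peak_id,
                "bin": b,
                "intragenic": intragenic,
                "gene_id": gene.gene_id,
                "tss_distance": d,
            }
        )
    truth = {
        "peaks": truth_rows,
        "bin_counts": [sum(1 for r in truth_rows if r["bin"] == b) for b in range(len(targets))],
        "n_intragenic": sum(1 for r in truth_rows if r["intragenic"]),
    }
    return PeakSet(peaks=peaks, provenance=f"simulated (seed={config.seed})"), truth


def _concretize(consensus: str, rng) -> str:
    return "".join(sorted(expand_iupac(c))[rng.integers(len(expand_iupac(c)))] for c in consensus)


def simulate_sequences(peaks: PeakSet, config: SyntheticConfig) -> tuple[dict[str, str], dict]:
    """Uniform-random DNA per peak, with exact motif instances planted.

    For each (name, consensus, fraction) in ``planted_motifs``, a random
    subset of peaks of that fraction receives one concrete instance of
    the consensus at a random offset on a random strand.  Sequences too
    short for the motif are skipped with a log message.
    """
    rng = _rng(config, 33)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences: dict[str, str] = {}
    peak_ids = []
    for p in peaks:
        sequences[p.peak_id] = bases[rng.integers(0, 4, p.width)].tobytes().decode()
        peak_ids.append(p.peak_id)
    planted: dict[str, list[str]] = {}
    for name, consensus, fraction in config.planted_motifs:
        IUPACMotif(name, consensus)  # validate
        k = int(round(fraction * len(peak_ids)))
        chosen = rng.choice(len(peak_ids), size=k, replace=False)
        hit_ids: list[str] = []
        for ci in sorted(int(c) for c in chosen):
            pid = peak_ids[ci]
            seq = sequences[pid]
            if len(consensus) > len(seq):
                logger.warning("sequence %s shorter than motif %s; planting skipped", pid, name)
                continue
            instance = _concretize(consensus, rng)
            if rng.random() < 0.5:
                instance = reverse_complement(instance)
            off = int(rng.integers(0, len(seq) - len(instance) + 1))
            sequences[pid] = seq[:off] + instance + seq[off + len(instance):]
            hit_ids.append(pid)
        planted[name] = hit_ids
    truth = {"planted": planted}
    return sequences, truth


def response_cells(config: SyntheticConfig) -> dict[str, int]:
    """Disjoint cell counts realising the marginal and category targets.

    Cells are (category x contrast pattern): loss-only, gain-only and
    both-contrast genes for POS and NEG; for AMB, cross-contrast
    conflicting genes plus single-contrast genes whose probes disagree
    within that contrast (dual-direction).  Raises
    :class:`FeasibilityError` when no non-negative allocation exists.
    """
    n_loss, n_gain, n_both = config.response_marginals
    n_pos, n_neg, n_amb = config.category_targets
    total = n_pos + n_neg + n_amb
    if n_loss + n_gain - n_both != total:
        raise FeasibilityError(
            f"marginals (loss {n_loss} + gain {n_gain} - both {n_both}) must equal "
            f"category total {total}"
        )
    loss_only_total = n_loss - n_both
    gain_only_total = n_gain - n_both
    if config.pos_breakdown is not None or config.neg_breakdown is not None:
        if config.pos_breakdown is None or config.neg_breakdown is None:
            raise FeasibilityError("pos_breakdown and neg_breakdown must be given together")
        pl, pg, pb = config.pos_breakdown
        nl, ng, nb = config.neg_breakdown
        if pl + pg - pb != n_pos or pb > min(pl, pg):
            raise FeasibilityError("pos_breakdown inconsistent with n_pos")
        if nl + ng - nb != n_neg or nb > min(nl, ng):
            raise FeasibilityError("neg_breakdown inconsistent with n_neg")
        cells = {
            "pos_loss_only": pl - pb,
            "pos_gain_only": pg - pb,
            "pos_both": pb,
            "neg_loss_only": nl - nb,
            "neg_gain_only": ng - nb,
            "neg_both": nb,
        }
        cells["amb_both"] = n_both - pb - nb
        cells["amb_loss_only"] = loss_only_total - cells["pos_loss_only"] - cells["neg_loss_only"]
        cells["amb_gain_only"] = gain_only_total - cells["pos_gain_only"] - cells["neg_gain_only"]
    else:
        amb_both = min(n_amb, n_both)
        rem_amb = n_amb - amb_both
        amb_loss_only = min(rem_amb, loss_only_total)
        amb_gain_only = rem_amb - amb_loss_only
        rb = n_both - amb_both
        pos_both = min(rb, n_pos)
        neg_both = rb - pos_both
        rl = loss_only_total - amb_loss_only
        pos_loss_only = min(rl, n_pos - pos_both)
        pos_gain_only = n_pos - pos_both - pos_loss_only
        rg = gain_only_total - amb_gain_only
        neg_loss_only = rl - pos_loss_only
        neg_gain_only = rg - pos_gain_only
        cells = {
            "pos_loss_only": pos_loss_only,
            "pos_gain_only": pos_gain_only,
            "pos_both": pos_both,
            "neg_loss_only": neg_loss_only,
            "neg_gain_only": neg_gain_only,
            "neg_both": neg_both,
            "amb_both": amb_both,
            "amb_loss_only": amb_loss_only,
            "amb_gain_only": amb_gain_only,
        }
    if any(v < 0 for v in cells.values()):
        raise FeasibilityError(f"infeasible target combination: {cells}")
    amb_total = cells["amb_both"] + cells["amb_loss_only"] + cells["amb_gain_only"]
    if amb_total != n_amb:
        raise FeasibilityError(
            f"ambiguous cells sum to {amb_total}, expected {n_amb}"
        )
    if (cells["amb_loss_only"] or cells["amb_gain_only"]) and not config.allow_dual_direction:
        raise FeasibilityError(
            "single-contrast ambiguous genes need dual-direction probes "
            "(allow_dual_direction=True)"
        )
    if cells["neg_gain_only"] > gain_only_total or cells["pos_gain_only"] > gain_only_total:
        raise FeasibilityError("gain margin exceeded")
    return cells


# probe sign patterns per cell: list of (contrast, direction)
_CELL_SIGNS = {
    "pos_loss_only": [(LOSS, DOWN)],
    "pos_gain_only": [(GAIN, UP)],
    "pos_both": [(LOSS, DOWN), (GAIN, UP)],
    "neg_loss_only": [(LOSS, UP)],
    "neg_gain_only": [(GAIN, DOWN)],
    "neg_both": [(LOSS, UP), (GAIN, DOWN)],
    "amb_loss_only": [(LOSS, UP), (LOSS, DOWN)],
    "amb_gain_only": [(GAIN, UP), (GAIN, DOWN)],
}
_CELL_CATEGORY = {
    "pos_loss_only": "POS",
    "pos_gain_only": "POS",
    "pos_both": "POS",
    "neg_loss_only": "NEG",
    "neg_gain_only": "NEG",
    "neg_both": "NEG",
    "amb_both": "AMB",
    "amb_loss_only": "AMB",
    "amb_gain_only": "AMB",
}


def simulate_response_table(
    config: SyntheticConfig, peak_genes: Iterable[str]
) -> tuple[list[ProbeResponse], dict]:
    """Plant categories onto peak-bearing genes so every target count is exact.

    Also emits ``n_nonpeak_responders`` responding genes without peaks
    (to exercise the intersection step) and ``n_decoy_probes``
    non-significant probes.
    """
    cells = response_cells(config)
    rng = _rng(config, 44)
    pool = sorted(set(peak_genes))
    need = sum(cells.values())
    if len(pool) < need:
        raise FeasibilityError(
            f"need {need} peak-bearing genes for the response table, have {len(pool)}"
        )
    chosen_idx = rng.choice(len(pool), size=need, replace=False)
    chosen = [pool[int(i)] for i in chosen_idx]
    probes: list[ProbeResponse] = []
    truth_category: dict[str, str] = {}
    truth_cell: dict[str, str] = {}
    counter = 0

    def add_probe(gene: str, contrast: str, direction: str, significant: bool = True):
        nonlocal counter
        counter += 1
        probes.append(
            ProbeResponse(f"pr{counter:05d}", gene, contrast, direction, significant)
        )

    cursor = 0
    for cell in sorted(cells):
        count = cells[cell]
        for _ in range(count):
            gene = chosen[cursor]
            cursor += 1
            truth_category[gene] = _CELL_CATEGORY[cell]
            truth_cell[gene] = cell
            if cell == "amb_both":
                # conflicting inference across contrasts, orientation randomised
                if rng.random() < 0.5:
                    signs = [(LOSS, DOWN), (GAIN, DOWN)]  # pos via loss, neg via gain
                else:
                    signs = [(LOSS, UP), (GAIN, UP)]  # neg via loss, pos via gain
            else:
                signs = _CELL_SIGNS[cell]
            for contrast, direction in signs:
                add_probe(gene, contrast, direction)
    for i in range(config.n_nonpeak_responders):
        gene = f"npk{i + 1:04d}"
        truth_category[gene] = "POS"
        truth_cell[gene] = "nonpeak"
        add_probe(gene, LOSS, DOWN)
    all_genes = chosen + [f"npk{i + 1:04d}" for i in range(config.n_nonpeak_responders)]
    for _ in range(config.n_decoy_probes):
        gene = all_genes[int(rng.integers(len(all_genes)))]
        direction = UP if rng.random() < 0.5 else DOWN
        contrast = LOSS if rng.random() < 0.5 else GAIN
        add_probe(gene, contrast, direction, significant=False)
    truth = {
        "cells": cells,
        "category_by_gene": truth_category,
        "cell_by_gene": truth_cell,
        "n_peak_responders": need,
        "n_nonpeak_responders": config.n_nonpeak_responders,
    }
    return probes, truth


def simulate_expression(
    gene_ids: Iterable[str], config: SyntheticConfig
) -> tuple[dict[str, float], dict[str, bool]]:
    """Log-uniform expression levels and Bernoulli novel flags per gene."""
    rng = _rng(config, 55)
    lo, hi = config.expression_log10_range
    expression: dict[str, float] = {}
    novel: dict[str, bool] = {}
    for gene in sorted(set(gene_ids)):
        expression[gene] = float(10 ** rng.uniform(lo, hi))
        novel[gene] = bool(rng.random() < config.frac_novel)
    return expression, novel


def simulate_term_map(
    gene_ids: Iterable[str], config: SyntheticConfig
) -> dict[str, set[str]]:
    """Random term->gene annotation drawn without replacement per term."""
    rng = _rng(config, 66)
    pool = sorted(set(gene_ids))
    lo, hi = config.term_size_range
    out: dict[str, set[str]] = {}
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(pool))
        members = rng.choice(len(pool), size=size, replace=False)
        out[f"TERM{t + 1:03d}"] = {pool[int(i)] for i in members}
    return out


def simulate_all(config: SyntheticConfig, outdir) -> dict:
    """Generate and write every synthetic input plus a ground-truth JSON.

    Returns a dict with in-memory objects ('annotation', 'peaks',
    'sequences', 'probes', 'expression', 'novel', 'term_map',
    'assignments', 'truth') and file paths under 'paths'.
    """
    from .target_assignment import assign_peaks_to_genes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth_ann = simulate_annotation(config)
    peaks, truth_peaks = simulate_peaks(annotation, config)
    sequences, truth_seq = simulate_sequences(peaks, config)
    assignments = assign_peaks_to_genes(peaks, annotation)
    peak_genes = sorted({a.gene_id for a in assignments})
    probes, truth_resp = simulate_response_table(config, peak_genes)
    responder_ids = sorted({p.gene_id for p in probes})
    expr_ids = sorted({g.gene_id for g in annotation} | set(responder_ids))
    expression, novel = simulate_expression(expr_ids, config)
    term_map = simulate_term_map([g.gene_id for g in annotation], config)
    paths = {
        "annotation_gff3": outdir / "genes.gff3",
        "annotation_bed": outdir / "genes.bed",
        "peaks_narrowpeak": outdir / "peaks.narrowPeak",
        "peaks_macs": outdir / "peaks_macs.tsv",
        "sequences": outdir / "peak_sequences.fasta",
        "probes": outdir / "probe_responses.tsv",
        "expression": outdir / "expression.tsv",
        "term_map": outdir / "terms.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_gene_annotation(annotation, paths["annotation_gff3"], format="gff3")
    write_gene_annotation(annotation, paths["annotation_bed"], format="bed")
    write_peaks(peaks, paths["peaks_narrowpeak"], dialect="narrowpeak")
    write_peaks(peaks, paths["peaks_macs"], dialect="macs_tab")
    write_fasta(sequences, paths["sequences"])
    write_probe_table(probes, paths["probes"])
    write_expression_table(expression, novel, paths["expression"])
    write_term_map(term_map, paths["term_map"])
    truth = {
        "config": config.to_dict(),
        "annotation": truth_ann,
        "peaks": truth_peaks,
        "sequences": truth_seq,
        "response": truth_resp,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {
        "annotation": annotation,
        "peaks": peaks,
        "sequences": sequences,
        "assignments": assignments,
        "probes": probes,
        "expression": expression,
        "novel": novel,
        "term_map": term_map,
        "truth": truth,
        "paths": {k: str(v) for k, v in paths.items()},
    }
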