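"""Direct-target classification from two expression contrasts.

Candidate direct targets of an activating/repressing transcription
factor are genes that (a) carry a ChIP peak and (b) respond in at least
one of two expression contrasts: a *loss* contrast (factor removed; a
gene that goes down is inferred to be activated by the factor) and a
*gain* contrast (factor overexpressed; a gene that goes up is inferred
to be activated).  Probe-level calls are collapsed to per-gene sign
sets, the inferred regulation directions are pooled over both
contrasts, and each gene is called POS (only activation inferred), NEG
(only repression) or AMB (conflicting inferences -- including genes
whose probes disagree within a single contrast).

The module also provides upper-tail hypergeometric term enrichment with
Benjamini-Hochberg correction, the -log10 geometric-mean cluster
enrichment score (1.3 corresponds to P = 0.05), and the three-criterion
screen-candidate selector (novel gene, assigned peak with P < 1e-20
i.e. score > 200, expression >= 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peak_model import PeakSet
from .target_assignment import Assignment

logger = logging.getLogger(__name__)

POS = "POS"
NEG = "NEG"
AMB = "AMB"
UP = "up"
DOWN = "down"
LOSS = "loss"
GAIN = "gain"

# Inferred regulation: lower expression without the factor, or higher
# expression with extra factor, both imply activation.
_INFERRED = {
    (LOSS, DOWN): "positive",
    (LOSS, UP): "negative",
    (GAIN, UP): "positive",
    (GAIN, DOWN): "negative",
}

__all__ = [
    "POS",
    "NEG",
    "AMB",
    "ProbeResponse",
    "ResponseRecord",
    "RegulatoryCall",
    "ContrastBreakdown",
    "ClassificationSummary",
    "collapse_probes",
    "classify",
    "classify_records",
    "intersect_with_peaks",
    "summarize",
    "hypergeom_enrichment",
    "cluster_enrichment_score",
    "select_screen_candidates",
    "read_probe_table",
    "write_probe_table",
    "write_calls",
    "read_expression_table",
    "write_expression_table",
    "read_term_map",
    "write_term_map",
    "summary_to_text",
]


@dataclass(frozen=True)
class ProbeResponse:
    """One probe's call in one contrast; direction is meaningful only when significant."""

    probe_id: str
    gene_id: str
    contrast: str  # loss | gain
    direction: str  # up | down
    significant: bool

    def __post_init__(self):
        if self.contrast not in (LOSS, GAIN):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.direction not in (UP, DOWN):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class ResponseRecord:
    """Per-gene union of significant probe directions in each contrast."""

    gene_id: str
    loss_signs: frozenset[str]
    gain_signs: frozenset[str]

    @property
    def responds(self) -> bool:
        return bool(self.loss_signs or self.gain_signs)


@dataclass(frozen=True)
class RegulatoryCall:
    gene_id: str
    category: str  # POS | NEG | AMB
    has_peak: bool = False

    def __post_init__(self):
        if self.category not in (POS, NEG, AMB):
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class ContrastBreakdown:
    """Within one category: genes responding in loss, in gain, and in both."""

    n_loss: int
    n_gain: int
    n_both: int
    pct_both: float


@dataclass(frozen=True)
class ClassificationSummary:
    total: int
    n_pos: int
    n_neg: int
    n_amb: int
    pct_pos: float
    pct_neg: float
    pct_amb: float
    n_loss: int
    n_gain: int
    n_both: int
    pct_both: float
    pos_breakdown: ContrastBreakdown
    neg_breakdown: ContrastBreakdown


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-away-from-zero to one decimal (57.777.. -> 57.8)."""
    if denominator == 0:
        raise ValueError("percentage with zero denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def collapse_probes(responses: Iterable[ProbeResponse]) -> list[ResponseRecord]:
    """Union significant probe directions per gene and contrast.

    Genes with no significant probe in either contrast are dropped.  A
    gene with significant up- and down-probes in the same contrast keeps
    both directions (and will classify as AMB).
    """
    signs: dict[str, dict[str, set[str]]] = {}
    for r in responses:
        if not r.significant:
            continue
        if not r.gene_id:
            raise ValueError(f"significant probe {r.probe_id!r} lacks a gene_id")
        gene = signs.setdefault(r.gene_id, {LOSS: set(), GAIN: set()})
        gene[r.contrast].add(r.direction)
    return [
        ResponseRecord(
            gene_id=g,
            loss_signs=frozenset(signs[g][LOSS]),
            gain_signs=frozenset(signs[g][GAIN]),
        )
        for g in sorted(signs)
    ]


def classify(record: ResponseRecord) -> RegulatoryCall:
    """POS/NEG/AMB call from the union of inferred regulation directions."""
    inferred = {_INFERRED[(LOSS, d)] for d in record.loss_signs}
    inferred |= {_INFERRED[(GAIN, d)] for d in record.gain_signs}
    if not inferred:
        raise ValueError(f"gene {record.gene_id}: no significant response in either contrast")
    if inferred == {"positive"}:
        category = POS
    elif inferred == {"negative"}:
        category = NEG
    else:
        category = AMB
    return RegulatoryCall(gene_id=record.gene_id, category=category)


def classify_records(records: Iterable[ResponseRecord]) -> list[RegulatoryCall]:
    return [classify(r) for r in records]


def intersect_with_peaks(
    calls: Iterable[RegulatoryCall], assignments: Iterable[Assignment]
) -> list[RegulatoryCall]:
    """Flag calls whose gene carries any peak assignment (overlap or nearest)."""
    peak_genes = {a.gene_id for a in assignments}
    return [
        RegulatoryCall(c.gene_id, c.category, has_peak=c.gene_id in peak_genes)
        for c in calls
    ]


def summarize(
    calls: Iterable[RegulatoryCall], records: Iterable[ResponseRecord]
) -> ClassificationSummary:
    """Count categories and contrast margins over peak-bearing genes.

    Satisfies the partition (POS + NEG + AMB = total) and the
    inclusion-exclusion identity (loss + gain - both = total), overall
    and within the POS-only and NEG-only breakdowns.
    """
    calls = [c for c in calls if c.has_peak]
    if not calls:
        raise ValueError("no peak-bearing classified genes to summarise")
    by_gene = {r.gene_id: r for r in records}
    category = {c.gene_id: c.category for c in calls}
    n_pos = sum(1 for c in calls if c.category == POS)
    n_neg = sum(1 for c in calls if c.category == NEG)
    n_amb = sum(1 for c in calls if c.category == AMB)
    total = len(calls)

    def margins(genes: Iterable[str]) -> tuple[int, int, int]:
        n_loss = n_gain = n_both = 0
        for g in genes:
            rec = by_gene.get(g)
            if rec is None:
                raise ValueError(f"classified gene {g!r} has no response record")
            in_loss = bool(rec.loss_signs)
            in_gain = bool(rec.gain_signs)
            n_loss += in_loss
            n_gain += in_gain
            n_both += in_loss and in_gain
        return n_loss, n_gain, n_both

    all_loss, all_gain, all_both = margins(category)
    pos_genes = [g for g, cat in category.items() if cat == POS]
    neg_genes = [g for g, cat in category.items() if cat == NEG]
    pos_l, pos_g, pos_b = margins(pos_genes)
    neg_l, neg_g, neg_b = margins(neg_genes)
    return ClassificationSummary(
        total=total,
        n_pos=n_pos,
        n_neg=n_neg,
        n_amb=n_amb,
        pct_pos=round_pct(n_pos, total),
        pct_neg=round_pct(n_neg, total),
        pct_amb=round_pct(n_amb, total),
        n_loss=all_loss,
        n_gain=all_gain,
        n_both=all_both,
        pct_both=round_pct(all_both, total),
        pos_breakdown=ContrastBreakdown(
            pos_l, pos_g, pos_b, round_pct(pos_b, n_pos) if n_pos else 0.0
        ),
        neg_breakdown=ContrastBreakdown(
            neg_l, neg_g, neg_b, round_pct(neg_b, n_neg) if n_neg else 0.0
        ),
    )


def hypergeom_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the foreground.

    For a term with K background genes, a foreground of size n drawn
    from N background genes, and k foreground genes in the term, the
    P-value is P(X >= k) with X ~ Hypergeom(N, K, n).  Term gene sets
    are intersected with the background first.  Returns a DataFrame with
    columns term, k, K, n, N, p_value, q_value (Benjamini-Hochberg),
    sorted by p_value then term.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        extra = sorted(fg - bg)[:5]
        raise ValueError(f"foreground is not a subset of background (e.g. {extra})")
    n, N = len(fg), len(bg)
    rows = []
    for term in sorted(term_map):
        term_genes = set(term_map[term]) & bg
        K = len(term_genes)
        k = len(term_genes & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value"])
    if len(df):
        df["q_value"] = stats.false_discovery_control(df["p_value"].to_numpy())
    else:
        df["q_value"] = []
    return df.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)


def cluster_enrichment_score(term_p_values: Sequence[float]) -> float:
    """-log10 of the geometric mean of member-term P-values.

    A cluster of terms all at P = 0.05 scores ~1.301, hence the
    conventional 1.3 cut-off for 'significant' clusters.
    """
    ps = np.asarray(list(term_p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("empty p-value list")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-np.mean(np.log10(ps)))


def select_screen_candidates(
    assignments: Iterable[Assignment],
    peaks: PeakSet,
    expression: Mapping[str, float],
    novel: Mapping[str, bool],
    min_peak_score: float = 200.0,
    min_expression: float = 10.0,
) -> list[str]:
    """Genes meeting all three screen criteria, sorted by gene_id.

    1. the gene is flagged novel (no reported role in the tissue);
    2. an assigned peak has score strictly above ``min_peak_score``
       (score > 200 means P < 1e-20);
    3. expression is at or above ``min_expression`` (boundary kept).

    Genes absent from the expression map are treated as not expressed
    and logged.
    """
    score_by_peak = {p.peak_id: p.score for p in peaks}
    best_score: dict[str, float] = {}
    for a in assignments:
        score = score_by_peak.get(a.peak_id)
        if score is None:
            continue
        best_score[a.gene_id] = max(best_score.get(a.gene_id, 0.0), score)
    selected = []
    for gene, score in best_score.items():
        if not novel.get(gene, False):
            continue
        if not score > min_peak_score:
            continue
        if gene not in expression:
            logger.warning("gene %s missing from expression map; treated as not expressed", gene)
            continue
        if expression[gene] >= min_expression:
            selected.append(gene)
    return sorted(selected)


# ---------------------------------------------------------------------------
# I/O


def read_probe_table(path) -> list[ProbeResponse]:
    """TSV with columns PROBE, GENE, CONTRAST (loss|gain), DIRECTION (up|down), SIG (0|1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"PROBE", "GENE", "CONTRAST", "DIRECTION", "SIG"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ProbeResponse(
            probe_id=row.PROBE,
            gene_id=row.GENE,
            contrast=row.CONTRAST,
            direction=row.DIRECTION,
            significant=row.SIG == "1",
        )
        for row in df.itertuples()
    ]


def write_probe_table(responses: Iterable[ProbeResponse], path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("PROBE\tGENE\tCONTRAST\tDIRECTION\tSIG\n")
        for r in responses:
            fh.write(
                f"{r.probe_id}\t{r.gene_id}\t{r.contrast}\t{r.direction}\t"
                f"{1 if r.significant else 0}\n"
            )


def _signs_str(signs: frozenset[str]) -> str:
    return "+".join(sorted(signs)) if signs else "."


def write_calls(
    calls: Iterable[RegulatoryCall],
    records: Iterable[ResponseRecord],
    path,
) -> None:
    """TSV mirroring the per-gene call table: GENE, CATEGORY, LOSS_SIGNS, GAIN_SIGNS, HAS_PEAK."""
    by_gene = {r.gene_id: r for r in records}
    with open(Path(path), "w") as fh:
        fh.write("GENE\tCATEGORY\tLOSS_SIGNS\tGAIN_SIGNS\tHAS_PEAK\n")
        for c in sorted(calls, key=lambda c: c.gene_id):
            rec = by_gene[c.gene_id]
            fh.write(
                f"{c.gene_id}\t{c.category}\t{_signs_str(rec.loss_signs)}\t"
                f"{_signs_str(rec.gain_signs)}\t{1 if c.has_peak else 0}\n"
            )


def read_expression_table(path) -> tuple[dict[str, float], dict[str, bool]]:
    """TSV with columns GENE, EXPRESSION and optional NOVEL (0|1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if "GENE" not in df.columns or "EXPRESSION" not in df.columns:
        raise ValueError(f"{path}: expected columns GENE and EXPRESSION")
    expr = dict(zip(df["GENE"].astype(str), df["EXPRESSION"].astype(float)))
    novel = (
        dict(zip(df["GENE"].astype(str), df["NOVEL"].astype(int) == 1))
        if "NOVEL" in df.columns
        else {}
    )
    return expr, novel


def write_expression_table(
    expression: Mapping[str, float], novel: Mapping[str, bool], path
) -> None:
    with open(Path(path), "w") as fh:
        fh.write("GENE\tEXPRESSION\tNOVEL\n")
        for gene in sorted(expression):
            fh.write(
                f"{gene}\t{expression[gene]:.6g}\t{1 if novel.get(gene, False) else 0}\n"
            )


def read_term_map(path) -> dict[str, set[str]]:
    """TSV with columns TERM, GENE; one row per term-gene pair."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "TERM" not in df.columns or "GENE" not in df.columns:
        raise ValueError(f"{path}: expected columns TERM and GENE")
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["TERM"], df["GENE"]):
        out.setdefault(term, set()).add(gene)
    return out


def write_term_map(term_map: Mapping[str, Iterable[str]], path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("TERM\tGENE\n")
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{term}\t{gene}\n")


def summary_to_text(s: ClassificationSummary) -> str:
    return "\n".join(
        [
            f"classified peak-bearing genes: {s.total}",
            f"  POS {s.n_pos} ({s.pct_pos}%)  NEG {s.n_neg} ({s.pct_neg}%)  "
            f"AMB {s.n_amb} ({s.pct_amb}%)",
            f"  respond to loss: {s.n_loss}  to gain: {s.n_gain}  "
            f"to both: {s.n_both} ({s.pct_both}%)",
            f"  POS breakdown: loss {s.pos_breakdown.n_loss}, gain {s.pos_breakdown.n_gain}, "
            f"both {s.pos_breakdown.n_both} ({s.pos_breakdown.pct_both}% of POS)",
            f"  NEG breakdown: loss {s.neg_breakdown.n_loss}, gain {s.neg_breakdown.n_gain}, "
            f"both {s.neg_breakdown.n_both} ({s.neg_breakdown.pct_both}% of NEG)",
        ]
    )
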