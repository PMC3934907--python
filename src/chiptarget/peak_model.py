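"""Scored ChIP-seq peaks under the MACS score convention.

Peak significance is carried as ``score = -10 * log10(P)``: score 50 is
P = 1e-5, score 640 is P = 1e-64.  Peaks are filtered on score and fold
enrichment, ranked so that index 1 is the most significant peak, and top
quantiles are selected by the ceiling rule (top 10% of 7,566 peaks is
757 peaks).

I/O dialects: ENCODE narrowPeak (0-based half-open, column 8 holds
-log10 P, converted to the -10*log10 scale by x10) and a MACS-style tab
table (1-based inclusive start, converted on read).  The annotated peak
table writer emits one row per peak-gene link with the columns INDEX,
PVALUE, CHR, START, END, GENE, GENE_STATUS, GENE_DIS, TSS_GENE, TSS_DIS,
where PVALUE holds the -10*log10(P) score and START/END are written
1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .target_assignment import Assignment

__all__ = [
    "Peak",
    "PeakSet",
    "PeakError",
    "PeakParseError",
    "score_from_p",
    "p_from_score",
    "filter_peaks",
    "rank_and_index",
    "select_top_fraction",
    "read_peaks",
    "write_peaks",
    "write_peak_table",
    "PEAK_TABLE_COLUMNS",
]

PEAK_TABLE_COLUMNS = (
    "INDEX",
    "PVALUE",
    "CHR",
    "START",
    "END",
    "GENE",
    "GENE_STATUS",
    "GENE_DIS",
    "TSS_GENE",
    "TSS_DIS",
)


class PeakError(ValueError):
    """Invalid peak content."""


class PeakParseError(PeakError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class Peak:
    """A scored genomic interval (0-based half-open) with fold enrichment."""

    peak_id: str
    chrom: str
    start: int
    end: int
    score: float  # -10 * log10(P), >= 0
    fold: float  # fold enrichment, > 0
    index: int | None = None  # 1 = most significant, set by rank_and_index

    def __post_init__(self):
        if self.start < 0:
            raise PeakError(f"peak {self.peak_id}: negative start {self.start}")
        if self.start >= self.end:
            raise PeakError(
                f"peak {self.peak_id}: start {self.start} must be < end {self.end}"
            )
        if self.score < 0:
            raise PeakError(f"peak {self.peak_id}: negative score {self.score}")
        if self.fold <= 0:
            raise PeakError(f"peak {self.peak_id}: fold must be > 0, got {self.fold}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """A collection of peaks with unique ids."""

    peaks: list[Peak]
    provenance: str = ""

    def __post_init__(self):
        seen: set[str] = set()
        for p in self.peaks:
            if p.peak_id in seen:
                raise PeakError(f"duplicate peak_id {p.peak_id!r}")
            seen.add(p.peak_id)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_id(self) -> dict[str, Peak]:
        return {p.peak_id: p for p in self.peaks}

    @property
    def is_indexed(self) -> bool:
        return bool(self.peaks) and all(p.index is not None for p in self.peaks)


def score_from_p(p: float) -> float:
    """Convert a P-value to the -10*log10(P) score (1e-5 -> 50)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"P-value must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def p_from_score(score: float) -> float:
    """Convert a -10*log10(P) score back to a P-value (50 -> 1e-5)."""
    if score < 0:
        raise ValueError(f"score must be >= 0, got {score}")
    return 10.0 ** (-score / 10.0)


def filter_peaks(peaks: PeakSet, min_score: float = 50.0, min_fold: float = 3.0) -> PeakSet:
    """Keep peaks with score >= min_score and fold >= min_fold.

    Boundary values pass: a peak at exactly P = 1e-5 (score 50) or fold 3
    is kept.  Input order is preserved and the input set is unmodified.
    """
    kept = [p for p in peaks if p.score >= min_score and p.fold >= min_fold]
    return PeakSet(
        peaks=kept,
        provenance=f"{peaks.provenance} | filter(score>={min_score}, fold>={min_fold})".strip(" |"),
    )


def rank_and_index(peaks: PeakSet) -> PeakSet:
    """Sort by descending score and assign index 1..N (1 = most significant).

    Score ties break deterministically by (chrom, start, peak_id).
    """
    if len(peaks) == 0:
        raise PeakError("cannot rank an empty peak set")
    ordered = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start, p.peak_id))
    indexed = [replace(p, index=i) for i, p in enumerate(ordered, 1)]
    return PeakSet(peaks=indexed, provenance=peaks.provenance)


def select_top_fraction(peaks: PeakSet, fraction: float) -> PeakSet:
    """Select the ceil(fraction * N) peaks with the smallest index."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not peaks.is_indexed:
        raise PeakError("select_top_fraction requires an indexed peak set")
    k = math.ceil(fraction * len(peaks))
    ordered = sorted(peaks, key=lambda p: p.index)
    return PeakSet(
        peaks=ordered[:k],
        provenance=f"{peaks.provenance} | top {fraction:g}".strip(" |"),
    )


def read_peaks(path, dialect: str, default_fold: float | None = None) -> PeakSet:
    """Read a peak table in ``narrowpeak`` or ``macs_tab`` dialect.

    narrowPeak: BED6+4; column 7 is fold enrichment (-1 means missing,
    which errors unless ``default_fold`` is given) and column 8 is
    -log10(P), converted to the -10*log10 score by multiplying by 10.

    macs_tab: tab-separated chrom, start, end, score, fold [, name] with
    a 1-based inclusive start that is converted to 0-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "narrowpeak":
        peaks = _read_narrowpeak(path, default_fold)
    elif dialect == "macs_tab":
        peaks = _read_macs_tab(path)
    else:
        raise PeakError(f"unknown peak dialect {dialect!r}")
    return PeakSet(peaks=peaks, provenance=f"read {path.name} ({dialect})")


def _float_field(path, lineno, value, label) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise PeakParseError(path, lineno, f"non-numeric {label}: {value!r}") from exc


def _read_narrowpeak(path: Path, default_fold: float | None) -> list[Peak]:
    peaks: list[Peak] = []
    n = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise PeakParseError(
                    path, lineno, f"narrowPeak needs 10 fields, got {len(fields)}"
                )
            n += 1
            start, end = int(fields[1]), int(fields[2])
            if start < 0:
                raise PeakParseError(path, lineno, f"negative start {start}")
            fold = _float_field(path, lineno, fields[6], "signalValue")
            if fold <= 0:
                if default_fold is None:
                    raise PeakParseError(
                        path,
                        lineno,
                        "missing fold enrichment (signalValue <= 0) and no default_fold",
                    )
                fold = default_fold
            neglog10p = _float_field(path, lineno, fields[7], "pValue")
            if neglog10p < 0:
                raise PeakParseError(path, lineno, "missing pValue (-1) in narrowPeak")
            name = fields[3] if fields[3] not in {".", ""} else f"peak_{n}"
            try:
                peaks.append(
                    Peak(
                        peak_id=name,
                        chrom=fields[0],
                        start=start,
                        end=end,
                        score=neglog10p * 10.0,  # -log10 P -> -10*log10 P
                        fold=fold,
                    )
                )
            except PeakError as exc:
                raise PeakParseError(path, lineno, str(exc)) from exc
    return peaks


def _read_macs_tab(path: Path) -> list[Peak]:
    peaks: list[Peak] = []
    n = 0
    header_skipped = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise PeakParseError(
                    path, lineno, f"macs_tab needs >= 5 fields, got {len(fields)}"
                )
            if not header_skipped:
                header_skipped = True
                try:
                    int(fields[1])
                except ValueError:
                    continue  # column-header line
            n += 1
            try:
                start1, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PeakParseError(path, lineno, f"non-integer coordinate: {exc}") from exc
            if start1 < 1:
                raise PeakParseError(path, lineno, f"1-based start must be >= 1, got {start1}")
            score = _float_field(path, lineno, fields[3], "score")
            fold = _float_field(path, lineno, fields[4], "fold")
            name = fields[5] if len(fields) > 5 and fields[5] else f"peak_{n}"
            try:
                peaks.append(
                    Peak(
                        peak_id=name,
                        chrom=fields[0],
                        start=start1 - 1,  # 1-based inclusive -> 0-based
                        end=end,
                        score=score,
                        fold=fold,
                    )
                )
            except PeakError as exc:
                raise PeakParseError(path, lineno, str(exc)) from exc
    return peaks


def write_peaks(peaks: PeakSet, path, dialect: str) -> None:
    """Write peaks in ``narrowpeak`` or ``macs_tab`` dialect (read_peaks inverse)."""
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "narrowpeak":
            for p in peaks:
                display = min(1000, int(round(p.score)))
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{display}\t.\t"
                    f"{p.fold!r}\t{p.score / 10.0!r}\t-1\t-1\n"
                )
        elif dialect == "macs_tab":
            fh.write("chrom\tstart\tend\tscore\tfold\tname\n")
            for p in peaks:
                fh.write(
                    f"{p.chrom}\t{p.start + 1}\t{p.end}\t{p.score!r}\t{p.fold!r}\t{p.peak_id}\n"
                )
        else:
            raise PeakError(f"unknown peak dialect {dialect!r}")


def write_peak_table(peaks: PeakSet, assignments: Iterable["Assignment"], path) -> None:
    """Write the annotated peak table: one row per peak-gene link.

    Rows are ordered by INDEX then GENE.  GENE_DIS is 0 for GENE_OVERLAP
    rows; TSS_GENE may differ from GENE since the nearest TSS can belong
    to a different gene than the assigned one.  Peaks with no assignment
    (e.g. on a chromosome absent from the annotation) are omitted.
    """
    if not peaks.is_indexed:
        raise PeakError("write_peak_table requires an indexed peak set")
    by_id = peaks.by_id()
    rows = []
    for a in assignments:
        peak = by_id.get(a.peak_id)
        if peak is None:
            raise PeakError(f"assignment refers to unknown peak {a.peak_id!r}")
        rows.append(
            (
                peak.index,
                a.gene_id,
                (
                    f"{peak.index}\t{peak.score:g}\t{peak.chrom}\t{peak.start + 1}\t"
                    f"{peak.end}\t{a.gene_id}\t{a.status}\t{a.gene_distance}\t"
                    f"{a.tss_gene_id}\t{a.tss_distance}"
                ),
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(Path(path), "w") as fh:
        fh.write("\t".join(PEAK_TABLE_COLUMNS) + "\n")
        for _, _, line in rows:
            fh.write(line + "\n")
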