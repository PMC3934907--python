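"""Degenerate IUPAC consensus scanning over peak sequences.

Motifs are IUPAC consensus strings (e.g. AGATAC, STTWTCA with S=C/G and
W=A/T) scanned on both strands.  The headline statistic is the fraction
of peaks containing at least one occurrence of the motif; enrichment is
judged against per-sequence mononucleotide shuffles, which preserve base
composition exactly (an optional dinucleotide shuffle preserves
dinucleotide counts as well).

Conventions: an ambiguous N base in a *sequence* matches no motif
position; a motif that equals its own reverse complement (as a set of
per-position base sets, e.g. TATCGATA) reports one hit per offset rather
than one per strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "IUPACMotif",
    "MotifSummary",
    "IUPAC_CODES",
    "expand_iupac",
    "reverse_complement",
    "scan_sequence",
    "peak_hit_fraction",
    "shuffle_enrichment",
    "builtin_motifs",
    "mononucleotide_shuffle",
    "dinucleotide_shuffle",
    "read_fasta",
    "write_fasta",
    "write_motif_table",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def expand_iupac(code: str) -> frozenset[str]:
    """The set of concrete bases an IUPAC code stands for (Y -> {C, T})."""
    try:
        return IUPAC_CODES[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None


def reverse_complement(consensus: str) -> str:
    """Reverse complement of an IUPAC consensus (YGATAY -> RTATCR)."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(consensus.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None


@dataclass(frozen=True)
class IUPACMotif:
    """A named degenerate consensus, length >= 4."""

    name: str
    consensus: str

    def __post_init__(self):
        cons = self.consensus.upper()
        object.__setattr__(self, "consensus", cons)
        if len(cons) < 4:
            raise ValueError(f"motif {self.name!r}: consensus must be >= 4 long")
        for c in cons:
            if c not in IUPAC_CODES:
                raise ValueError(f"motif {self.name!r}: invalid IUPAC code {c!r}")

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def is_palindromic(self) -> bool:
        """True when the motif equals its reverse complement as base sets."""
        rc = reverse_complement(self.consensus)
        return all(
            IUPAC_CODES[a] == IUPAC_CODES[b] for a, b in zip(self.consensus, rc)
        )

    def regex(self, strand: str = "+") -> re.Pattern:
        cons = self.consensus if strand == "+" else reverse_complement(self.consensus)
        parts = []
        for c in cons:
            bases = sorted(IUPAC_CODES[c])
            parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
        return re.compile("".join(parts))


@dataclass
class MotifSummary:
    """Per-motif occurrence statistics over a set of peak sequences."""

    motif: IUPACMotif
    n_peaks: int
    n_with_hit: int
    fraction: float
    background_fraction: float | None = None
    enrichment_ratio: float | None = None
    empirical_p: float | None = None


def scan_sequence(
    seq: str, motif: IUPACMotif, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All (offset, strand) occurrences of the motif in ``seq``.

    Overlapping occurrences are all reported.  Offsets are 0-based
    positions on the forward sequence for both strands.  A motif longer
    than the sequence yields an empty list.  For a palindromic motif
    each offset is reported once, on the forward strand.
    """
    seq = seq.upper()
    hits: list[tuple[int, str]] = []
    fwd = re.compile(f"(?=({motif.regex('+').pattern}))")
    for m in fwd.finditer(seq):
        hits.append((m.start(), "+"))
    if both_strands and not motif.is_palindromic:
        rev = re.compile(f"(?=({motif.regex('-').pattern}))")
        for m in rev.finditer(seq):
            hits.append((m.start(), "-"))
    hits.sort()
    return hits


def _has_hit(seq: str, fwd: re.Pattern, rev: re.Pattern | None) -> bool:
    if fwd.search(seq):
        return True
    return rev is not None and rev.search(seq) is not None


def _hit_patterns(motif: IUPACMotif, both_strands: bool = True):
    fwd = motif.regex("+")
    rev = motif.regex("-") if both_strands and not motif.is_palindromic else None
    return fwd, rev


def peak_hit_fraction(sequences: Mapping[str, str], motif: IUPACMotif) -> MotifSummary:
    """Fraction of peaks with at least one motif occurrence on either strand."""
    if not sequences:
        raise ValueError("empty sequence set")
    fwd, rev = _hit_patterns(motif)
    n_hit = sum(1 for s in sequences.values() if _has_hit(s.upper(), fwd, rev))
    return MotifSummary(
        motif=motif,
        n_peaks=len(sequences),
        n_with_hit=n_hit,
        fraction=n_hit / len(sequences),
    )


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random permutation of the sequence; base composition is preserved."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode()


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 2000) -> str:
    """Shuffle preserving dinucleotide counts (random Eulerian rewiring).

    Successor lists are permuted and a walk from the original first base
    is attempted; walks that strand part of the edge multiset are
    rejected and retried.
    """
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        succ: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            succ.setdefault(a, []).append(b)
        for key in succ:
            succ[key] = list(rng.permutation(succ[key]))
        pos = {key: 0 for key in succ}
        out = [seq[0]]
        cur = seq[0]
        for _ in range(len(seq) - 1):
            lst = succ.get(cur)
            if lst is None or pos[cur] >= len(lst):
                break
            nxt = lst[pos[cur]]
            pos[cur] += 1
            out.append(nxt)
            cur = nxt
        if len(out) == len(seq):
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian ordering")


def shuffle_enrichment(
    sequences: Mapping[str, str],
    motif: IUPACMotif,
    n_shuffles: int = 99,
    seed: int = 0,
    method: str = "mono",
) -> MotifSummary:
    """Motif enrichment versus a per-sequence shuffle background.

    ``background_fraction`` is the mean hit fraction over ``n_shuffles``
    rounds of shuffling every sequence; ``empirical_p`` is the add-one
    rank of the observed fraction among the shuffled rounds,
    (1 + #{rounds >= observed}) / (n_shuffles + 1).  A zero background
    with a positive foreground reports an infinite enrichment ratio.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if method not in {"mono", "dinuc"}:
        raise ValueError(f"unknown shuffle method {method!r}")
    observed = peak_hit_fraction(sequences, motif)
    fwd, rev = _hit_patterns(motif)
    rng = np.random.default_rng(seed)
    shuffle = mononucleotide_shuffle if method == "mono" else dinucleotide_shuffle
    upper = {k: v.upper() for k, v in sorted(sequences.items())}
    fractions = np.empty(n_shuffles)
    for r in range(n_shuffles):
        n_hit = sum(
            1 for s in upper.values() if _has_hit(shuffle(s, rng), fwd, rev)
        )
        fractions[r] = n_hit / len(upper)
    bg = float(fractions.mean())
    if bg > 0:
        ratio = observed.fraction / bg
    else:
        ratio = float("inf") if observed.fraction > 0 else 0.0
    emp_p = (1 + int((fractions >= observed.fraction).sum())) / (n_shuffles + 1)
    return MotifSummary(
        motif=motif,
        n_peaks=observed.n_peaks,
        n_with_hit=observed.n_with_hit,
        fraction=observed.fraction,
        background_fraction=bg,
        enrichment_ratio=ratio,
        empirical_p=emp_p,
    )


def builtin_motifs() -> list[IUPACMotif]:
    """The consensus motifs enriched in eye-disc So binding regions.

    AGATAC is the empirically enriched So-like motif and YGATAY the
    published So consensus; the rest are binding motifs of candidate
    co-regulators active in the eye disc.
    """
    return [
        IUPACMotif("So", "AGATAC"),
        IUPACMotif("So-consensus", "YGATAY"),
        IUPACMotif("Optix", "STTWTCA"),
        IUPACMotif("Iro-C", "AACAYAA"),
        IUPACMotif("DRE", "TATCGATA"),
        IUPACMotif("Trl", "AGAGMGMG"),
        IUPACMotif("Hr78/Usp", "CGGTCACACTG"),
        IUPACMotif("Abd-B/Cad/Hb-class", "ATTTKTA"),
    ]


def read_fasta(path) -> dict[str, str]:
    """Read peak sequences keyed by record id."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        out[record.id] = str(record.seq)
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(Path(path), "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_motif_table(summaries: Iterable[MotifSummary], path) -> None:
    """TSV: MOTIF, CONSENSUS, N_PEAKS, N_WITH_HIT, FRACTION, BG_FRACTION, RATIO, EMP_P."""
    with open(Path(path), "w") as fh:
        fh.write("MOTIF\tCONSENSUS\tN_PEAKS\tN_WITH_HIT\tFRACTION\tBG_FRACTION\tRATIO\tEMP_P\n")
        for s in summaries:
            bg = "" if s.background_fraction is None else f"{s.background_fraction:.6g}"
            ratio = "" if s.enrichment_ratio is None else f"{s.enrichment_ratio:.6g}"
            emp = "" if s.empirical_p is None else f"{s.empirical_p:.6g}"
            fh.write(
                f"{s.motif.name}\t{s.motif.consensus}\t{s.n_peaks}\t{s.n_with_hit}\t"
                f"{s.fraction:.6g}\t{bg}\t{ratio}\t{emp}\n"
            )
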