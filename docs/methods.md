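# Methods

## Coordinate and score conventions

All intervals are 0-based half-open internally; GFF3/GTF input
(1-based inclusive) and the annotated peak-table output (1-based
inclusive START/END) convert exactly once at the I/O boundary. Peak
significance is the MACS convention `score = -10·log₁₀(P)`; the
annotated table's PVALUE column carries this score, not the raw
P-value. Conversions are exact inverses to 1e-12 relative tolerance
over P ∈ [1e-300, 1].

Filtering keeps `score ≥ 50` **and** `fold ≥ 3`; both boundaries are
inclusive, reading the exclusion rule ("P larger than 1e-5", "fold
less than 3") literally. Ranking sorts by descending score with the
deterministic tie-break (chrom, start, peak_id); top quantiles use
`k = ceil(fraction · N)`, which is what makes the top decile of 7,566
peaks exactly 757.

## Peak→gene assignment

A peak is assigned to *every* gene span it partially overlaps
(`GENE_OVERLAP`, distance 0); gene extent is the annotated gene
feature including UTRs and introns, and strand is ignored for
overlap. A peak with no overlap is assigned to the gene(s) minimising
the half-open edge gap on either side; exact ties assign all tied
genes, ordered by gene_id, to avoid a directional bias. A consequence
of the half-open gap is that a gene *abutting* a peak is GENE_CLOSE
at distance 0; we accept this degenerate case rather than introduce a
±1 adjustment that would break the published distance example
arithmetic.

Nearest-TSS distance is measured from the nearest peak edge (0 when
the TSS is inside the peak), not from the summit or midpoint: the
binned statement "x% of peaks < 1 kb from a TSS" reads most naturally
as edge distance, and no summit column is required. The TSS of a gene
is `start` (+) or `end − 1` (−). Distance bins are half-open
upward — 1,000 bp belongs to the 1–5 kb bin — because the headline bin
is "< 1 kb".

Positional queries use an interval tree (overlap) and sorted arrays
with binary search (nearest edge, nearest TSS); both are checked
against exhaustive linear-scan oracles in the tests.

## Motif scanning

Motifs are IUPAC consensus strings scanned by compiled regular
expressions with a look-ahead so overlapping occurrences are all
found; the reverse strand is scanned with the reverse-complement
pattern on the forward sequence. An `N` in a *sequence* matches no
motif position (conservative). A motif equal to its own reverse
complement as per-position base sets (e.g. TATCGATA) reports one hit
per offset: "at least one occurrence" is unaffected and per-offset
uniqueness is the least surprising contract.

The background model is a per-sequence mononucleotide shuffle, which
preserves base composition exactly; the enrichment ratio is observed
over mean-shuffled hit fraction and the empirical P-value is add-one:
`(1 + #{rounds ≥ observed}) / (n_shuffles + 1)`. A dinucleotide-
preserving shuffle (random Eulerian rewiring with rejection) is
available via `method="dinuc"` for sequences where CpG-like
composition matters. Known-motif scanning deliberately replaces de
novo discovery: the deliverable statistic is the fraction of peaks
containing a motif, which known-motif scanning specifies completely.

## Target classification

Per gene and contrast we keep the *union* of significant probe
directions. Inference: loss-down ⇒ activated, loss-up ⇒ repressed,
gain-up ⇒ activated, gain-down ⇒ repressed. Pooling over both
contrasts: {activated} ⇒ POS, {repressed} ⇒ NEG, both ⇒ AMB. Genes
whose probes disagree *within* one contrast (distinct isoform-level
probes moving in opposite directions) therefore land in AMB through
the same rule — the one uniform treatment that needs no special case.

Percentages are rounded half-away-from-zero to one decimal (the
convention that reproduces every published figure, e.g. 33/468 =
7.0513 → 7.1). Category percentages are over the classified total;
the both-contrast percentages within POS and NEG are over the
category counts.

Term enrichment is a plain upper-tail hypergeometric test per term
with Benjamini–Hochberg correction across terms — not a reimplementation
of DAVID's EASE/clustering machinery, which is out of scope; the
cluster score `-log₁₀(geometric mean of member P-values)` is kept so
the conventional 1.3 ⇔ 0.05 threshold applies. Screen-candidate
selection is strict on the peak score (score > 200, from "P < 1e-20")
and inclusive on expression (≥ 10); genes missing from the expression
table count as not expressed and are logged.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: 7,566 peaks of
width ~N(1000, 250²) truncated at 100 bp; scores log-uniform on
[50, 650] and folds on [3, 60]; TSS-distance bin targets
(0.524, 0.167, 0.098, 0.103, 0.108) — the first, third (via the ≤10 kb
cumulative 78.9%) and last bins are stated, the 10–20 kb bin takes the
remainder so the vector sums to 1; intragenic fraction 0.847; one
planted motif (AGATAC in 40% of peaks, a typical ChIP hit rate for the
profiled factor); response marginals (460, 444, 94) with category
targets (468, 290, 52) and both-contrast breakdowns (257, 244, 33) and
(151, 149, 10).

Geometry is deliberately sparse: intergenic gaps are drawn from
[95, 140] kb, larger than `2·max_tss_distance + peak width`, so a peak
placed at distance *d* from its gene's TSS (inside the gene body for
intragenic peaks, upstream for intergenic ones) is *exactly* at
distance *d* from the nearest TSS, and its planted intragenic flag is
realised exactly. Parameter-recovery tests therefore fight only
multinomial/binomial sampling noise (±0.01 at n = 10,000 bins, ±0.02
at n = 2,000 for the intragenic fraction). Real genomes are not
sparse — nested genes, shared promoters and peak-spanning loci all
occur — so passing recovery here validates the pipeline's arithmetic,
not its behaviour on dense annotation. An `overlap_fraction` knob
plants nested gene pairs to exercise multi-gene assignment, at the
cost of the exactness guarantee.

The response table satisfies its targets *by construction*: the nine
disjoint cells (category × contrast pattern) are solved from the
marginal and breakdown targets — for the defaults this forces 51
cross-contrast ambiguous genes, 1 loss-only dual-direction gene, and 0
gain-only — and genes are dealt into cells after a seeded shuffle.
Infeasible targets raise a `FeasibilityError` rather than being
silently adjusted. Microarray intensity modelling, probe noise, and
the differential-expression testing itself are out of scope: the
generator emits the *output* of that upstream analysis (probe
direction + significance flags) plus non-significant decoy probes.

All generators are pure functions of the configuration (which carries
the seed, expanded into independent named streams); outputs are
byte-identical across runs.

## Problem sizes and runtimes

The default test suite runs the full 7,566-peak pipeline once
(seconds), a 10,000-peak run for bin recovery, and keeps motif
shuffle backgrounds at 9–99 rounds; the whole suite finishes in a few
seconds on one core. `scripts/acceptance.py` uses the full default
conditions end to end (~4 s).

## Known limitations

- Isoform-level TSSs are not modelled; one TSS per gene.
- Chromosome names match by exact string equality; no "chr" prefix
  normalisation.
- The empirical motif P-value resolution is bounded by
  `1/(n_shuffles+1)`.
- `GENE_CLOSE` at distance 0 for abutting genes (see above).
- The enrichment module reports raw and BH-corrected hypergeometric
  P-values; it is not an emulation of DAVID's modified Fisher/EASE
  score, so numeric agreement with DAVID output is not expected.
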