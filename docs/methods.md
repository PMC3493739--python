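# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Pipeline model

The design under analysis is one pooled sequencing library per condition:
no biological replicates, so between-library inference rests on count
statistics under proportional library totals, not on dispersion estimates.
The stages run in the order a read experiences them:

1. **Cleaning.** A read is insert + 3′ adapter (+ occasionally a 5′-adapter
   ligation artifact at the read start). Rules apply in a fixed order —
   quality, 5′ contaminant, 3′-adapter trimming, length — and each rejected
   read is charged to exactly the first rule it fails, so
   raw = kept + Σ rejections always holds. Quality = mean Phred ≥ 20 and no
   `N` (the conventional choice; any threshold can be passed in). Adapter
   matching tolerates 1 mismatch per 10 compared adapter bases (floor), with
   a 6-base minimum overlap for the 3′ adapter and an 8-base prefix for the
   5′ contaminant. The length window is **inclusive** [18, 30] nt: the
   upstream size selection isolates 18–30 nt RNA, and known matures of 20
   and 24 nt must survive; both bounds are configurable for anyone who
   prefers exclusive bounds.

2. **Mapping and categories.** Tags map by perfect full-length match on both
   strands (k-mer seed of 12 + verification; minus-strand hits reported in
   plus-strand coordinates). Each genome-matched tag gets exactly one
   category: the first of rRNA > scRNA > snoRNA > snRNA > piRNA > tRNA >
   repeat > exon_intron whose interval overlaps any hit by ≥ 1 base on the
   same strand, then known_miRNA by exact mature-sequence identity, else
   unannotated. The cascade order follows the conventional listing of
   classes to discard; it is configurable because no tie-break between,
   say, piRNA and tRNA is canonical. Multi-mapping tags keep all hits and
   are categorized over the union. BED input is 0-based half-open;
   everything internal is 1-based inclusive (validated against the packaged
   precursor table, where end − start + 1 equals the printed length for all
   25 rows).

3. **Differential expression.** RPM = count/total × 10⁶. The zero-count
   floor of 0.01 RPM before fold changes is evidenced by the packaged
   table's own extreme row (a printed std of 0.01 is far below the minimum
   attainable nonzero RPM at ~10⁷ reads). Raw counts, never floored values,
   feed the p-value. The Audic–Claverie point probability is evaluated with
   log-gamma; the cumulative tail is the CDF of a negative binomial with
   x+1 successes and success probability N1/(N1+N2), computed via the
   regularized incomplete beta — a numerics choice, proven equivalent to
   direct summation of the printed formula to 1e-12 for all x+y ≤ 50 in the
   test suite. The source formula defines only the point probability; this
   package's tail convention is cumulative one-sided tails with a doubled,
   capped two-sided default, each mode exposed. Published per-row p-values
   from other tail conventions are therefore not expected to reproduce
   exactly, and the packaged-table checks deliberately cover the fold-change
   column, not the p column. The reported fold-change column follows the
   published numeric convention log2(control/case); the up/down class is
   oriented to the case library (up = higher in case) — the two statements
   differ only in sign and are both emitted.

4. **Novel-miRNA calling.** Each unannotated tag with count ≥ 3 (below
   that, sequencing-error singletons dominate) is folded in an 80-nt
   genomic window on each side, on its own strand. The folding engine is a
   deliberately small nearest-neighbor model: pair strengths G:C 3.3,
   A:U 0.9, G:U 1.0 kcal/mol; a stack of adjacent pairs contributes minus
   the mean of its two pair strengths (GC/GC −3.3, AU/AU −0.9, GU/GU −1.0);
   linear loop penalties (hairpin 1.0 + 0.1/nt, interior/bulge 1.0 + 0.5
   per unpaired nt, ≤ 6 nt per side); multibranch loops disallowed, so every
   structure is a single stem-loop — the only geometry a pre-miRNA can
   have. The precursor is the minimum-energy closing pair that encloses the
   mature within 60–100 nt; constraining the span here (rather than taking
   the globally best structure) stops incidental base-pairing of flanking
   genomic sequence from inflating the precursor. Thresholds: MFE ≤ −18
   kcal/mol, ≥ 14 mature bases paired, terminal loop 3–20 nt, all
   configurable. Absolute energies from this model are not comparable to
   Turner-parameter folders (ViennaRNA et al.), and printed MFE values of
   published precursors are not a validation surface; only relative
   stability and geometry matter to the caller. Candidates shared between
   libraries = identical mature sequence + overlapping precursor loci.

5. **Target rules.** Duplexes are ungapped: the six rules address fixed
   positions 1..L from the miRNA 5′ end and are ill-defined under gaps. A
   G:U wobble counts 0.5 toward the numeric caps (rules i and v) but is a
   pair, not a mismatch, for the adjacency rules ii–iv — the source rules
   attach the 0.5 only to *counting*; a strictness switch treats wobbles as
   adjacency mismatches for anyone reading them otherwise. Duplex energy
   reuses the pair-strength stack sum with +0.5 per interior mismatch run;
   since rule vi is a *ratio* of two energies under the same model, the
   absolute scale cancels, and any internally consistent model gives the
   same decision boundary in practice (the exhaustive rule-engine test pins
   the implemented one against an independent checker).

6. **Enrichment.** Hypergeometric upper tail, summed in log space. The
   background is every gene carrying ≥ 1 GO annotation in the supplied map
   (the natural "reference gene background" when none is stated), and
   unannotated genes are excluded from both N and n. No GO-graph
   propagation to ancestors — nothing in the source procedure suggests it —
   but raw p and BH FDR are both emitted.

## Synthetic data: what it emulates, what it does not

The generator fabricates the full input bundle deterministically per seed:
uniform-random genome (GC ≈ 0.5), planted annotation intervals, mature
spike-ins with condition-dependent expected RPM, hairpin precursors whose
star arm pairs the mature arm except at ≤ 3 designed bulges (one bulge is
placed opposite the mature interior so the mature maps uniquely), reads
assembled as insert + 3′ adapter truncated to 36 nt, per-base error 0.1 %
(never in the first 18 bases of spike-ins, keeping expected counting exact
at small scale), and a gene→GO map with one term elevated in the target
genes. Per-miRNA counts are one multinomial draw with probabilities ∝
expected RPM; leftover mass becomes background fragments sampled uniformly
from the genome. Truth tables (TSV next to the FASTQ) conserve the library
total exactly.

Not emulated: realistic quality-score error profiles, PCR duplication,
isomiR heterogeneity, repeat-rich genome structure, and genome-scale
multimapping. Passing the end-to-end tests therefore demonstrates the
*bookkeeping and statistics* are right — conservation, coordinates,
calibration, recovery of planted signal — not that the caller's thresholds
are optimal on real genomes.

## Problem sizes and default study conditions

Defaults were chosen once as a desk-scale version of the study design: two
libraries of 20,000 reads, 12 known miRNAs (geometric RPM ladder
300–20,000) of which 4 well-expressed ones carry a true 4-fold change in
alternating directions, 4 planted hairpins at 800 RPM, three
annotated-class fragments at 2,000 RPM. Calibration simulations use
200 miRNAs × 10⁵ reads with 500 null replicates (type-I control ≤ 1 % under
the joint |log2 fc| ≥ 1 and p ≤ 0.001 gate) and 200 replicates with 4-fold
effects planted at RPM ≥ 100 (power ≥ 90 %). Hairpin recoverability is
measured over 10 seeds × 2 libraries × 4 planted hairpins.

## Numerical conventions

- Percentages round half-up to 2 decimals (decimal arithmetic, not binary
  float rounding).
- Equality tolerances: 1e-12 absolute for tail-vs-summation checks, 1e-9
  for the Σ_y p(x|y) = 1 normalization (x ≤ 1000), 1e-4 for reproducing
  printed fold changes from 4-decimal std columns.
- Ties in folding resolve to the lexicographically smallest closing pair;
  candidate output is sorted by (chromosome, start, sequence), making
  calling order-independent.
- Unicode minus signs and stray spaces in transcribed published tables are
  normalized at parse time.
- All generators draw from `numpy.random.default_rng` seeded per component;
  a fixed seed gives byte-identical FASTQ, TSV and JSON outputs (the run
  log excludes the output directory path for that reason).

## Known limitations

- The exact-match mapper is deliberate (legacy small-RNA practice) and will
  under-count tags carrying sequencing errors; at the default error rate the
  loss is < 3 % of reads per 22-nt tag.
- The stem-loop caller's min tag count of 3 trades sensitivity at very low
  expression for speed and precision; single-read novel miRNAs are
  invisible by design.
- One library per condition means the p-value measures sampling, not
  biological, variability; with replicates available a dispersion-based
  method should be preferred.
- The hairpin energy model's absolute kcal/mol scale is internal; compare
  MFE values only within runs of this package.
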