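# Methods

## Model and procedure

### Terms and events

A gene is decomposed into *terms*: exons, introns and splice junctions, each
carrying a read count per sample. Junction terms are identified by (donor,
acceptor, strand) and their effective length is the mapped junction-database
segment (default 80 nt, i.e. a 40 bp overlap on each side), not the spanned
genomic distance. Internally all coordinates are 0-based half-open; GTF/GFF3
I/O converts from/to 1-based inclusive. Introns are inferred as gaps between
consecutive exons of a transcript, except that a gap containing another
annotated exon of the gene is a skipped region of that isoform, not an
intron term.

Candidate events come from annotated structure only (no novel-junction
discovery): a cassette-exon event requires an internal exon with both
flanking junctions and at least one annotated skipping junction
(`H_e` = {upstream junction, exon, downstream junction}, `S_e` = all
skipping junctions pooled); an intron-retention event requires at least one
junction spanning the intron (`H_e` = {intron}, `S_e` = all spanning
junctions, restrictable to the boundary-exact junction with
`canonical_skip_only`). Pooling multiple skipping junctions into one `S_e`
is the default because alternate excising junctions carry the same signal;
testing them separately would split it.

### Normalization

Library composition is corrected by the trimmed mean of M-values (TMM):
reference sample chosen as the one whose 75th-percentile relative expression
is closest to the cross-sample mean; M-values trimmed 30% and A-values 5%
per tail; weights are the inverse delta-method binomial variance; factors
rescaled to product 1. Expression is
`log2((count + 0.5) / (lib·factor + 1) · 1e6)`. The +0.5/+1 offsets avoid
log 0 and make the transform strictly increasing in count; they also mean
exact scale invariance under joint count/library doubling holds only away
from very low counts. Library sizes default to column sums of the term
matrix and can be overridden by a mapped-totals file. Voom-style precision
weights are *not* propagated: inference consumes only coefficients and
p-values, and unweighted least squares on log-CPM keeps the model fully
specified by what this package controls.

### Per-term inference

Each term's log-CPM vector is fit by OLS against a samples × conditions
indicator design; the contrast (e.g. "B − A") gives `β` with variance
`s²·cᵀ(DᵀD)⁻¹c`. Residual variances are moderated toward a scaled
inverse-chi-square prior fitted by the method of moments on log variances
(digamma/trigamma matching with a Newton trigamma-inverse). Moderated
t-statistics use the posterior variance
`(d₀s₀² + df·s²)/(d₀ + df)` on `df + d₀` degrees of freedom, `d₀` capped at
10⁶. Degenerate cases: when the observed spread of log variances does not
exceed chi-square sampling spread (e.g. all variances equal), `d₀ = ∞` and
the prior is a point mass at the geometric-mean variance, so identical
variances moderate to exactly their common value; when *every* residual
variance is zero, a nonzero contrast receives the smallest representable
p-value so significance ordering survives without a 0/0.

One-tailed conversion: `p₁ = p₂/2` if `β > 0`, `1 − p₂/2` if `β < 0`, and
exactly 0.5 when `β = 0` — directionless evidence must be neutral in the
event sum.

### Event summarization

`x_e = Σ_{H_e} p_k + Σ_{S_e} (1 − p_k)` follows the Irwin–Hall distribution
with `n = |H_e| + |S_e|` under the null. The CDF is evaluated exactly via
the alternating sum `F(x) = (1/n!) Σ_k (−1)^k C(n,k)(x−k)ⁿ` with compensated
summation (n ≤ 12, so cancellation is mild); on the lower tail this is
`xⁿ/n!`. The combined p-value is the symmetric two-sided rule
`min(1, 2·min(F, 1−F))`, which coincides with `2·xⁿ/n!` for `x_e ≤ 1`
(the most significant events) and is continuous and well-defined for every
`x_e`; direction is spliced-in iff `F < 0.5`. No multiple-testing correction
is applied to event p-values by default (raw combined p-values are the
ranking tool); Benjamini–Hochberg is available behind a flag.

An event is reported only when its context flanking exons reach `min_reads`
(default 4, mirroring the junction read floor) in at least half the
replicates of some condition, and every `H_e ∪ S_e` term has a nonzero count
somewhere.

### Splicing index

`RPKM_j = count / (mapped·10⁻⁶ · length·10⁻³)`; `RPKM_g` is the plain sum
over a gene's junctions; `NI = RPKM_j / RPKM_g` sums to 1 across a gene
within a sample (so any consistent length convention cancels when junction
lengths are equal, and per-sample scaling cancels exactly);
`SI = ln(mean NI)_test − ln(mean NI)_ref` on group-mean NI, while the t-test
runs on per-replicate NI. Filter order: junctions with zero counts overall
removed; gene expressed (> 5 reads) in both groups; junction read floor
(≥ 4 in ≥ half the replicates of either group); unpaired two-tailed t-test
with raw p ≤ 0.05 as the gate and the Šidák adjustment
`1 − (1−p)^m` reported alongside (`m` = junctions reaching the test; global
family by default, per-gene optional); |SI| ≥ 1.0 in ln units. A zero
group-mean NI marks the junction unevaluable rather than producing ±∞.
Gating on raw p while reporting the adjusted value reflects the pipeline's
use of the test as an omission rule with the correction as annotation; both
columns are in the output so the stricter gate is one filter away.

### Intron fold change and PTC scanning

Intron analysis pools replicate reads per condition *before* RPKM (a
per-replicate mode exists), drops introns with < 5 reads in every condition,
and reports `RPKM_kd / RPKM_ctrl`; introns silent in the control but
expressed in the knockdown are flagged "exclusive" with no numeric fold
change.

PTC scanning reads spliced sense-strand mRNA with an annotated CDS start and
stop, walks codons from the start, and reports the first of {TAA, TAG, TGA}
(standard nuclear code; codons containing N are skipped as non-stop; a
transcript with no in-frame stop is reported as non-stop, not an error).
`is_ptc` is true iff the first stop precedes the annotated stop. The 3′UTR
distance runs from the first nucleotide *after* the stop codon to the
transcript 3′ end — pure UTR length, excluding the stop codon itself; the
alternative inclusive convention differs by exactly 3 nt and is configurable
at the caller level. Cohorts of FS/AS pairs are summarized by the medians of
the PTC-to-3′-end and normal-stop-to-3′-end distances plus a shared-bin
histogram.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical skeleton of a two-group bulk
splicing study: 4 biological replicates per group, negative-binomial counts
with variance `μ + φμ²` (default dispersion φ = 0.05, a typical biological
replicate level), baseline mean 200 reads per term, library-size spread
±20%, and planted events with reciprocal 4-fold effects (inclusion terms ×4
and skipping terms ÷4 in the test group for spliced-in; reversed for
spliced-out). Reciprocal planting is the default because genuine splicing
shifts move inclusion and skipping evidence in opposite directions; a
one-sided mode exists for robustness checks. Gene models are 3–5 exons with
one full-length isoform and (optionally) one exon-skipping isoform, which is
what creates annotated skipping junctions.

What the simulations do **not** model: positional read biases, mappability
differences between terms, shared-exon dependence between overlapping genes,
GC effects, unannotated junctions, partial intron retention, and
term-length-dependent mean–variance structure (all terms share one baseline
mean). Passing the calibration and power benchmarks therefore shows the
inference machinery is correct and well calibrated under NB sampling — it
does not certify performance on real libraries, where annotation quality and
counting upstream of this package dominate. Planted-truth recall is scored
only on planted event ids; genes carrying a planted event also contain
correlated side events (they share junction terms), which the empirical FDR
column makes visible rather than hiding.

PTC cohorts are FS/AS pairs with a retained intron inserted at a codon
boundary; the intron prefix is stop-free and a TAA is planted at a recorded
offset, so the first in-frame stop is known exactly. Normal 3′UTR lengths
are drawn 40–200 nt (median ≈ 120, the typical worm scale) and retained
introns 200–2000 nt, giving extensions around a kilobase.

## Numerical choices and problem sizes

- Irwin–Hall alternating sum via `math.fsum`; n capped at 12.
- Trigamma inverse: Newton iteration, tolerance 1e-10, ~60 iterations max.
- TMM factor treated as 1 when |log₂ factor| < 1e-10 (numerical zero trim).
- t-test NaNs (constant NI) and zero-NI junctions carry explicit flags, not
  silent drops; tie-breaks in the top-2 junction table go to the lower
  coordinate.
- Benchmarks in the acceptance script use 1,500 null genes (10,500 terms,
  ≥ 3,000 null events, of which the first 2,000 enumerated are scored),
  500 planted-event genes, 5,000 variance draws for prior recovery, 10⁶
  Monte-Carlo draws per Irwin–Hall spot check, and a 100-pair PTC cohort —
  sizes chosen so each property is measured with comfortable statistical
  resolution while the whole script completes in seconds.

## Known limitations

- Only two-group single-factor designs; no covariates or blocking.
- Only cassette-exon and intron-retention events; alternative
  donors/acceptors, initiation, termination and mutually exclusive exons are
  out of scope.
- Event p-values within a gene are correlated (shared junction terms); the
  reported raw p-values are exchangeable for ranking but not independent.
- The per-term model ignores voom precision weights, slightly underweighting
  low-count terms relative to a weighted fit.
- RPKM "mapped reads" defaults to per-sample totals of the supplied matrix;
  supply alignment-level totals when absolute RPKM columns matter (NI and SI
  are ratios and do not depend on this choice).
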