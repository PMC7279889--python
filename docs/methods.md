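# Methods

This note documents the models, numerical choices and limitations behind
`quadloc`. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Localization ratios and the condition contrast

Counts are normalized by DESeq-style median-of-ratios size factors
(computed over genes with nonzero counts in every sample, rescaled to
geometric mean 1). The localization ratio of a gene in one replicate is
`log2((neurite + c)/(soma + c))` on normalized counts with pseudocount
`c = 0.5`; the pseudocount is symmetric so zero counts give LR = 0 rather
than ±∞, at the cost of shrinking ratios for very low counts. Soma and
neurite samples are paired by (condition, replicate) because the two
fractions of one prep come from the same membrane.

Genes with fewer than 10 raw counts in any sample are excluded before
testing (strict `< 10`; a gene with all counts exactly 10 is retained).

Three per-gene tests of ΔLR between conditions are provided:

* **welch** — Welch's t on the per-replicate LRs. Degenerate zero-variance
  cases: equal means give p = 1; unequal means (t undefined) fall back to
  the permutation p. These arise routinely in n = 3 designs with ties.
* **permutation** — exact enumeration of all C(n₁+n₂, n₁) replicate-label
  assignments, two-sided on |Δmean|. With 3 + 3 replicates there are only
  20 assignments, so p-values are discrete on multiples of 0.1. For
  calibration diagnostics an atom-randomized variant
  (p = (#greater + U·#tied)/N) is available; it is exactly U(0,1) under
  the null and is what the Kolmogorov–Smirnov uniformity check in the
  acceptance suite uses — a naive KS test against U(0,1) on the raw
  discrete p-values would reject for any large gene count purely because
  of discreteness.
* **moderated** (default) — a moderated t: per-gene pooled variances are
  shrunk toward a scaled-inverse-χ² prior whose hyperparameters (prior df
  d₀, prior variance s₀²) are fitted from the moments of log s² across
  genes (digamma/trigamma matching); the test df becomes d₀ + d. With
  three replicates a plain Welch t is limited by the instability of a
  3-point variance estimate, not by the information in the data;
  empirical-Bayes moderation is the standard remedy at this design size.
  If the observed spread of variances is no larger than sampling noise the
  prior df is infinite and a common variance is used.

Benjamini–Hochberg FDR is applied within the contrast, over filtered genes
only. Target calling: `fdr < α` plus a configurable direction gate
(default: ΔLR < 0, impaired localization in the second condition). For
designs too noisy for a reasonable FDR, a magnitude rule classifies
ΔLR ≤ −0.25 as targets and ΔLR ≥ +0.25 as nontargets, leaving the rest
unclassified.

The same machinery applies unchanged to ribosome-occupancy ratios by
relabelling compartments (footprint/rnaseq).

## G-quadruplex definitions

**WGGA regex.** The scanner counts one match at every offset where the
lookahead pattern `(?=([AU]GGA(.{0,6})[AU]GGA(.{0,6})[AU]GGA(.{0,6})[AU]GGA))`
succeeds; overlapping elements at distinct offsets count separately.
Within an offset the reported span uses lazy linker quantifiers, whose
backtracking order makes the reported (l1, l2, l3) the lexicographically
smallest feasible triple — deterministic, reproducible spans. Note the
prose description of this motif class elsewhere says "0–7 nt linkers"
while the literal regex bounds them at 6; the regex is taken as
authoritative and the cap is configurable (`linker_max`). DNA input is
silently normalized T→U; characters outside A/C/G/T/U/N are rejected; N
matches neither W nor G. The scanner is verified against an exhaustive
all-offsets × all-(0–6)³-linker enumeration oracle.

**Windowed structure annotations.** Folding predictions are consumed, not
computed: windows of 80 nt slid 20 nt at a time (a final window anchored
at `len − 80` covers the 3′ terminus; end handling is not specified by
the window scheme itself, anchoring is this package's choice), each
carrying a structure string in which `+` marks predicted quadruplex
participation. Overlapping windows are reconciled by union — a nucleotide
participates if any covering window says so. Density is masked-G per nt.

**RT stops.** A stop position is called a quadruplex 3′ end when
`count_K ≥ ratio_min × max(count_Li, 1)` with `ratio_min = 5` ("at least
five times more frequent in potassium"). The Li count is floored at 1 to
avoid infinite ratios while preserving the inclusive threshold on the
floored scale; so (K=5, Li=0) is called and (K=4, Li=0) is not. The G4
interval is `[max(0, pos−60), pos)`. Coordinates are 0-based half-open
throughout, including BED export.

## Enrichment statistics

6mer enrichment counts overlapping kmer occurrences (positions) by
default; a presence-per-sequence mode is available since the choice is not
forced by the analysis definition. Each kmer gets a two-sided Fisher's
exact test (minimum-likelihood definition: sum of tables with point
probability ≤ observed) on occurrence vs total-position tables, and BH
correction runs over all 4^k kmers. The background set is the expressed
non-target genes.

The Wilcoxon rank-sum test enumerates all group assignments (tie-safe via
midranks) when the combined sample size is ≤ 10, and otherwise uses the
normal approximation with tie and continuity corrections. Cliff's delta is
(#concordant − #discordant)/(n·m) over cross pairs, computed by binary
search in O((n+m) log m); its companion p-value is the Wilcoxon test on
the same two samples. Binomial overlap tests are upper-tail exact with the
null fraction taken from the supplied universe. Gene identifiers are
case-folded and stripped of trailing version suffixes before set
operations.

Conservation comparison bins per-G scores by (in-quadruplex, in-target)
into four disjoint groups and reports pairwise rank-sum p-values; empty
groups yield NaN rather than an error.

## Bind-n-Seq

Per-kmer R values use positional kmer frequencies normalized within each
pool; kmers absent from the input are flagged undefined (NaN), never
infinite. Motif-class enrichment uses per-read presence (≥ 1 match), and
the two metrics are never mixed. Bootstrap subsampling draws
`ceil(fraction·N)` reads without replacement, independently per pool, for
each of `n_subsamples` subsamples (defaults 0.2 and 20 — the subsampling
scheme's size and count are this package's choice), and reports the mean
and SD of the recomputed ratio; subsamples with no matching input read are
excluded and counted. At fraction 1.0 the mean equals the point estimate
and the SD is 0. The fold-predicted motif class is a pluggable per-read
predicate so external folding-engine calls can be supplied as a TSV.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the analysis assumes,
with full ground truth; they are not read-level simulators.

* **Transcriptome.** Background 3′UTRs (150–400 nt, uniform A/C/G/U by
  default, configurable GC) are rejection-sampled until they contain zero
  WGGA-regex matches, so planted-element recovery is exact and enrichment
  directions are unambiguous. Targets (default 2.5% of 2000 genes)
  receive one planted four-WGGA-tract element with linkers drawn from
  0–6 nt, overwriting a random window. 5′UTR and CDS backgrounds are
  generated quadruplex-free (no planting), so region-restricted
  enrichment has a known null.
* **Counts.** Gene baselines are log-normal (σ = 1) around a mean depth of
  500; each gene has a baseline LR ~ Normal(0, 0.5) shared by conditions.
  The planted effect multiplies the knockout *neurite* mean by 2^ΔLR
  (default ΔLR = −1), leaving soma unchanged — a localization change, not
  an expression change. Overdispersion is placed at the prep level: each
  (gene, condition, replicate) draws a gamma factor with mean 1 and
  variance equal to the dispersion (default 0.1), shared by the soma and
  neurite fractions of that prep, with Poisson counting on top. Marginal
  counts are exactly NB(μ, dispersion); because the two fractions of a
  prep share the biological factor, replicate-to-replicate LR noise is
  Poisson-dominated — the property that makes a one-log2-unit effect
  detectable with triplicates, and the property real split-prep
  fractionation data share. Library sizes are jittered ±20% per sample.
* **RT stops.** Every UTR position gets Binomial(depth, rate) counts for
  K⁺ and Li⁺; the position immediately 3′ of each planted element uses the
  elevated K⁺ rate (defaults: 0.05 vs background 0.001, depth 1000).
* **RBNS pools.** Input reads are random 40-mers; a configurable fraction
  (default 0.1) carries a planted WGGA element, because under a uniform
  composition the four-tract class occurs at ~3·10⁻⁵ per read and a
  desk-scale pool would contain essentially no matching input reads — the
  planted fraction stands in for the astronomically larger diversity of a
  real random pool. The bound pool resamples input reads with replacement,
  weighting matching reads by the enrichment factor E (default 10) under
  K⁺ and uniformly under Li⁺. The weight-implied expected fraction ratio,
  `E/(E·f + 1 − f)` for input match fraction `f`, is the closed-form
  oracle the bootstrap estimate is checked against.

One global seed expands to per-stage child seeds by fixed offsets, so any
stage can be regenerated alone. Everything is byte-deterministic per seed.

What passing tests on these data do **not** show: robustness to real-data
features the generators omit — isoform mixtures, 3′UTR length variation
across conditions, GC/mappability bias, correlated gene modules,
compartment-specific dispersion differences, partial or degenerate
quadruplex motifs in the background, and RBNS adapter context or
sequencing error. Distributional choices are stand-ins (no noise model is
prescribed by the analysis itself) and are asserted only via
self-consistency and planted-truth recovery, never against external data.

## Problem sizes and defaults

The synthetic study defaults — 2000 genes, 50 targets, ΔLR = −1,
triplicates, dispersion 0.1, depth 500, quadruplexes in all targets and no
nontargets, RBNS enrichment 10 at 40-nt reads — are the package's standard
conditions and are what the acceptance script runs (10 simulated
experiments per recovery estimate; 1000 sequences for the scanner-oracle
check; 50 000-read RBNS pools; 200-gene, 10-seed RT-stop recovery). The
full pipeline completes in seconds on one CPU at these sizes.

## Known limitations

* The moderated test assumes per-gene LR variances are exchangeable around
  a common prior; strong mean–variance structure (e.g. a heavy low-count
  tail surviving the count filter) is only partially captured by the prior
  spread.
* The exact Wilcoxon path enumerates C(n+m, n) assignments and is
  restricted to combined n ≤ 10 by default.
* The WGGA scanner counts matches per start offset (lookahead semantics);
  it does not attempt to merge overlapping offsets into physical element
  loci, and densities inherit that convention.
* `size_factors` requires at least one gene with nonzero counts in every
  sample and raises otherwise (advising a pseudocount) rather than
  silently degrading.
* p-values below 1e-300 are floored for serialization; report floats are
  rounded to 6 significant digits to keep outputs byte-stable.
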