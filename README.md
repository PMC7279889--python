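# quadloc

Analysis toolkit for subcellular RNA localization and RNA G-quadruplex
content, built for studies that fractionate neuronal cells into soma and
neurite compartments, sequence both fractions in a wildtype and a
perturbed condition (e.g. an RNA-binding-protein knockout), and ask which
transcripts depend on the perturbed factor for transport — and what
sequence features those transcripts share.

## What it computes

**Localization ratio (LR).** For each gene, after median-of-ratios
normalization of the count matrix,

```
LR = log2( (neurite counts + c) / (soma counts + c) )
```

computed per replicate pair (the soma and neurite fractions of one prep
are physically paired), with pseudocount `c = 0.5`. Positive LR means
neurite-enriched. A condition contrast tests, per gene, whether LR changes
between conditions (ΔLR = LR₂ − LR₁) using a replicate-level test: Welch's
t, an exact replicate-label permutation, or an empirical-Bayes moderated t
(the default; variance shrinkage is essential at n = 3). Benjamini–Hochberg
FDR is applied over tested genes; genes with fewer than 10 counts in any
sample are excluded first. Targets are called either by `FDR < α` with a
direction gate (ΔLR < 0), or — for noisy designs — by `|ΔLR| ≥ 0.25`.

**G-quadruplex detection**, three independent routes:

1. *WGGA motif*: the lookahead regex
   `(?=([AU]GGA(.{0,6})[AU]GGA(.{0,6})[AU]GGA(.{0,6})[AU]GGA))` — four
   W-G-G-A tracts (W = A/U) with 0–6 nt linkers, counting one match per
   feasible start offset (overlaps included). Density = matches per nt.
2. *Predicted structure*: per-nucleotide `+` annotations from an external
   folding engine run on 80-nt windows slid by 20 nt, unioned into a
   per-base participation mask. Density = masked G residues per nt.
3. *Experimental RT stops*: reverse transcriptase stalls at folded
   quadruplexes under K⁺ but not Li⁺; a stop with
   `count_K ≥ 5 × max(count_Li, 1)` defines a G4 in the 60 nt upstream.
   Density = covered bp per nt.

**Enrichment statistics**: per-6mer Fisher's exact tests with BH correction,
binomial tests for overlap with externally bound gene sets (CLIP targets),
Wilcoxon rank-sum comparisons of feature distributions, Cliff's delta
effect sizes, and conservation-score binning of guanosines by quadruplex
participation.

**Bind-n-Seq (RBNS)**: per-kmer R values (bound/input positional kmer
frequency), motif-class read-fraction ratios (WGGA regex, four-GGG-tract
regex with 1–7 nt linkers, or external fold predictions), and bootstrap
subsampling for means and standard deviations, contrasting K⁺ and Li⁺
binding conditions.

**Synthetic data with ground truth** (`quadloc.synthio`): every generator
needed to exercise the pipeline end to end — planted-quadruplex 3′UTRs
over a quadruplex-free background, prep-paired negative-binomial count
matrices with a localization effect planted in the knockout neurite only,
K⁺-specific RT-stop tables, and weighted-sampling RBNS pools — all pure
functions of a seed.

## Worked example

```
quadloc run-all --seed 7 --outdir demo_run
```

simulates a 2000-gene experiment (50 targets with ΔLR = −1, triplicates,
NB dispersion 0.1, depth 500), runs the full analysis and prints the
report; the key sections of the actual output:

```
"localization": {
  "confusion_vs_truth": {
    "empirical_fdr": 0.0204082, "fn": 1, "fp": 1,
    "recall": 0.979592, "tn": 1933, "tp": 48
  },
  "n_called_targets": 49, "n_excluded_low_count": 17,
  "n_genes": 2000, "n_tested": 1983
},
"enrichment": {
  "n_significant_kmers": 15,
  "top_kmers": ["GAAGGA", "GGAAGG", "AGGAAG", ...],
  "top_kmers_gga_fraction": 1.0,
  "wgga_density_cliffs_delta": 0.979117
},
"rbns": {
  "K":  {"bootstrap_mean": 5.31837, "bootstrap_sd": 0.153496,
         "expected_ratio": 5.26166},
  "Li": {"bootstrap_mean": 1.0129,  "bootstrap_sd": 0.0242502,
         "expected_ratio": 1.0}
},
"rt_stop": {"n_calls": 1530, "n_planted_g4_genes": 50, "recovery": 1.0}
```

Reading this: 48 of the 49 testable planted targets were recovered at
BH-FDR 0.1 with one false positive; every top enriched 6mer in target
3′UTRs contains GGA (the planted tract); the K⁺ Bind-n-Seq pool shows the
weight-implied quadruplex-read enrichment while Li⁺ collapses to 1; and
all 50 planted quadruplexes are recovered from differential RT stops.

Other subcommands (`simulate`, `scan-g4`, `localize`, `enrich`, `rbns`)
expose the individual stages on files; `quadloc --help` lists options.

## Layout

```
src/quadloc/
  gquad.py         G-quadruplex detection (regex / structure mask / RT stops)
  localization.py  size factors, LR, differential tests, target calling
  enrichment.py    kmer, overlap, rank and effect-size statistics
  rbns.py          Bind-n-Seq R values and motif-class bootstraps
  synthio.py       synthetic-data generators with planted truth
  io.py            FASTA / TSV / BED readers and writers
  pipeline.py      run-all orchestration and report
  cli.py           click command line
docs/methods.md    model, assumptions, parameter choices, limitations
```
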