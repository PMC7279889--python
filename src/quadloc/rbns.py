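"""RNA Bind-n-Seq enrichment analysis.

Quantifies the sequence preference of an RNA-binding domain from a pair of
read pools — the random input pool and the protein-bound pool — via:

* per-kmer R values: ratio of a kmer's positional frequency in the bound
  pool to its frequency in the input pool;
* motif-class enrichment: ratio of the fraction of reads with at least one
  match to a G-quadruplex motif class (four-WGGA-tract regex, four-GGG-tract
  regex, or externally supplied fold-predicted calls) in bound vs input;
* bootstrap subsampling of both pools to put a mean and standard deviation
  on the motif-class ratio.

The K+/Li+ contrast is the physical control: K+ stabilizes folded
quadruplexes (enrichment expected for a quadruplex-binding domain), Li+
destabilizes them (enrichment collapses toward 1).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gquad import wgga_pattern

__all__ = [
    "ReadPool",
    "MotifEnrichment",
    "kmer_r_values",
    "wgga_matcher",
    "ggg_quadruplex_matcher",
    "fold_predicted_matcher",
    "motif_fraction_ratio",
    "bootstrap_enrichment",
]


@dataclass
class ReadPool:
    """Fixed-length reads from one pool of a Bind-n-Seq experiment."""

    reads: list[str]
    condition: str = "K"  # "K" or "Li"
    role: str = "input"  # "input" or "bound"

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("empty read pool")
        n = len(self.reads[0])
        if any(len(r) != n for r in self.reads):
            raise ValueError("reads must have uniform length")
        self.reads = [r.upper().replace("T", "U") for r in self.reads]

    @property
    def read_length(self) -> int:
        return len(self.reads[0])

    def __len__(self) -> int:
        return len(self.reads)


def _kmer_freqs(reads: Sequence[str], k: int) -> Counter[str]:
    counts: Counter[str] = Counter()
    for r in reads:
        for i in range(len(r) - k + 1):
            counts[r[i : i + k]] += 1
    return counts


def kmer_r_values(
    input_pool: ReadPool, bound_pool: ReadPool, k: int = 6
) -> pd.DataFrame:
    """Per-kmer enrichment (R) of bound over input positional frequencies.

    Frequencies are normalized over all kmer positions in each pool so they
    sum to 1; R = freq_bound / freq_input. Kmers absent from the input pool
    get R = NaN (undefined), never infinity. Sorted by R descending.
    """
    if k > input_pool.read_length:
        raise ValueError("k exceeds read length")
    fin = _kmer_freqs(input_pool.reads, k)
    fbnd = _kmer_freqs(bound_pool.reads, k)
    tot_in = sum(fin.values())
    tot_bnd = sum(fbnd.values())
    kmers = sorted(set(fin) | set(fbnd))
    fi = np.array([fin.get(km, 0) / tot_in for km in kmers])
    fb = np.array([fbnd.get(km, 0) / tot_bnd for km in kmers])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(fi > 0, fb / np.where(fi > 0, fi, 1.0), np.nan)
    df = pd.DataFrame(
        {"kmer": kmers, "freq_input": fi, "freq_bound": fb, "R": r}
    )
    return df.sort_values(
        "R", ascending=False, na_position="last", kind="stable"
    ).reset_index(drop=True)


def wgga_matcher(linker_max: int = 6) -> Callable[[str], bool]:
    """Predicate: read contains four WGGA tracts with 0..linker_max linkers."""
    pat = wgga_pattern(linker_max)
    return lambda read: pat.search(read.upper().replace("T", "U")) is not None


def ggg_quadruplex_matcher(linker_max: int = 7) -> Callable[[str], bool]:
    """Predicate: four GGG tracts separated by 1..linker_max nucleotides."""
    if linker_max < 1:
        raise ValueError("GGG-tract linkers are at least 1 nt")
    lk = f".{{1,{linker_max}}}?"
    pat = re.compile(f"GGG{lk}GGG{lk}GGG{lk}GGG")
    return lambda read: pat.search(read.upper().replace("T", "U")) is not None


def fold_predicted_matcher(
    calls: Mapping[str, bool]
) -> Callable[[str], bool]:
    """Predicate backed by external per-read fold predictions (read -> bool).

    Built from e.g. a TSV of an external folding engine's quadruplex calls
    on each read's randomized region; reads without a call count as
    non-matching.
    """
    return lambda read: bool(calls.get(read, False))


@dataclass
class MotifEnrichment:
    """Bound/input fraction ratio for one motif class, optionally bootstrapped."""

    motif_class: str
    fraction_input: float
    fraction_bound: float
    ratio: float
    bootstrap_mean: float | None = None
    bootstrap_sd: float | None = None
    n_subsamples: int | None = None
    subsample_size: int | None = None
    n_failed_subsamples: int = 0
    seed: int | None = None


def _match_flags(pool: ReadPool, matcher: Callable[[str], bool]) -> np.ndarray:
    return np.fromiter(
        (matcher(r) for r in pool.reads), dtype=bool, count=len(pool)
    )


def motif_fraction_ratio(
    input_pool: ReadPool,
    bound_pool: ReadPool,
    matcher: Callable[[str], bool],
    motif_class: str = "custom",
) -> MotifEnrichment:
    """Point estimate: (bound reads with >=1 match / bound reads) over input.

    Fractions are per-read presence, not positional counts. A zero input
    fraction leaves the ratio undefined (NaN).
    """
    fi = float(_match_flags(input_pool, matcher).mean())
    fb = float(_match_flags(bound_pool, matcher).mean())
    ratio = fb / fi if fi > 0 else float("nan")
    return MotifEnrichment(
        motif_class=motif_class,
        fraction_input=fi,
        fraction_bound=fb,
        ratio=ratio,
    )


def bootstrap_enrichment(
    input_pool: ReadPool,
    bound_pool: ReadPool,
    matcher: Callable[[str], bool],
    n_subsamples: int = 20,
    subsample_fraction: float = 0.2,
    seed: int | None = None,
    motif_class: str = "custom",
) -> MotifEnrichment:
    """Motif-class ratio with mean and SD across subsampled read sets.

    Each subsample draws ceil(fraction * N) reads without replacement,
    independently from each pool, and recomputes the fraction ratio.
    Subsamples whose input draw contains no matching read have an undefined
    ratio; they are excluded from the mean/SD and counted in
    ``n_failed_subsamples``. Deterministic under a fixed seed.
    """
    if n_subsamples < 2:
        raise ValueError("need at least 2 subsamples")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    flags_in = _match_flags(input_pool, matcher)
    flags_bnd = _match_flags(bound_pool, matcher)
    n_in = int(np.ceil(subsample_fraction * len(flags_in)))
    n_bnd = int(np.ceil(subsample_fraction * len(flags_bnd)))
    ratios = []
    failed = 0
    for _ in range(n_subsamples):
        fi = flags_in[rng.choice(len(flags_in), size=n_in, replace=False)].mean()
        fb = flags_bnd[
            rng.choice(len(flags_bnd), size=n_bnd, replace=False)
        ].mean()
        if fi == 0:
            failed += 1
            continue
        ratios.append(fb / fi)
    point = motif_fraction_ratio(input_pool, bound_pool, matcher, motif_class)
    mean = float(np.mean(ratios)) if ratios else float("nan")
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else float("nan")
    return MotifEnrichment(
        motif_class=motif_class,
        fraction_input=point.fraction_input,
        fraction_bound=point.fraction_bound,
        ratio=point.ratio,
        bootstrap_mean=mean,
        bootstrap_sd=sd,
        n_subsamples=n_subsamples,
        subsample_size=n_in,
        n_failed_subsamples=failed,
        seed=seed,
    )
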