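"""Statistics linking gene sets to sequence features.

kmer enrichment (Fisher's exact + BH over all 4^k kmers), binomial tests
for overlap with externally defined bound-gene sets (e.g. CLIP targets),
two-sample rank statistics (Wilcoxon rank-sum, Cliff's delta effect size),
per-gene transcript feature assembly, and conservation-score binning of
guanosines by quadruplex participation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import gquad

__all__ = [
    "OverlapTestResult",
    "EffectSizeResult",
    "ConservationComparison",
    "count_kmers",
    "kmer_enrichment",
    "define_clip_targets",
    "binomial_overlap",
    "wilcoxon_rank_sum",
    "cliffs_delta",
    "effect_size",
    "feature_table",
    "conservation_compare",
]

_ALPHABET = "ACGU"


def count_kmers(
    seqs: Iterable[str], k: int = 6
) -> tuple[Counter[str], int]:
    """Overlapping kmer occurrence counts and the total number of positions.

    Each sequence of length L contributes max(0, L - k + 1) positions;
    kmers containing N are skipped (but still consume a position).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    total = 0
    for s in seqs:
        s = s.upper().replace("T", "U")
        n = len(s) - k + 1
        if n <= 0:
            continue
        total += n
        for i in range(n):
            kmer = s[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    return counts, total


def _presence_counts(
    seqs: Sequence[str], k: int
) -> tuple[Counter[str], int]:
    counts: Counter[str] = Counter()
    for s in seqs:
        s = s.upper().replace("T", "U")
        seen = {s[i : i + k] for i in range(len(s) - k + 1)}
        counts.update(km for km in seen if "N" not in km)
    return counts, len(seqs)


def kmer_enrichment(
    fg_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    k: int = 6,
    alpha: float = 0.05,
    mode: str = "occurrence",
) -> pd.DataFrame:
    """Per-kmer Fisher's exact enrichment of foreground vs background.

    ``mode="occurrence"`` (default) tests occurrence counts against total
    kmer positions; ``mode="presence"`` tests genes-containing-the-kmer
    against gene totals. Two-sided Fisher uses the minimum-likelihood
    definition (sum over tables with point probability <= observed). BH
    correction is applied over all 4^k kmers; ``significant`` flags
    q < alpha.
    """
    if not len(fg_seqs) or not len(bg_seqs):
        raise ValueError("both sequence sets must be nonempty")
    counter = count_kmers if mode == "occurrence" else _presence_counts
    if mode not in ("occurrence", "presence"):
        raise ValueError(f"unknown mode {mode!r}")
    fg, total_fg = counter(fg_seqs, k)
    bg, total_bg = counter(bg_seqs, k)
    if total_fg == 0 or total_bg == 0:
        raise ValueError("zero kmer positions in one of the sets")
    kmers = ["".join(t) for t in product(_ALPHABET, repeat=k)]
    rows = []
    for km in kmers:
        a, b = fg.get(km, 0), bg.get(km, 0)
        if a == 0 and b == 0:
            p = 1.0
        else:
            _, p = stats.fisher_exact(
                [[a, total_fg - a], [b, total_bg - b]], alternative="two-sided"
            )
        f_fg = a / total_fg
        f_bg = b / total_bg
        with np.errstate(divide="ignore", invalid="ignore"):
            l2e = np.log2(f_fg / f_bg) if b > 0 and a > 0 else (
                np.inf if a > 0 else (-np.inf if b > 0 else 0.0)
            )
        rows.append((km, a, b, float(l2e), float(p)))
    df = pd.DataFrame(
        rows, columns=["kmer", "count_fg", "count_bg", "log2_enrichment", "p"]
    )
    df["total_fg"] = total_fg
    df["total_bg"] = total_bg
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df["significant"] = df["q"] < alpha
    return df.sort_values(["q", "p", "kmer"], kind="stable").reset_index(
        drop=True
    )


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def _normalize_id(gene: str) -> str:
    return _VERSION_SUFFIX.sub("", gene.strip()).casefold()


def define_clip_targets(*gene_lists: Iterable[str]) -> set[str]:
    """Intersection of bound-gene lists after identifier normalization.

    Normalization case-folds and strips trailing version suffixes
    (e.g. ``ENSMUSG00000000838.12`` -> ``ensmusg00000000838``).
    """
    if not gene_lists:
        raise ValueError("need at least one gene list")
    sets = [{_normalize_id(g) for g in lst} for lst in gene_lists]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


@dataclass(frozen=True)
class OverlapTestResult:
    """Binomial enrichment of a gene set within an externally bound set."""

    n_targets: int
    n_bound: int
    background_fraction: float
    fold: float
    p: float


def binomial_overlap(
    target_set: Iterable[str],
    bound_set: Iterable[str],
    universe: Iterable[str],
) -> OverlapTestResult:
    """Upper-tail exact binomial test for bound-set overlap enrichment.

    Null probability is the bound fraction of the universe; p is
    P(X >= n_bound) for X ~ Binomial(n_targets, background_fraction).
    """
    uni = {_normalize_id(g) for g in universe}
    if not uni:
        raise ValueError("empty universe")
    tgt = {_normalize_id(g) for g in target_set}
    if not tgt <= uni:
        raise ValueError("target set not contained in universe")
    bound = {_normalize_id(g) for g in bound_set} & uni
    p0 = len(bound) / len(uni)
    n = len(tgt)
    k = len(tgt & bound)
    p = stats.binomtest(k, n, p0, alternative="greater").pvalue if n else 1.0
    fold = (k / n) / p0 if n and p0 > 0 else float("nan")
    return OverlapTestResult(
        n_targets=n, n_bound=k, background_fraction=p0, fold=fold, p=float(p)
    )


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Midranks handle ties; the p-value is the fraction of the
    C(n_x + n_y, n_x) assignments whose rank-sum deviates from its null
    mean at least as much as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n_x = len(x)
    n = len(pooled)
    w_obs = ranks[:n_x].sum()
    mu = n_x * (n + 1) / 2.0
    obs_dev = abs(w_obs - mu)
    count = 0
    total = comb(n, n_x)
    for idx in combinations(range(n), n_x):
        if abs(ranks[list(idx)].sum() - mu) >= obs_dev - 1e-9:
            count += 1
    return count / total


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration (tie-safe, via midranks) when the combined sample
    size is <= ``exact_max_n``; otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if len(x) + len(y) <= exact_max_n:
        return _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross pairs, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    ys = np.sort(y)
    gt = np.searchsorted(ys, x, side="left").sum()
    le = np.searchsorted(ys, x, side="right").sum()
    lt = len(x) * len(y) - le
    return float(gt - lt) / (len(x) * len(y))


@dataclass(frozen=True)
class EffectSizeResult:
    feature: str
    cliffs_delta: float
    p: float


def effect_size(
    feature: str, x: Sequence[float], y: Sequence[float]
) -> EffectSizeResult:
    """Cliff's delta with a companion Wilcoxon rank-sum p-value."""
    return EffectSizeResult(
        feature=feature,
        cliffs_delta=cliffs_delta(x, y),
        p=wilcoxon_rank_sum(x, y),
    )


def feature_table(
    genes: Sequence[str],
    utr3_seqs: Mapping[str, str] | None = None,
    cds_seqs: Mapping[str, str] | None = None,
    utr5_seqs: Mapping[str, str] | None = None,
    masks: Mapping[str, gquad.G4Mask] | None = None,
    exp_g4s: Mapping[str, Sequence[gquad.ExperimentalG4]] | None = None,
    expression: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble per-gene transcript features.

    Region lengths, WGGA-element density per region, quadruplex-G density
    (where structure masks are supplied, 3'UTR only), experimental-G4
    overlap density, and mean normalized expression. Missing inputs leave
    the feature absent (NaN), never zero.
    """
    regions = {"utr3": utr3_seqs, "cds": cds_seqs, "utr5": utr5_seqs}
    rows: dict[str, dict[str, float]] = {g: {} for g in genes}
    for name, seqs in regions.items():
        if seqs is None:
            continue
        for g in genes:
            s = seqs.get(g)
            if s is None:
                continue
            rna = gquad.RnaSequence(g, s)
            rows[g][f"{name}_length"] = len(rna)
            rows[g][f"{name}_wgga_density"] = gquad.wgga_density(rna)
    if masks is not None and utr3_seqs is not None:
        for g in genes:
            if g in masks and g in utr3_seqs:
                rows[g]["utr3_quadruplex_g_density"] = (
                    gquad.quadruplex_g_density(
                        gquad.RnaSequence(g, utr3_seqs[g]), masks[g]
                    )
                )
    if exp_g4s is not None and utr3_seqs is not None:
        for g in genes:
            if g in utr3_seqs:
                rows[g]["utr3_experimental_g4_density"] = (
                    gquad.experimental_overlap_density(
                        0, len(utr3_seqs[g]), exp_g4s.get(g, [])
                    )
                )
    if expression is not None:
        for g in genes:
            if g in expression:
                rows[g]["mean_expression"] = float(expression[g])
    return pd.DataFrame.from_dict(rows, orient="index").reindex(genes)


@dataclass
class ConservationComparison:
    """Per-G conservation scores binned by quadruplex status and targetness.

    ``groups`` maps (in_quadruplex, is_target) -> score array;
    ``pairwise_p`` maps frozenset of two group keys -> Wilcoxon p (NaN if a
    group is empty).
    """

    groups: dict[tuple[bool, bool], np.ndarray]
    pairwise_p: dict[tuple[tuple[bool, bool], tuple[bool, bool]], float] = field(
        default_factory=dict
    )


def conservation_compare(
    scores: pd.DataFrame,
    seqs: Mapping[str, str],
    masks: Mapping[str, gquad.G4Mask],
    target_flags: Mapping[str, bool],
) -> ConservationComparison:
    """Bin per-G conservation scores and run pairwise rank-sum tests.

    ``scores`` has columns gene, position, score, giving a conservation
    value (e.g. PhyloP) at guanosine positions. Each G is assigned to one
    of four disjoint bins by (participates-in-quadruplex, in-target-gene).
    Positions out of bounds or not at a G raise an error.
    """
    groups: dict[tuple[bool, bool], list[float]] = {
        (q, t): [] for q in (False, True) for t in (False, True)
    }
    for gene, pos, score in scores[["gene", "position", "score"]].itertuples(
        index=False
    ):
        if gene not in seqs or gene not in masks:
            raise ValueError(f"no sequence/mask for gene {gene}")
        seq = seqs[gene].upper().replace("T", "U")
        pos = int(pos)
        if not 0 <= pos < len(seq):
            raise ValueError(f"{gene}: position {pos} out of bounds")
        if seq[pos] != "G":
            raise ValueError(f"{gene}: position {pos} is not a G")
        key = (bool(masks[gene].mask[pos]), bool(target_flags.get(gene, False)))
        groups[key].append(float(score))
    arr_groups = {k: np.asarray(v) for k, v in groups.items()}
    result = ConservationComparison(groups=arr_groups)
    keys = sorted(arr_groups)
    for a, b in combinations(keys, 2):
        if len(arr_groups[a]) == 0 or len(arr_groups[b]) == 0:
            result.pairwise_p[(a, b)] = float("nan")
        else:
            result.pairwise_p[(a, b)] = wilcoxon_rank_sum(
                arr_groups[a], arr_groups[b]
            )
    return result
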