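"""Localization-ratio quantification and differential testing.

The localization ratio (LR) of a gene is log2(neurite abundance / soma
abundance) after median-of-ratios normalization; positive LR means
neurite-enriched. Genes whose LR drops in a perturbed condition are called
localization targets. The same machinery applies to ribosome-occupancy
ratios by relabelling the compartments (footprint / rnaseq).

The condition contrast is a replicate-level test: per-replicate LRs are
compared across conditions with Welch's t or an exact permutation of
replicate labels, and Benjamini-Hochberg FDR is applied over tested genes.

Two classification rules are provided:

* FDR rule: target iff BH-FDR < ``fdr_max`` and delta-LR in the required
  direction (default: decrease).
* Log-fold-change rule (for noisy designs where few genes reach a
  reasonable FDR): target iff delta-LR <= -``lfc_min``; nontarget iff
  delta-LR >= +``lfc_min``; otherwise unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import wilcoxon_rank_sum

__all__ = [
    "LRTable",
    "filter_low_counts",
    "size_factors",
    "normalize_counts",
    "compute_lr",
    "diff_localization",
    "classify_targets_fdr",
    "classify_targets_lfc",
    "compartment_expression_change",
]


def filter_low_counts(counts: pd.DataFrame, min_count: int = 10) -> pd.DataFrame:
    """Drop genes with fewer than ``min_count`` counts in *any* sample."""
    if counts.empty:
        return counts
    keep = (counts >= min_count).all(axis=1)
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (DESeq-style) per-sample normalization factors.

    For each gene with nonzero counts in every sample, compute the ratio of
    each sample's count to the gene's geometric mean; the factor for a
    sample is the median of these ratios, rescaled so factors have
    geometric mean 1.
    """
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; add a pseudocount "
            "or filter samples before computing size factors"
        )
    sub = counts.loc[nonzero].to_numpy(dtype=float)
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


@dataclass
class LRTable:
    """Per-replicate and per-condition localization ratios.

    ``lr``: DataFrame, genes x (condition, replicate) MultiIndex columns.
    ``condition_means``: DataFrame, genes x condition.
    """

    lr: pd.DataFrame
    condition_means: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.lr.index


def compute_lr(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    pseudocount: float = 0.5,
    normalize: bool = True,
    numerator: str = "neurite",
    denominator: str = "soma",
) -> LRTable:
    """Per-replicate log2(numerator / denominator) abundance ratios.

    Samples are paired by (condition, replicate): the physical fractionation
    makes the neurite and soma fractions of one membrane prep a pair. For
    ribosome-occupancy analysis pass ``numerator="footprint"``,
    ``denominator="rnaseq"``.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    norm = normalize_counts(counts) if normalize else counts.astype(float)

    pairs: dict[tuple[str, int], dict[str, str]] = {}
    for sid in counts.columns:
        row = meta.loc[sid]
        pairs.setdefault(
            (str(row["condition"]), int(row["replicate"])), {}
        )[str(row["compartment"])] = sid

    cols = {}
    for (cond, rep), comps in sorted(pairs.items()):
        if numerator not in comps or denominator not in comps:
            raise ValueError(
                f"unpaired replicate: condition={cond} replicate={rep} has "
                f"compartments {sorted(comps)}"
            )
        num = norm[comps[numerator]] + pseudocount
        den = norm[comps[denominator]] + pseudocount
        cols[(cond, rep)] = np.log2(num / den)
    lr = pd.DataFrame(cols)
    lr.columns = pd.MultiIndex.from_tuples(
        lr.columns, names=["condition", "replicate"]
    )
    means = lr.T.groupby(level="condition").mean().T
    return LRTable(lr=lr, condition_means=means)


def _welch_vectorized(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Welch's t p-values per row of (genes x replicates) matrices."""
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return p, se2


def _fit_inverse_chisq_prior(
    s2: np.ndarray, df: float
) -> tuple[float, float]:
    """Fit a scaled-inverse-chi-square prior to per-gene sample variances.

    Empirical-Bayes hyperparameters (prior df d0, prior variance s0^2) are
    estimated from the moments of log(s^2), whose marginal mean/variance
    under the hierarchical model involve digamma/trigamma terms. Returns
    (d0, s0sq); d0 = inf means the variances are consistent with a single
    common value.
    """
    from scipy.special import polygamma, digamma
    from scipy.optimize import brentq

    z = np.log(np.maximum(s2, 1e-12))
    var_z = float(np.var(z, ddof=1)) if len(z) > 1 else 0.0
    target = var_z - float(polygamma(1, df / 2))
    if target <= 0:
        d0 = np.inf
        s0sq = float(np.exp(np.mean(z) - digamma(df / 2) + np.log(df / 2)))
        return d0, s0sq
    f = lambda d0: float(polygamma(1, d0 / 2)) - target
    if f(1e-2) < 0:
        d0 = 1e-2
    elif f(1e7) > 0:
        d0 = np.inf
    else:
        d0 = brentq(f, 1e-2, 1e7)
    if np.isfinite(d0):
        mean_shift = (
            digamma(df / 2) - np.log(df / 2)
            - digamma(d0 / 2) + np.log(d0 / 2)
        )
    else:
        mean_shift = digamma(df / 2) - np.log(df / 2)
    s0sq = float(np.exp(np.mean(z) - mean_shift))
    return float(d0), s0sq


def _moderated_t(
    x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Moderated-t p-values: pooled variances shrunk toward an EB prior.

    With few replicates the per-gene variance estimate dominates the error
    of a plain t statistic; shrinking each gene's pooled variance toward a
    prior fitted across all genes (and adding the prior df to the residual
    df) restores power while keeping null calibration.
    """
    n1, n2 = x.shape[1], y.shape[1]
    df = n1 + n2 - 2
    ss = x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    d0, s0sq = _fit_inverse_chisq_prior(s2, df)
    if np.isfinite(d0):
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_post = d0 + df
    else:
        s2_post = np.full_like(s2, s0sq)
        df_post = max(len(s2) - 1, df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    delta = y.mean(axis=1) - x.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
        p = 2.0 * stats.t.sf(np.abs(t), df_post)
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


def _permutation_pvalues(
    x: np.ndarray, y: np.ndarray, randomize: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Exact label-permutation p-values on |mean difference|, per gene.

    All C(n1+n2, n1) reassignments of the replicate-level values are
    enumerated. With ``randomize=True`` the discrete p-values are smoothed
    uniformly within their atoms (p = (#greater + U * #tied-or-identity) / N),
    giving exactly U(0,1) nulls; used for calibration diagnostics.
    """
    n1, n2 = x.shape[1], y.shape[1]
    pooled = np.hstack([x, y])  # genes x (n1+n2)
    idx_sets = list(combinations(range(n1 + n2), n1))
    sel = np.zeros((len(idx_sets), n1 + n2), dtype=float)
    for i, c in enumerate(idx_sets):
        sel[i, list(c)] = 1.0
    # mean of "condition1" group per permutation, then |delta|
    m1 = pooled @ sel.T / n1  # genes x nperm
    tot = pooled.sum(axis=1, keepdims=True)
    m2 = (tot - m1 * n1) / n2
    absdelta = np.abs(m2 - m1)
    obs = np.abs(y.mean(axis=1) - x.mean(axis=1))[:, None]
    eps = 1e-12 * (1.0 + absdelta.max(initial=0.0))
    n_ge = (absdelta >= obs - eps).sum(axis=1)
    if not randomize:
        return n_ge / len(idx_sets)
    n_gt = (absdelta > obs + eps).sum(axis=1)
    u = (rng or np.random.default_rng()).uniform(size=len(n_ge))
    return (n_gt + u * (n_ge - n_gt)) / len(idx_sets)


def diff_localization(
    lrtab: LRTable,
    condition1: str,
    condition2: str,
    method: str = "welch",
    randomize_permutation: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Test each gene for an LR change between two conditions.

    Returns a DataFrame with lr_cond1, lr_cond2, delta_lr
    (condition2 - condition1), p and Benjamini-Hochberg fdr.

    Degenerate zero-variance cases under Welch: equal means give p = 1;
    unequal means (t undefined) fall back to the permutation p.
    """
    x = lrtab.lr[condition1].to_numpy(dtype=float)
    y = lrtab.lr[condition2].to_numpy(dtype=float)
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    delta = y.mean(axis=1) - x.mean(axis=1)

    if method == "welch":
        p, se2 = _welch_vectorized(x, y)
        zerovar = se2 == 0
        if zerovar.any():
            eq = zerovar & (np.abs(delta) < 1e-12)
            p[eq] = 1.0
            hard = zerovar & ~eq
            if hard.any():
                p[hard] = _permutation_pvalues(x[hard], y[hard])
        p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    elif method == "moderated":
        p = _moderated_t(x, y)
    elif method == "permutation":
        p = _permutation_pvalues(
            x, y, randomize=randomize_permutation, rng=rng
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "lr_cond1": x.mean(axis=1),
            "lr_cond2": y.mean(axis=1),
            "delta_lr": delta,
            "p": p,
            "fdr": fdr,
        },
        index=lrtab.genes,
    )


def classify_targets_fdr(
    results: pd.DataFrame, fdr_max: float = 0.01, direction: str | None = "decrease"
) -> pd.DataFrame:
    """Target = FDR below cutoff and (optionally) delta-LR in direction.

    ``direction="decrease"`` requires delta_lr < 0 (impaired localization in
    the second condition); ``None`` disables the direction gate.
    """
    out = results.copy()
    sig = out["fdr"] < fdr_max
    if direction == "decrease":
        sig &= out["delta_lr"] < 0
    elif direction == "increase":
        sig &= out["delta_lr"] > 0
    elif direction is not None:
        raise ValueError(f"unknown direction {direction!r}")
    out["class"] = np.where(sig, "target", "nontarget")
    return out


def classify_targets_lfc(
    results: pd.DataFrame, lfc_min: float = 0.25
) -> pd.DataFrame:
    """Magnitude-only rule for noisy designs: |delta-LR| >= cutoff.

    delta_lr <= -lfc_min -> target (localization decreased);
    delta_lr >= +lfc_min -> nontarget (increased); else unclassified.
    """
    out = results.copy()
    cls = np.full(len(out), "unclassified", dtype=object)
    cls[out["delta_lr"].to_numpy() <= -lfc_min] = "target"
    cls[out["delta_lr"].to_numpy() >= lfc_min] = "nontarget"
    out["class"] = cls
    return out


def compartment_expression_change(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    targets: set[str],
    nontargets: set[str],
    condition1: str,
    condition2: str,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-compartment expression change (cond2 vs cond1) and group tests.

    For each gene and compartment, log2(mean cond2 / mean cond1) of
    normalized counts (plus pseudocount). Returns the per-gene change table
    and, per compartment, the two-sided Wilcoxon rank-sum p comparing the
    changes of targets vs nontargets. A neurite-restricted effect shows up
    as a small neurite p with a near-1 soma p.
    """
    if not targets or not nontargets:
        raise ValueError("empty gene set")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    norm = normalize_counts(counts)
    changes = {}
    for comp in sorted(meta["compartment"].unique()):
        s1 = meta.index[
            (meta["compartment"] == comp) & (meta["condition"] == condition1)
        ]
        s2 = meta.index[
            (meta["compartment"] == comp) & (meta["condition"] == condition2)
        ]
        changes[comp] = np.log2(
            (norm[s2].mean(axis=1) + pseudocount)
            / (norm[s1].mean(axis=1) + pseudocount)
        )
    table = pd.DataFrame(changes)
    pvals = {}
    for comp in table.columns:
        tg = table.loc[table.index.intersection(sorted(targets)), comp]
        ntg = table.loc[table.index.intersection(sorted(nontargets)), comp]
        if len(tg) == 0 or len(ntg) == 0:
            raise ValueError(f"gene set empty after intersection ({comp})")
        pvals[comp] = wilcoxon_rank_sum(tg.to_numpy(), ntg.to_numpy())
    return table, pvals
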