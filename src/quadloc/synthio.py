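"""Synthetic data generation with known ground truth.

Emulates the statistical structure of a soma/neurite fractionation study of
an RNA-binding-protein knockout, at desk scale:

* a transcriptome of 3'UTR sequences in which a planted subset of
  "target" genes carries a four-WGGA-tract G-quadruplex element while the
  background is rejection-sampled to be free of such elements;
* negative-binomial soma/neurite count matrices for two conditions
  (e.g. WT and KO) in which target genes' KO *neurite* means are scaled by
  2^delta_lr (soma unchanged), so the planted effect is a localization
  change, not an expression change;
* K+/Li+ RT-stop tables with potassium-specific stalls immediately 3' of
  each planted quadruplex;
* Bind-n-Seq input/bound read pools in which bound sampling is biased
  toward quadruplex-bearing reads under K+ but not under Li+.

Every generator is a pure function of (config, seed); one global seed
expands to per-stage child seeds by fixed offsets so individual stages can
be re-run reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .gquad import scan_wgga
from .rbns import ReadPool, wgga_matcher

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "plant_g4",
    "plan_truth",
    "make_transcriptome",
    "make_background_regions",
    "simulate_counts",
    "simulate_rt_stops",
    "simulate_rbns",
    "expected_fraction_ratio",
]

# fixed child-seed offsets, one per generator stage
_SEED_TRUTH = 1
_SEED_COUNTS = 2
_SEED_RTSTOP = 3
_SEED_RBNS = 4
_SEED_REGIONS = 5

_MAX_REJECTION_TRIES = 200


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults emulate the scale of the real design at desk size: 2000
    expressed genes, a small planted target set (2.5% -> 50 genes) whose
    neurite localization drops one log2 unit in the knockout, triplicate
    fractionations per condition, negative-binomial dispersion 0.1 and a
    mean sequencing depth of 500 counts per gene per sample. G-quadruplex
    elements are planted in every target 3'UTR and in no nontarget UTR so
    that enrichment directions are unambiguous against truth.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    utr_len_range: tuple[int, int] = (150, 400)
    target_fraction: float = 0.025
    delta_lr_effect: float = -1.0
    nb_dispersion: float = 0.1
    mean_depth: float = 500.0
    g4_prob_target: float = 1.0
    g4_prob_nontarget: float = 0.0
    rbns_enrichment: float = 10.0
    gc_fraction: float = 0.5
    lr_baseline_sd: float = 0.5
    expr_lognormal_sigma: float = 1.0
    conditions: tuple[str, str] = ("WT", "KO")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("g4_prob_target", "g4_prob_nontarget", "target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.utr_len_range[0] > self.utr_len_range[1] or self.utr_len_range[0] < 1:
            raise ValueError("invalid utr_len_range")
        if self.rbns_enrichment < 1:
            raise ValueError("rbns_enrichment must be >= 1")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth that recovery tests assert against."""

    gene_ids: list[str]
    is_target: np.ndarray
    planted_delta_lr: np.ndarray
    utr_lengths: np.ndarray
    has_g4: np.ndarray
    g4_intervals: dict[str, list[tuple[int, int]]]
    seed: int

    def validate(self) -> None:
        if ((self.planted_delta_lr != 0) & ~self.is_target).any():
            raise ValueError("nonzero planted delta on a non-target gene")
        lengths = dict(zip(self.gene_ids, self.utr_lengths))
        for g, ivs in self.g4_intervals.items():
            for s, e in ivs:
                if not 0 <= s < e <= lengths[g]:
                    raise ValueError(f"{g}: interval ({s}, {e}) out of UTR")

    @property
    def target_ids(self) -> list[str]:
        return [g for g, t in zip(self.gene_ids, self.is_target) if t]

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_ids": self.gene_ids,
                "is_target": self.is_target.astype(int).tolist(),
                "planted_delta_lr": self.planted_delta_lr.tolist(),
                "utr_lengths": self.utr_lengths.tolist(),
                "has_g4": self.has_g4.astype(int).tolist(),
                "g4_intervals": {
                    g: [list(iv) for iv in ivs]
                    for g, ivs in self.g4_intervals.items()
                },
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            gene_ids=d["gene_ids"],
            is_target=np.asarray(d["is_target"], dtype=bool),
            planted_delta_lr=np.asarray(d["planted_delta_lr"], dtype=float),
            utr_lengths=np.asarray(d["utr_lengths"], dtype=int),
            has_g4=np.asarray(d["has_g4"], dtype=bool),
            g4_intervals={
                g: [tuple(iv) for iv in ivs]
                for g, ivs in d["g4_intervals"].items()
            },
            seed=d["seed"],
        )


def _composition(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


_BASES = np.array(list("ACGU"))


def _random_seq(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    return "".join(rng.choice(_BASES, size=length, p=_composition(gc)))


def plant_g4(
    utr_sequence: str,
    n_tracts: int = 4,
    linker_range: tuple[int, int] = (0, 6),
    rng: np.random.Generator | None = None,
    w_choices: str = "AU",
) -> tuple[str, tuple[int, int]]:
    """Overwrite a random window of a UTR with a WGGA quadruplex element.

    The element is ``n_tracts`` WGGA tracts (W drawn from ``w_choices``)
    joined by random-nucleotide linkers with lengths drawn uniformly from
    ``linker_range``. Sequence length is unchanged. Returns the new
    sequence and the (start, end) interval of the planted element.
    """
    lo, hi = linker_range
    if not 0 <= lo <= hi:
        raise ValueError("invalid linker_range")
    max_len = 4 * n_tracts + (n_tracts - 1) * hi
    if len(utr_sequence) < max_len:
        raise ValueError(
            f"sequence length {len(utr_sequence)} < maximal element "
            f"length {max_len}"
        )
    rng = rng or np.random.default_rng()
    parts = []
    for i in range(n_tracts):
        if i > 0:
            lk = int(rng.integers(lo, hi + 1))
            parts.append(_random_seq(lk, rng) if lk else "")
        parts.append(str(rng.choice(list(w_choices))) + "GGA")
    element = "".join(parts)
    start = int(rng.integers(0, len(utr_sequence) - len(element) + 1))
    end = start + len(element)
    return utr_sequence[:start] + element + utr_sequence[end:], (start, end)


def plan_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw the planted truth (targets, effects, UTR lengths, G4 carriers).

    Does not build sequences; ``make_transcriptome`` fills in planted
    intervals when sequences are generated. Deterministic per config.
    """
    rng = np.random.default_rng(config.seed + _SEED_TRUTH)
    n = config.n_genes
    width = len(str(max(n, 1)))
    gene_ids = [f"gene{i:0{width}d}" for i in range(1, n + 1)]
    n_targets = int(round(n * config.target_fraction))
    is_target = np.zeros(n, dtype=bool)
    is_target[rng.choice(n, size=n_targets, replace=False)] = True
    planted = np.where(is_target, config.delta_lr_effect, 0.0)
    lo, hi = config.utr_len_range
    utr_lengths = rng.integers(lo, hi + 1, size=n)
    p_g4 = np.where(is_target, config.g4_prob_target, config.g4_prob_nontarget)
    has_g4 = rng.uniform(size=n) < p_g4
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        is_target=is_target,
        planted_delta_lr=planted,
        utr_lengths=np.asarray(utr_lengths, dtype=int),
        has_g4=has_g4,
        g4_intervals={},
        seed=config.seed,
    )
    truth.validate()
    return truth


def _g4_free_seq(
    length: int, rng: np.random.Generator, gc: float
) -> str:
    """Rejection-sample a background sequence with zero WGGA-element matches."""
    for _ in range(_MAX_REJECTION_TRIES):
        s = _random_seq(length, rng, gc)
        if not scan_wgga(s):
            return s
    raise RuntimeError(
        f"rejection sampling failed after {_MAX_REJECTION_TRIES} tries "
        f"(length={length}, gc={gc}); composition too G4-prone"
    )


def make_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate 3'UTR sequences plus the planted truth.

    Backgrounds are rejection-sampled to contain no WGGA quadruplex element;
    genes selected as G4 carriers receive one planted element whose interval
    is recorded in the truth.
    """
    truth = plan_truth(config)
    # sequence generation uses a child stream keyed off the same stage seed
    # so plan_truth's draws stay identical whether or not sequences are built
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _SEED_TRUTH]).generate_state(1)[0]
    )
    seqs: dict[str, str] = {}
    for gid, length, g4 in zip(truth.gene_ids, truth.utr_lengths, truth.has_g4):
        s = _g4_free_seq(int(length), rng, config.gc_fraction)
        if g4:
            s, interval = plant_g4(s, rng=rng)
            truth.g4_intervals[gid] = [interval]
        seqs[gid] = s
    truth.validate()
    return seqs, truth


def make_background_regions(
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """G4-free 5'UTR and CDS sequences for every gene (no planting).

    5'UTRs are 50-150 nt, CDS lengths 300-900 nt (multiples of 3);
    both region types are rejection-sampled to be quadruplex-element-free
    so their G4 densities are identically zero by construction.
    """
    rng = np.random.default_rng(
        (seed if seed is not None else config.seed) + _SEED_REGIONS
    )
    utr5, cds = {}, {}
    for gid in truth.gene_ids:
        utr5[gid] = _g4_free_seq(
            int(rng.integers(50, 151)), rng, config.gc_fraction
        )
        cds[gid] = _g4_free_seq(
            3 * int(rng.integers(100, 301)), rng, config.gc_fraction
        )
    return utr5, cds


def simulate_counts(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial soma/neurite counts for both conditions.

    Gene baselines are log-normal across genes; each gene has a baseline
    localization ratio (normal, mean 0) shared by both conditions; the
    planted delta scales the knockout *neurite* mean by 2^delta only.

    Biological overdispersion is modelled at the prep level: each
    (gene, condition, replicate) draws a gamma factor (mean 1, variance
    ``nb_dispersion``) shared by the soma and neurite fractions of that
    prep — the two fractions come from the same physical membrane prep, so
    expression noise is common to the pair and cancels in the localization
    ratio, while residual fraction-level noise is Poisson. Marginally each
    count is negative binomial with variance mu + dispersion * mu^2.
    Per-sample library sizes are jittered +/-20%.

    Returns (counts, meta): genes x samples integer DataFrame and a sample
    sheet with columns sample_id, compartment, condition, replicate.
    """
    rng = np.random.default_rng(config.seed + _SEED_COUNTS)
    n = len(truth.gene_ids)
    base = rng.lognormal(mean=0.0, sigma=config.expr_lognormal_sigma, size=n)
    base = base / np.exp(config.expr_lognormal_sigma**2 / 2)  # mean 1
    mu_soma = config.mean_depth * base
    lr0 = rng.normal(0.0, config.lr_baseline_sd, size=n)
    cond1, cond2 = config.conditions
    shape = 1.0 / config.nb_dispersion

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for cond in (cond1, cond2):
        delta = truth.planted_delta_lr if cond == cond2 else 0.0
        mu_neur = mu_soma * 2.0 ** (lr0 + delta)
        for rep in range(1, config.n_replicates + 1):
            bio = rng.gamma(shape, config.nb_dispersion, size=n)  # mean 1
            for comp, mu in (("soma", mu_soma), ("neurite", mu_neur)):
                lib = rng.uniform(0.8, 1.2)
                sid = f"{cond}_{comp}_{rep}"
                cols[sid] = rng.poisson(bio * mu * lib)
                meta_rows.append((sid, comp, cond, rep))
    counts = pd.DataFrame(cols, index=truth.gene_ids)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "compartment", "condition", "replicate"]
    )
    return counts, meta


def simulate_rt_stops(
    truth: SyntheticTruth,
    stop_rate_g4: float = 0.05,
    stop_rate_bg: float = 0.001,
    depth: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """K+/Li+ RT-stop count table with stalls 3' of planted quadruplexes.

    At the position immediately 3' of each planted G4 (its end coordinate)
    the K+ stop count is Binomial(depth, stop_rate_g4); everywhere else —
    and for Li+ everywhere — counts are Binomial(depth, stop_rate_bg).
    """
    for r in (stop_rate_g4, stop_rate_bg):
        if not 0 < r <= 1:
            raise ValueError("stop rates must be in (0, 1]")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return pd.DataFrame(
            columns=["transcript_id", "position", "count_K", "count_Li"]
        )
    rng = np.random.default_rng(
        (seed if seed is not None else truth.seed) + _SEED_RTSTOP
    )
    tids, positions, k_rates = [], [], []
    for gid, length in zip(truth.gene_ids, truth.utr_lengths):
        length = int(length)
        pos = np.arange(length)
        rates = np.full(length, stop_rate_bg)
        for _, e in truth.g4_intervals.get(gid, []):
            if e < length:
                rates[e] = stop_rate_g4
        tids.append(np.repeat(gid, length))
        positions.append(pos)
        k_rates.append(rates)
    tid_arr = np.concatenate(tids)
    pos_arr = np.concatenate(positions)
    k_rate_arr = np.concatenate(k_rates)
    count_k = rng.binomial(depth, k_rate_arr)
    count_li = rng.binomial(depth, stop_rate_bg, size=len(k_rate_arr))
    return pd.DataFrame(
        {
            "transcript_id": tid_arr,
            "position": pos_arr,
            "count_K": count_k,
            "count_Li": count_li,
        }
    )


def expected_fraction_ratio(fraction_input: float, enrichment: float) -> float:
    """Weight-implied bound/input motif-fraction ratio.

    If matching reads are sampled into the bound pool with weight E and
    non-matching reads with weight 1, the expected bound fraction is
    E*f / (E*f + (1-f)) for input fraction f, so the ratio is
    E / (E*f + 1 - f).
    """
    f = fraction_input
    return enrichment / (enrichment * f + 1.0 - f)


def simulate_rbns(
    read_len: int = 40,
    n_reads: int = 100_000,
    enrichment: float = 10.0,
    condition: str = "K",
    g4_fraction: float = 0.1,
    matcher: Callable[[str], bool] | None = None,
    seed: int | None = None,
) -> tuple[ReadPool, ReadPool]:
    """Simulate Bind-n-Seq input and bound pools.

    Input reads are random ``read_len``-mers; a ``g4_fraction`` subset
    carries a planted WGGA quadruplex element so the motif class is
    represented at a measurable frequency in a desk-scale pool. The bound
    pool resamples input reads with replacement, weighting motif-matching
    reads by ``enrichment`` under K+ and uniformly (weight 1 for all reads)
    under Li+ — folded quadruplexes do not exist in lithium.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if condition not in ("K", "Li"):
        raise ValueError("condition must be 'K' or 'Li'")
    rng = np.random.default_rng(
        (seed if seed is not None else 0) + _SEED_RBNS
    )
    matcher = matcher or wgga_matcher()
    flat = rng.choice(_BASES, size=(n_reads, read_len))
    reads = ["".join(row) for row in flat]
    n_plant = int(round(g4_fraction * n_reads))
    for i in rng.choice(n_reads, size=n_plant, replace=False):
        reads[i], _ = plant_g4(reads[i], rng=rng)
    flags = np.fromiter((matcher(r) for r in reads), dtype=bool, count=n_reads)
    if condition == "K":
        w = np.where(flags, enrichment, 1.0)
    else:
        w = np.ones(n_reads)
    idx = rng.choice(n_reads, size=n_reads, replace=True, p=w / w.sum())
    bound = [reads[i] for i in idx]
    return (
        ReadPool(reads=reads, condition=condition, role="input"),
        ReadPool(reads=bound, condition=condition, role="bound"),
    )
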