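"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the WGGA oracle
works on tract-position boolean arrays (and a literal triple loop for small
inputs), the statistics oracles enumerate 2x2 tables / binomial terms /
rank permutations directly.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def is_wgga_tract(seq: str, i: int) -> bool:
    return i + 4 <= len(seq) and seq[i] in "AU" and seq[i + 1 : i + 4] == "GGA"


def wgga_offsets_literal(seq: str, linker_max: int = 6) -> list[int]:
    """All offsets with a four-tract element, by exhaustive linker triples."""
    out = []
    for i in range(len(seq)):
        found = False
        for l1 in range(linker_max + 1):
            for l2 in range(linker_max + 1):
                for l3 in range(linker_max + 1):
                    p2 = i + 4 + l1
                    p3 = p2 + 4 + l2
                    p4 = p3 + 4 + l3
                    if (
                        is_wgga_tract(seq, i)
                        and is_wgga_tract(seq, p2)
                        and is_wgga_tract(seq, p3)
                        and is_wgga_tract(seq, p4)
                    ):
                        out.append(i)
                        found = True
                        break
                if found:
                    break
            if found:
                break
    return out


def wgga_minimal_linkers(seq: str, i: int, linker_max: int = 6):
    """Lexicographically smallest feasible (l1, l2, l3) at offset i, or None."""
    for l1 in range(linker_max + 1):
        for l2 in range(linker_max + 1):
            for l3 in range(linker_max + 1):
                p2 = i + 4 + l1
                p3 = p2 + 4 + l2
                p4 = p3 + 4 + l3
                if (
                    is_wgga_tract(seq, i)
                    and is_wgga_tract(seq, p2)
                    and is_wgga_tract(seq, p3)
                    and is_wgga_tract(seq, p4)
                ):
                    return (l1, l2, l3)
    return None


def wgga_offsets_fast(seq: str, linker_max: int = 6) -> np.ndarray:
    """Vectorized version of the exhaustive scan (tract-chain reachability)."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(a)
    tract = np.zeros(n, dtype=bool)
    if n >= 4:
        w = (a[: n - 3] == ord("A")) | (a[: n - 3] == ord("U"))
        tract[: n - 3] = (
            w
            & (a[1 : n - 2] == ord("G"))
            & (a[2 : n - 1] == ord("G"))
            & (a[3:n] == ord("A"))
        )
    reach = tract.copy()
    for _ in range(3):
        nxt = np.zeros(n, dtype=bool)
        for gap in range(linker_max + 1):
            shift = 4 + gap
            if shift < n:
                nxt[: n - shift] |= reach[shift:]
        reach = tract & nxt
    return np.nonzero(reach)[0]


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing tables with probability <= observed."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = comb(n, c1)

    def prob(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p for k in range(lo, hi + 1) if (p := prob(k)) <= p_obs * (1 + 1e-9))


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    return sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1))


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Step-function BH definition, O(m^2): q_i = min_{j >= rank(i)} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    ps = np.sort(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        rank = int(np.searchsorted(ps, pi, side="left"))
        q[i] = min(ps[j] * m / (j + 1) for j in range(rank, m))
    return np.minimum(q, 1.0)


def rank_sum_exact(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments (midranks)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    nx, n = len(x), len(pooled)
    mu = nx * (n + 1) / 2.0
    obs = abs(ranks[:nx].sum() - mu)
    hits = total = 0
    for idx in combinations(range(n), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def cliffs_delta_pairs(x, y) -> float:
    gt = sum(1 for xi in x for yj in y if xi > yj)
    lt = sum(1 for xi in x for yj in y if xi < yj)
    return (gt - lt) / (len(x) * len(y))


def coverage_per_base(region_start, region_end, intervals) -> float:
    """Per-base brute-force union coverage density."""
    covered = 0
    for pos in range(region_start, region_end):
        if any(s <= pos < e for s, e in intervals):
            covered += 1
    return covered / (region_end - region_start)


def kmer_counts_sliding(seqs, k):
    counts: dict[str, int] = {}
    total = 0
    for s in seqs:
        for i in range(len(s) - k + 1):
            total += 1
            km = s[i : i + k]
            if "N" not in km:
                counts[km] = counts.get(km, 0) + 1
    return counts, total
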