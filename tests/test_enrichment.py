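"""Unit and property tests for enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from quadloc import gquad
from quadloc.enrichment import (
    binomial_overlap,
    cliffs_delta,
    conservation_compare,
    count_kmers,
    define_clip_targets,
    effect_size,
    feature_table,
    kmer_enrichment,
    wilcoxon_rank_sum,
)

from oracles import (
    bh_qvalues,
    binomial_upper_tail,
    cliffs_delta_pairs,
    fisher_two_sided,
    kmer_counts_sliding,
    rank_sum_exact,
)

floats = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False, width=32)
samples = st.lists(floats, min_size=1, max_size=8)


class TestCountKmers:
    def test_single_kmer(self):
        counts, total = count_kmers(["AAAAAA"], k=6)
        assert counts == {"AAAAAA": 1} and total == 1

    def test_overlapping_counting_conserves_positions(self):
        counts, total = count_kmers(["GGAGGA"], k=3)
        assert counts == {"GGA": 2, "GAG": 1, "AGG": 1}
        assert total == 4

    def test_n_containing_kmers_skipped_but_positions_counted(self):
        counts, total = count_kmers(["ANAA"], k=2)
        assert total == 3 and counts == {"AA": 1}

    def test_matches_sliding_window_oracle(self, rng):
        seqs = [
            "".join(rng.choice(list("ACGU"), size=rng.integers(3, 40)))
            for _ in range(20)
        ]
        counts, total = count_kmers(seqs, k=4)
        exp_counts, exp_total = kmer_counts_sliding(seqs, 4)
        assert dict(counts) == exp_counts
        assert total == exp_total == sum(max(0, len(s) - 3) for s in seqs)


class TestKmerEnrichment:
    def test_equal_frequencies_give_p_one(self):
        df = kmer_enrichment(["AU" * 10], ["AU" * 10], k=2)
        row = df.set_index("kmer").loc["AU"]
        assert row["p"] == pytest.approx(1.0)

    def test_fisher_p_matches_exhaustive_enumeration(self):
        # 9/10 fg successes vs 1/10 bg: enumerate all 2x2 tables directly
        _, p = stats.fisher_exact([[9, 1], [1, 9]])
        assert p == pytest.approx(202 / 184756)
        assert fisher_two_sided(9, 1, 1, 9) == pytest.approx(202 / 184756)

    def test_fisher_symmetric_under_group_swap(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(0, 30, size=4)
            p1 = stats.fisher_exact([[a, b], [c, d]])[1]
            p2 = stats.fisher_exact([[c, d], [a, b]])[1]
            assert p1 == pytest.approx(p2)

    def test_planted_motif_drives_gga_kmers(self):
        from quadloc import synthio

        cfg = synthio.SimulationConfig(
            n_genes=400, target_fraction=0.25, seed=5
        )
        utr3, truth = synthio.make_transcriptome(cfg)
        tgt = [utr3[g] for g in truth.target_ids]
        bg = [utr3[g] for g in truth.gene_ids if g not in set(truth.target_ids)]
        df = kmer_enrichment(tgt, bg, k=6)
        top = df.head(5)
        assert top["significant"].all()
        assert all("GGA" in k for k in top["kmer"])

    def test_presence_mode_counts_sequences(self):
        df = kmer_enrichment(
            ["AAAA", "AAAA", "CCCC"], ["CCCC"], k=4, mode="presence"
        )
        row = df.set_index("kmer").loc["AAAA"]
        assert row["count_fg"] == 2 and row["total_fg"] == 3


def test_bh_matches_step_function_oracle(rng):
    for _ in range(5):
        p = rng.uniform(size=rng.integers(1, 60))
        _, q, _, _ = multipletests(p, method="fdr_bh")
        assert q == pytest.approx(bh_qvalues(p))


class TestClipTargets:
    def test_triple_intersection(self):
        assert define_clip_targets({"A", "B", "C"}, {"A", "B"}, {"A"}) == {"a"}

    def test_single_list_identity(self):
        assert define_clip_targets(["x", "y"]) == {"x", "y"}

    def test_disjoint_lists_empty(self):
        assert define_clip_targets(["a"], ["b"]) == set()

    def test_version_suffixes_and_case_folded(self):
        assert define_clip_targets(
            ["ENSMUSG001.12"], ["ensmusg001.3"]
        ) == {"ensmusg001"}


class TestBinomialOverlap:
    def test_all_targets_bound_closed_form(self):
        uni = [f"g{i}" for i in range(20)]
        bound = uni[:10]  # background fraction 0.5
        res = binomial_overlap(uni[:10], bound, uni)
        assert res.p == pytest.approx(0.5**10)
        assert res.n_bound == 10

    def test_expected_overlap_fold_near_one(self):
        uni = [f"g{i}" for i in range(100)]
        bound = uni[:25]
        targets = uni[20:40]  # 5 of 20 bound = 0.25
        res = binomial_overlap(targets, bound, uni)
        assert res.fold == pytest.approx(1.0)

    def test_upper_tail_matches_direct_sum(self):
        uni = [f"g{i}" for i in range(80)]
        bound = uni[:20]  # p0 = 0.25
        targets = uni[9:29]  # 11 bound of 20
        res = binomial_overlap(targets, bound, uni)
        assert res.p == pytest.approx(binomial_upper_tail(11, 20, 0.25))

    def test_fold_identity(self):
        uni = [f"g{i}" for i in range(50)]
        res = binomial_overlap(uni[:10], uni[:15], uni)
        assert res.fold * res.background_fraction * res.n_targets == (
            pytest.approx(res.n_bound)
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            binomial_overlap([], [], [])


class TestWilcoxon:
    def test_fully_separated_triplets(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_large_shift_tiny_p(self, rng):
        x = rng.normal(0, 1, 300)
        y = rng.normal(5, 1, 300)
        assert wilcoxon_rank_sum(x, y) < 1e-6

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            x = rng.integers(0, 5, size=rng.integers(2, 5)).astype(float)
            y = rng.integers(0, 5, size=rng.integers(2, 5)).astype(float)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(rank_sum_exact(x, y))

    def test_exact_path_matches_scipy_when_tie_free(self, rng):
        for _ in range(10):
            pool = rng.permutation(100)[:8].astype(float)
            x, y = pool[:4], pool[4:]
            expected = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            assert wilcoxon_rank_sum(x, y) == pytest.approx(expected)


class TestCliffsDelta:
    def test_complete_separation(self):
        assert cliffs_delta([1, 2, 3], [4, 5, 6]) == -1.0

    def test_identical_symmetry(self):
        assert cliffs_delta([1, 2, 3], [1, 2, 3]) == 0.0

    def test_balanced_pairs(self):
        assert cliffs_delta([1, 3], [2]) == 0.0

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 10, size=rng.integers(1, 12)).astype(float)
            y = rng.integers(0, 10, size=rng.integers(1, 12)).astype(float)
            assert cliffs_delta(x, y) == pytest.approx(cliffs_delta_pairs(x, y))

    @given(samples, samples)
    def test_antisymmetric_and_bounded(self, x, y):
        d = cliffs_delta(x, y)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-cliffs_delta(y, x))

    @given(samples, samples)
    def test_invariant_under_monotone_transform(self, x, y):
        d1 = cliffs_delta(x, y)
        f = lambda v: np.arctan(np.asarray(v) / 8.0)  # strictly increasing
        assert cliffs_delta(f(x), f(y)) == pytest.approx(d1)


class TestFeatureTable:
    def test_wgga_density_feature(self):
        utr = {"g": "AGGAAGGAAGGAAGGA" + "C" * 84}
        df = feature_table(["g"], utr3_seqs=utr)
        assert df.loc["g", "utr3_wgga_density"] == pytest.approx(0.01)
        assert df.loc["g", "utr3_length"] == 100

    def test_missing_region_is_nan_not_zero(self):
        df = feature_table(
            ["g"], utr3_seqs={"g": "ACGU"}, cds_seqs={}
        )
        assert np.isnan(df.loc["g"].get("cds_length", np.nan))

    def test_target_density_effect_restricted_to_utr3(self, small_simulation):
        from quadloc.synthio import make_background_regions

        cfg, utr3, truth, _, _ = small_simulation
        utr5, cds = make_background_regions(truth, cfg)
        df = feature_table(
            truth.gene_ids, utr3_seqs=utr3, cds_seqs=cds, utr5_seqs=utr5
        )
        tmask = np.asarray(truth.is_target)
        d_utr3 = cliffs_delta(
            df.loc[tmask, "utr3_wgga_density"],
            df.loc[~tmask, "utr3_wgga_density"],
        )
        d_cds = cliffs_delta(
            df.loc[tmask, "cds_wgga_density"], df.loc[~tmask, "cds_wgga_density"]
        )
        assert d_utr3 > 0.8
        assert abs(d_cds) < 0.1


class TestConservationCompare:
    def _inputs(self, shift=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        seqs = {"t": "G" * 50, "n": "G" * 50}
        masks = {
            "t": gquad.G4Mask("t", np.arange(50) < 25),
            "n": gquad.G4Mask("n", np.arange(50) < 25),
        }
        rows = []
        for g in seqs:
            for pos in range(50):
                s = rng.normal()
                if masks[g].mask[pos]:
                    s += shift
                rows.append((g, pos, s))
        scores = pd.DataFrame(rows, columns=["gene", "position", "score"])
        return scores, seqs, masks, {"t": True, "n": False}

    def test_identical_distributions_give_large_p(self):
        scores, seqs, masks, flags = self._inputs(shift=0.0)
        res = conservation_compare(scores, seqs, masks, flags)
        in_vs_out = res.pairwise_p[((False, True), (True, True))]
        assert in_vs_out > 0.05

    def test_shifted_quadruplex_scores_detected(self):
        scores, seqs, masks, flags = self._inputs(shift=-1.5)
        res = conservation_compare(scores, seqs, masks, flags)
        assert res.pairwise_p[((False, True), (True, True))] < 0.001
        assert res.pairwise_p[((False, False), (True, False))] < 0.001

    def test_empty_group_flagged_not_crashing(self):
        scores, seqs, masks, flags = self._inputs()
        flags = {"t": True, "n": True}  # no nontarget scores at all
        res = conservation_compare(scores, seqs, masks, flags)
        assert np.isnan(res.pairwise_p[((False, False), (True, False))])

    def test_non_g_position_rejected(self):
        scores = pd.DataFrame(
            [("t", 0, 1.0)], columns=["gene", "position", "score"]
        )
        masks = {"t": gquad.G4Mask("t", np.ones(4, bool))}
        with pytest.raises(ValueError, match="not a G"):
            conservation_compare(scores, {"t": "ACGU"}, masks, {"t": True})


def test_effect_size_combines_delta_and_wilcoxon():
    res = effect_size("len", [1, 2, 3], [4, 5, 6])
    assert res.cliffs_delta == -1.0
    assert res.p == pytest.approx(0.1)
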