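"""Bias statistics: KS, rank-sum, Fisher, fold-depletion, stage ratios, FRAP."""

import math
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

import cuic
from cuic.errors import InputError, UndefinedResultError
from cuic.simulate import SimulationConfig, gen_transcripts


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def ks_d_oracle(x, y):
    """D via explicit pointwise ECDF evaluation."""
    pts = sorted(set(x) | set(y))
    d = 0.0
    for t in pts:
        fx = sum(v <= t for v in x) / len(x)
        fy = sum(v <= t for v in y) / len(y)
        d = max(d, abs(fx - fy))
    return d


def permutation_p_oracle(x, y, stat):
    pooled = list(x) + list(y)
    n = len(x)
    obs = stat(x, y)
    hits = total = 0
    for comb_idx in combinations(range(len(pooled)), n):
        chosen = [pooled[i] for i in comb_idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(comb_idx)]
        total += 1
        if stat(chosen, rest) >= obs - 1e-12:
            hits += 1
    return hits / total


def fisher_p_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by hypergeometric enumeration."""
    n, r, col = a + b + c + d, a + b, a + c
    denom = comb(n, col)
    probs = {}
    for k in range(max(0, r + col - n), min(r, col) + 1):
        probs[k] = Fraction(comb(r, k) * comb(n - r, col - k), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestKS:
    def test_identical_samples_have_zero_d(self):
        d, p = cuic.ks_two_sample([1, 2, 3], [3, 2, 1])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_samples(self):
        d, p = cuic.ks_two_sample([1, 2, 3], [4, 5, 6], mode="exact")
        assert d == 1.0
        assert p == pytest.approx(2 / 20)

    def test_exact_matches_independent_enumeration(self, rng):
        for _ in range(25):
            x = rng.normal(size=int(rng.integers(2, 6))).round(1)
            y = rng.normal(size=int(rng.integers(2, 6))).round(1)
            d, p = cuic.ks_two_sample(x, y, mode="exact")
            assert d == pytest.approx(ks_d_oracle(list(x), list(y)))
            assert p == pytest.approx(
                permutation_p_oracle(list(x), list(y), ks_d_oracle)
            )

    def test_d_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(loc=0.7, size=15)
        d0, _ = cuic.ks_two_sample(x, y)
        d1, _ = cuic.ks_two_sample(np.exp(x), np.exp(y))
        d2, _ = cuic.ks_two_sample(x**3, y**3)
        assert d0 == pytest.approx(d1) == pytest.approx(d2)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            cuic.ks_two_sample([], [1.0])

    def test_asymptotic_p_tracks_permutation_p_at_large_n(self, rng):
        """At n = m = 100 the asymptotic p approximates a seeded Monte-Carlo
        permutation p within 0.05 (the permutation distribution is too
        discrete for that to hold at very small n)."""
        n = 100
        for loc in (0.0, 0.2, 0.5):
            x, y = rng.normal(size=n), rng.normal(loc=loc, size=n)
            d, p_asym = cuic.ks_two_sample(x, y)
            pooled = np.concatenate([x, y])
            hits = 0
            n_perm = 2000
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                hits += cuic.stats.ks_statistic(perm[:n], perm[n:]) >= d - 1e-12
            assert abs(p_asym - hits / n_perm) < 0.05

    def test_agrees_with_scipy_asymptotic(self, rng):
        x, y = rng.normal(size=40), rng.normal(0.4, size=55)
        d, p = cuic.ks_two_sample(x, y)
        ref = sps.ks_2samp(x, y, method="asymp")
        assert (d, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))


class TestRankSum:
    def test_separated_samples(self):
        u, p = cuic.rank_sum_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0 and p == pytest.approx(2 / 20)

    def test_tied_singletons_get_midrank(self):
        u, _ = cuic.rank_sum_test([1.0], [1.0], mode="exact")
        assert u == 0.5

    def test_label_swap_symmetry(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=7)
        u_xy, p_xy = cuic.rank_sum_test(x, y)
        u_yx, p_yx = cuic.rank_sum_test(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))
        assert p_xy == pytest.approx(p_yx)

    def test_exact_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 6)))
            y = rng.normal(size=int(rng.integers(2, 6)))
            u, p = cuic.rank_sum_test(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected_p",
        [([[2, 0], [0, 2]], 1 / 3), ([[1, 1], [1, 1]], 1.0), ([[0, 5], [5, 0]], 1 / 126)],
    )
    def test_enumerable_tables(self, table, expected_p):
        _, p = cuic.fisher_exact_2x2(table)
        assert p == pytest.approx(expected_p)

    def test_matches_rational_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            _, p = cuic.fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_p_oracle(a, b, c, d), rel=1e-9)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            t = rng.integers(0, 20, size=(2, 2))
            if t.sum() == 0:
                continue
            odds, p = cuic.fisher_exact_2x2(t)
            ref_odds, ref_p = sps.fisher_exact(t)
            assert p == pytest.approx(ref_p, rel=1e-6)
            if math.isfinite(odds) and not math.isnan(odds):
                assert odds == pytest.approx(ref_odds)

    def test_invariant_under_simultaneous_row_and_column_swap(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            _, p1 = cuic.fisher_exact_2x2([[a, b], [c, d]])
            _, p2 = cuic.fisher_exact_2x2([[d, c], [b, a]])
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            cuic.fisher_exact_2x2([[0, 0], [0, 0]])


class TestDepletion:
    def test_five_fold_example(self):
        idx = {f"n{i}": (0.9 if i < 10 else 0.1) for i in range(50)}
        idx.update({f"a{i}": (0.9 if i < 2 else 0.1) for i in range(50)})
        abundant = {f"a{i}" for i in range(50)}
        assert cuic.depletion_fold(idx, abundant) == pytest.approx(5.0)

    def test_equal_fractions_give_one(self):
        idx = {"a": 0.9, "b": 0.1, "c": 0.9, "d": 0.1}
        assert cuic.depletion_fold(idx, {"a", "b"}) == pytest.approx(1.0)

    def test_no_high_index_anywhere_is_undefined(self):
        idx = {"a": 0.1, "b": 0.2, "c": 0.3}
        with pytest.raises(UndefinedResultError):
            cuic.depletion_fold(idx, {"a"})

    def test_empty_abundant_high_fraction_is_infinite(self):
        idx = {"a": 0.1, "b": 0.9}
        assert cuic.depletion_fold(idx, {"a"}) == math.inf

    def test_all_baseline_flag(self):
        idx = {"n1": 0.9, "n2": 0.1, "a1": 0.9, "a2": 0.1, "a3": 0.1}
        ab = {"a1", "a2", "a3"}
        non_base = cuic.depletion_fold(idx, ab, baseline="non_abundant")
        all_base = cuic.depletion_fold(idx, ab, baseline="all")
        assert non_base == pytest.approx((1 / 2) / (1 / 3))
        assert all_base == pytest.approx((2 / 5) / (1 / 3))


class TestStageRatios:
    def test_equal_stages_give_zero_log_ratio(self):
        fpkm = {f"t{i}": float(i + 1) for i in range(6)}
        ratios, (d, p) = cuic.stage_ratio_distribution(
            fpkm, dict(fpkm), rp_ids={"t0", "t1"}
        )
        assert all(v == 0.0 for v in ratios.values())
        assert d == 0.0

    def test_zero_pseudocount_with_zero_fpkm_rejected(self):
        with pytest.raises(InputError):
            cuic.stage_ratio_distribution(
                {"a": 0.0, "b": 1.0, "c": 1.0, "d": 1.0},
                {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0},
                rp_ids={"a", "b"},
                pseudocount=0.0,
            )

    def test_no_shared_ids_rejected(self):
        with pytest.raises(InputError):
            cuic.stage_ratio_distribution({"a": 1.0}, {"b": 1.0}, rp_ids=set())

    def test_planted_rp_decline_is_detected(self):
        """A 2-fold RP-specific decline between stages is flagged by KS at
        n = 60 RP vs 600 non-RP transcripts."""
        cfg = SimulationConfig(seed=3, n_rp=60, n_nonrp=600, rp_stage_fold=0.5)
        transcripts, _ = gen_transcripts(cfg)
        early = {t.transcript_id: t.abundance["branching"] for t in transcripts}
        late = {t.transcript_id: t.abundance["refinement"] for t in transcripts}
        rp_ids = {t.transcript_id for t in transcripts if t.is_rp}
        ratios, (_, p) = cuic.stage_ratio_distribution(early, late, rp_ids)
        assert p < 0.01
        rp_med = np.median([v for k, v in ratios.items() if k in rp_ids])
        assert rp_med == pytest.approx(-1.0, abs=0.25)  # log2 of the 2-fold drop


class TestFrap:
    def test_endpoints_and_linearity(self):
        i_pre, i_post = 100.0, 20.0
        rx = cuic.frap_relative_recovery(
            [i_pre, i_post, (i_pre + i_post) / 2], i_pre, i_post
        )
        assert rx.tolist() == [1.0, 0.0, 0.5]

    def test_background_correction(self):
        rx = cuic.frap_relative_recovery(
            [60.0], 110.0, 30.0, background=10.0,
            background_pre=10.0, background_post=10.0,
        )
        assert rx[0] == pytest.approx((50 - 20) / (100 - 20))

    def test_no_bleach_contrast_rejected(self):
        with pytest.raises(UndefinedResultError):
            cuic.frap_relative_recovery([1.0], 10.0, 10.0)


def test_bias_report_summarises_planted_bias():
    from cuic.simulate import calibrate_logistic_bias, gen_biased_abundance, gen_indices

    indices = gen_indices(80, seed=42)
    baseline, beta = calibrate_logistic_bias(list(indices.values()), 30, 5.0)
    fpkm, truth = gen_biased_abundance(indices, beta, seed=42, baseline=baseline)
    res = cuic.bias_report(indices, fpkm)
    assert res.n_abundant + res.n_non_abundant == 80
    assert res.group_hi_mean < res.group_lo_mean  # abundant RPs are surface-biased
    margins = np.array(res.fisher_table)
    assert margins.sum() == 80
    assert res.fold_depletion > 1.0
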