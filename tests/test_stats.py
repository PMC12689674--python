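"""Rank tests against enumeration/permutation oracles; summaries; study runner."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from osteoguide import (
    PerturbationModel,
    StudyDesign,
    friedman_test,
    kruskal_wallis,
    run_study,
    summarize,
    wilcoxon_signed_rank,
)
from osteoguide.stats_report import _signed_rank_distribution


def friedman_permutation_p(x: np.ndarray, stat: float, n_perm: int, seed: int) -> float:
    """Within-block permutation null of the Friedman statistic (vectorised)."""
    rng = np.random.default_rng(seed)
    n, k = x.shape
    ranks = sps.rankdata(x, axis=1)
    perm_idx = np.argsort(rng.random((n_perm, n, k)), axis=2)
    permuted = np.take_along_axis(np.broadcast_to(ranks, (n_perm, n, k)), perm_idx, axis=2)
    rbar = (k + 1) / 2
    ss_treat = n * ((permuted.mean(axis=1) - rbar) ** 2).sum(axis=1)
    ss_total = ((permuted - rbar) ** 2).sum(axis=(1, 2)) / (n * (k - 1))
    null = ss_treat / ss_total
    return float((null >= stat - 1e-12).mean())


def kruskal_permutation_p(groups, stat: float, n_perm: int, seed: int) -> float:
    """Group-label permutation null of the Kruskal-Wallis H (vectorised)."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    tie_counts = np.unique(pooled, return_counts=True)[1]
    corr = 1 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    order = np.argsort(rng.random((n_perm, n_total)), axis=1)
    shuffled = ranks[order]
    h = np.zeros(n_perm)
    start = 0
    for m in sizes:
        h += shuffled[:, start:start + m].sum(axis=1) ** 2 / m
        start += m
    h = (12 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)) / corr
    return float((h >= stat - 1e-12).mean())


class TestFriedman:
    def test_hand_computed_rank_sums(self):
        res = friedman_test([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
        assert res.statistic == pytest.approx(4.0, abs=1e-12)
        assert res.df == 2

    def test_constant_matrix_degenerate(self):
        res = friedman_test(np.ones((4, 3)))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_agrees_with_scipy_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(size=(7, 4))
            ours = friedman_test(x, method="chisq")
            ref = sps.friedmanchisquare(*x.T)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_permutation_oracle(self, rng):
        x = rng.normal(size=(5, 3))
        res = friedman_test(x)
        p_perm = friedman_permutation_p(x, res.statistic, 20_000, seed=4)
        assert abs(res.p_value - p_perm) < 0.03

    @given(seed=st.integers(0, 500))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(6, 3))
        a = friedman_test(x)
        b = friedman_test(np.exp(x))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_missing_cells_rejected(self):
        x = np.ones((3, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_test(x)


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(0.0625, abs=1e-12)
        assert res.method == "exact"

    def test_single_nonzero_difference(self):
        res = wilcoxon_signed_rank([2.5])
        assert res.p_value == 1.0

    def test_antisymmetric_differences_null_case(self):
        d = [1.0, -1.0, 2.0, -2.0, 3.0, -3.0]
        res = wilcoxon_signed_rank(d)
        n = len(d)
        assert res.statistic == pytest.approx(n * (n + 1) / 4)
        assert res.p_value > 0.95

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_distribution_sums_to_one_and_symmetric(self):
        ranks = np.arange(1.0, 9.0)
        dist = _signed_rank_distribution(ranks)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(dist, dist[::-1], atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        d = rng.normal(size=n)
        while np.unique(np.abs(d)).size < n:
            d = rng.normal(size=n)
        res = wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array([np.sum(np.asarray(signs) * ranks)
                       for signs in itertools.product([0, 1], repeat=n)])
        p_two = 2 * min((ws <= w_obs + 1e-12).mean(), (ws >= w_obs - 1e-12).mean())
        assert res.p_value == pytest.approx(min(1.0, p_two), abs=1e-12)

    def test_exact_agrees_with_scipy(self, rng):
        d = rng.normal(size=14)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_approximation_close_to_scipy(self, rng):
        d = rng.normal(0.3, 1.0, size=60)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert ours.method == "approximate"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=0.05)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7, abs=1e-12)

    def test_identical_groups(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])

    def test_agrees_with_scipy(self, rng):
        groups = [rng.normal(size=7), rng.normal(1, 1, size=9), rng.normal(size=5)]
        ours = kruskal_wallis(groups, method="chisq")
        ref = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_permutation_oracle(self, rng):
        groups = [rng.normal(size=5), rng.normal(0.8, 1, size=6), rng.normal(size=4)]
        res = kruskal_wallis(groups)
        p_perm = kruskal_permutation_p(groups, res.statistic, 20_000, seed=8)
        assert abs(res.p_value - p_perm) < 0.03

    @given(seed=st.integers(0, 500))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(size=5), rng.normal(size=6)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)


class TestSummarize:
    def test_type7_quartiles(self):
        df = pd.DataFrame({"v": [1.0, 2, 3, 4, 5], "g": "a"})
        row = summarize(df, "v", "g")[0]
        assert row.median == 3.0
        assert row.iqr == 2.0

    def test_single_value_group(self):
        df = pd.DataFrame({"v": [7.0], "g": "a"})
        row = summarize(df, "v", "g")[0]
        assert row.median == 7.0 and row.iqr == 0.0

    def test_constant_group_whiskers(self):
        df = pd.DataFrame({"v": [2.0] * 6, "g": "a"})
        row = summarize(df, "v", "g")[0]
        assert row.whisker_low == row.whisker_high == 2.0

    def test_whiskers_exclude_outliers_but_stay_in_data(self, rng):
        x = np.concatenate([rng.normal(size=40), [25.0]])
        df = pd.DataFrame({"v": x, "g": "a"})
        row = summarize(df, "v", "g")[0]
        assert row.whisker_high < 25.0
        assert row.whisker_low >= x.min()

    def test_all_nan_group_omitted(self):
        df = pd.DataFrame({"v": [1.0, np.nan], "g": ["a", "b"]})
        rows = summarize(df, "v", "g")
        assert [r.group["g"] for r in rows] == ["a"]


def small_design(**kwargs) -> StudyDesign:
    base = dict(designs=("SS", "AS"), heights=(1.0,), instruments=("saw",),
                replicates=2)
    base.update(kwargs)
    return StudyDesign(**base)


class TestRunStudy:
    def test_counts_and_determinism(self, tmp_path):
        d = small_design()
        a = run_study(d, master_seed=3, with_reconstruction=False)
        b = run_study(d, master_seed=3, with_reconstruction=False)
        assert a.tests["counts"] == {"fibulae": 4, "segments": 12,
                                     "planes": 24, "failures": 0}
        pd.testing.assert_frame_equal(a.segments, b.segments)

    def test_zero_noise_deviations_and_pvalues(self):
        d = small_design(designs=("SS", "FS", "AS"))
        zero = PerturbationModel()
        d.perturbation_overrides = {(dsg, h, ins): zero
                                    for _, dsg, h, ins in d.cells()}
        res = run_study(d, master_seed=1, with_reconstruction=False)
        for col in ("d_l_vest", "d_l_ling", "d_angle_prox", "d_angle_dist"):
            assert res.segments[col].abs().max() < 1e-9
        for metric, t in res.tests["slot_design"].items():
            assert t["p_value"] == 1.0

    def test_instrument_difference_power(self):
        """A 2 deg vs 0.5 deg tilt contrast must be detected by the paired
        Wilcoxon in nearly all replicate studies."""
        detected = 0
        n_rep = 15
        for rep in range(n_rep):
            d = StudyDesign(designs=("SS",), heights=(1.0,),
                            instruments=("saw", "piezo"), replicates=5)
            d.perturbation_overrides = {
                ("SS", 1.0, "saw"): PerturbationModel(tilt_sd=2.0),
                ("SS", 1.0, "piezo"): PerturbationModel(tilt_sd=0.5),
            }
            res = run_study(d, master_seed=100 + rep, with_reconstruction=False)
            p = res.tests["instrument"]["d_angle_prox"]["p_value"]
            if p < 0.05:
                detected += 1
        assert detected >= int(0.9 * n_rep)

    def test_outputs_written(self, tmp_path):
        d = small_design(replicates=1)
        run_study(d, master_seed=2, output_dir=tmp_path, with_reconstruction=True)
        for name in ("segments.csv", "planes.csv", "reconstruction.csv",
                     "tests.json", "summaries.csv"):
            assert (tmp_path / name).exists()
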