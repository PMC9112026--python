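"""Rank statistics: exact small-n enumerations, asymptotics, the battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pvgrad import run_association_battery, spearman, wilcoxon_rank_sum
from pvgrad.stats import compare_groups


def brute_spearman_p(x, y):
    """Test-side oracle: direct permutation loop via np.corrcoef of ranks."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= rho_obs - 1e-9:
            count += 1
    return count / total


class TestSpearman:
    def test_worked_example(self):
        """rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 24/120 = 0.8."""
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)
        assert res.method == "exact"

    def test_perfect_monotone(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        up = spearman(x, np.argsort(np.argsort(x)))
        assert up.rho == pytest.approx(1.0)
        down = spearman(x, -np.argsort(np.argsort(x)).astype(float))
        assert down.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed,n", [(0, 5), (1, 6), (2, 7), (3, 8)])
    def test_exact_p_matches_permutation_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        res = spearman(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_spearman_p(x, y), abs=1e-12)

    def test_exact_p_with_ties(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0, 4.0]
        y = [0.5, 2.0, 2.0, 3.0, 5.0, 4.0]
        res = spearman(x, y)
        assert res.p_value == pytest.approx(brute_spearman_p(x, y), abs=1e-12)

    def test_large_n_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.method == "t-approx"
        assert res.rho == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = spearman(x, y)
        b = spearman(np.exp(x), y**3)
        assert a.rho == pytest.approx(b.rho, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(res.rho) and res.method == "undefined"

    def test_incomplete_pairs_dropped(self):
        res = spearman([1, 2, np.nan, 4, 5, 6], [2, 1, 3, np.nan, 5, 6])
        assert res.n == 4

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [2, 1])


class TestRankSum:
    def test_worked_example_exact(self):
        """a=[1,2,3] vs b=[4,5,6]: 2 of C(6,3)=20 assignments as extreme."""
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=6)
        b = rng.normal(size=5)
        r1 = wilcoxon_rank_sum(a, b)
        r2 = wilcoxon_rank_sum(a + 100.0, b + 100.0)
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            res = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_large_n_matches_scipy_ranksums(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=25)
        b = rng.normal(0.5, 1, size=30)
        res = wilcoxon_rank_sum(a, b)
        ref = sps.ranksums(a, b)  # no ties here, so tie correction is inert
        assert res.method == "normal-approx"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tie_correction_matches_mannwhitney(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 5, size=20).astype(float)
        b = rng.integers(1, 6, size=18).astype(float)
        res = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_small_n_matches_enumeration_with_ties(self):
        a = [1.0, 2.0, 2.0, 5.0]
        b = [2.0, 3.0, 4.0]
        res = wilcoxon_rank_sum(a, b)
        ranks = sps.rankdata(np.concatenate([a, b]))
        mu = len(a) * (len(ranks) + 1) / 2
        obs = abs(ranks[:4].sum() - mu)
        count = sum(
            1
            for combo in itertools.combinations(range(7), 4)
            if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9
        )
        assert res.p_value == pytest.approx(count / 35)


def synthetic_gradients(n_subjects=12, seed=0, coupled=True):
    """Gradient table + subject table with the battery's default layout."""
    rng = np.random.default_rng(seed)
    sids = [f"p{i}" for i in range(n_subjects)]
    severity = rng.uniform(0.5, 2.5, n_subjects)
    edss = np.clip(np.round((2 + 2 * severity + rng.normal(0, 0.3, n_subjects)) * 2) / 2, 0, 10)
    rows = []
    for compartment in ("NAWM", "lesion"):
        for metric in ("mean_abs_z", "volume_fraction"):
            for pair in ("1-2", "1-5", "1-10", "1-20", "1-30"):
                for tau in (0.0, 1.0, 2.0, 3.0):
                    for sid, s in zip(sids, severity):
                        signal = s if coupled else rng.normal()
                        rows.append(
                            {
                                "subject_id": sid,
                                "compartment": compartment,
                                "metric": metric,
                                "pair": pair,
                                "tau": tau,
                                "value": signal + rng.normal(0, 0.2),
                            }
                        )
    subjects = pd.DataFrame(
        {
            "subject_id": sids,
            "edss": edss,
            "lesion_count": rng.poisson(20, n_subjects),
            "lesion_volume_mm3": rng.gamma(5, 100, n_subjects),
        }
    )
    return pd.DataFrame(rows), subjects


class TestBattery:
    def test_row_count_is_82(self):
        gradients, subjects = synthetic_gradients()
        out = run_association_battery(gradients, subjects)
        assert len(out) == 82  # 2 compartments x 2 metrics x 5 pairs x 4 taus + 2

    def test_coupled_signal_detected_and_conventional_not(self):
        gradients, subjects = synthetic_gradients(n_subjects=30, seed=1)
        out = run_association_battery(gradients, subjects)
        grad_rows = out[out.compartment != "conventional"]
        conv_rows = out[out.compartment == "conventional"]
        assert grad_rows.rho.median() > 0.7
        assert conv_rows.rho.abs().max() < 0.6

    def test_requires_three_edss(self):
        gradients, subjects = synthetic_gradients(n_subjects=4)
        subjects.loc[1:, "edss"] = np.nan
        with pytest.raises(ValueError, match="at least 3"):
            run_association_battery(gradients, subjects)

    def test_bh_adjustment_column(self):
        gradients, subjects = synthetic_gradients()
        out = run_association_battery(gradients, subjects, adjust=True)
        assert "p_bh" in out.columns
        ok = np.isfinite(out.p_bh)
        assert (out.p_bh[ok] >= out.p_value[ok] - 1e-12).all()

    def test_null_coupling_gives_null_rhos(self):
        gradients, subjects = synthetic_gradients(n_subjects=40, seed=2, coupled=False)
        out = run_association_battery(gradients, subjects)
        grad_rows = out[out.compartment != "conventional"]
        assert abs(grad_rows.rho.mean()) < 0.15
        assert (grad_rows.p_value < 0.05).mean() < 0.25

    def test_group_comparison_battery(self):
        gradients, subjects = synthetic_gradients(n_subjects=20, seed=3)
        subjects["group"] = ["earlyMS"] * 10 + ["progressiveMS"] * 10
        # shift progressive values upward in the gradients
        prog = subjects.subject_id[subjects.group == "progressiveMS"]
        gradients.loc[gradients.subject_id.isin(prog), "value"] += 5.0
        out = compare_groups(gradients, subjects)
        assert len(out) == 80
        assert (out.p_value < 0.05).mean() > 0.9
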