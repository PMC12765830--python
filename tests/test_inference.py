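"""t tests, gatekeeping sequence, Wilcoxon rank-sum, Fisher exact."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from paintrial import (
    GatekeepingPlan,
    fisher_exact_2x2,
    gatekept_primary_analysis,
    two_sample_t,
    two_sample_t_from_summary,
    wilcoxon_rank_sum,
)
from paintrial.inference import CONFIRMATORY, EXPLORATORY
from paintrial.records import ContractError


class TestTwoSampleT:
    def test_constant_equal_samples_are_null(self):
        res = two_sample_t([3.0, 3.0, 3.0], [3.0, 3.0])
        assert res.difference == 0 and res.p == 1.0

    def test_pooled_p_matches_closed_form_on_3v3(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = two_sample_t(x, y)
        # independent closed-form check
        sp2 = (np.var(x, ddof=1) * 2 + np.var(y, ddof=1) * 2) / 4
        t = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (2 / 3))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 4))
        assert res.p == pytest.approx(0.1962611781, rel=1e-8)

    def test_summary_mode_reproduces_printed_contrast(self):
        res = two_sample_t_from_summary(-61.15, 28.25, 132, -49.63, 29.35, 131)
        assert round(res.difference, 2) == -11.52
        assert res.p < 0.05
        assert res.ci[0] < res.difference < res.ci[1]

    def test_welch_matches_reference_implementation(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        res = two_sample_t(x, y, variance_mode="welch")
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.p == pytest.approx(ref.pvalue)

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        a, b = two_sample_t(x, y), two_sample_t(y, x)
        assert a.p == pytest.approx(b.p)
        assert a.difference == pytest.approx(-b.difference)

    def test_small_samples_rejected(self):
        with pytest.raises(ContractError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_ci_covers_true_shift_at_nominal_rate(self):
        rng = np.random.default_rng(77)
        delta, n, reps = 1.0, 25, 2000
        covered = 0
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            x = rng.normal(delta, 1, n)
            res = two_sample_t(x, y)
            covered += res.ci[0] <= delta <= res.ci[1]
        rate = covered / reps
        assert abs(rate - 0.95) < 3 * math.sqrt(0.95 * 0.05 / reps)


class TestGatekeeping:
    def _panel(self, shift1, shift2, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "placebo": rng.normal(0, 1, n),
            "tegileridine_1_0": rng.normal(shift1, 1, n),
            "tegileridine_0_75": rng.normal(shift2, 1, n),
        }

    def test_significant_first_test_opens_the_gate(self):
        results = gatekept_primary_analysis(self._panel(1.0, 1.0))
        assert [r.status for r in results] == [CONFIRMATORY, CONFIRMATORY]
        assert all(r.p < 0.05 for r in results)

    def test_failed_first_test_closes_the_gate(self):
        panel = self._panel(0.0, 1.5, seed=3)
        first = two_sample_t(panel["tegileridine_1_0"], panel["placebo"])
        assert first.p >= 0.05  # premise of the scenario
        results = gatekept_primary_analysis(panel)
        assert results[0].status == CONFIRMATORY
        assert results[1].status == EXPLORATORY
        assert results[1].p < 0.05  # small p yet only exploratory

    def test_missing_arm_is_contract_error(self):
        with pytest.raises(ContractError):
            gatekept_primary_analysis({"placebo": [1.0, 2.0]})

    def test_unadjusted_p_values_pass_through(self):
        panel = self._panel(1.0, 1.0, seed=5)
        results = gatekept_primary_analysis(panel)
        direct = two_sample_t(panel["tegileridine_1_0"], panel["placebo"], level=0.95)
        assert results[0].p == pytest.approx(direct.p)


class TestWilcoxon:
    def test_fully_separated_small_samples(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_matches_full_enumeration(self):
        x, y = [1.0, 4.0, 2.5], [2.5, 3.0, 5.0, 0.5]
        _, p = wilcoxon_rank_sum(x, y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        mu = 3 * 8 / 2
        d_obs = abs(ranks[:3].sum() - mu)
        hits = sum(
            1
            for idx in combinations(range(7), 3)
            if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-12
        )
        assert p == pytest.approx(hits / math.comb(7, 3))

    def test_large_sample_null_rejection_rate(self):
        rng = np.random.default_rng(15)
        reps, hits = 400, 0
        for _ in range(reps):
            _, p = wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
            hits += p < 0.05
        assert 0.015 <= hits / reps <= 0.095

    def test_symmetry_under_swap(self):
        x, y = [1.0, 5.0, 7.0, 2.0], [3.0, 3.0, 8.0]
        assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(wilcoxon_rank_sum(y, x)[1])


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_identical_rows_are_null(self):
        assert fisher_exact_2x2([[5, 7], [5, 7]]) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 15, size=(2, 2))
        p_pkg = fisher_exact_2x2(t)
        row1, col1, n = t[0].sum(), t[:, 0].sum(), t.sum()
        lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
        pmf = {x: stats.hypergeom.pmf(x, n, col1, row1) for x in range(lo, hi + 1)}
        p_brute = sum(v for v in pmf.values() if v <= pmf[t[0, 0]] * (1 + 1e-9))
        assert p_pkg == pytest.approx(p_brute, rel=1e-7)

    def test_zero_margin_is_contract_error(self):
        with pytest.raises(ContractError):
            fisher_exact_2x2([[0, 0], [3, 4]])
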