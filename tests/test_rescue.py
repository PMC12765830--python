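"""Exact intervals, survival machinery and consumption summaries."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paintrial import (
    RescueEvent,
    TrialDataset,
    clopper_pearson,
    cumulative_rescue_consumption,
    km_estimate,
    logrank_test,
    no_rescue_proportion,
    time_to_first_rescue,
)
from paintrial.records import ContractError
from tests.conftest import grid_participant


def participant_with_rescues(pid, arm, rescue_times, drug="parecoxib", dose=40.0):
    return grid_participant(
        5,
        pid=pid,
        arm=arm,
        rescues=tuple(RescueEvent(time_h=t, drug=drug, dose=dose) for t in rescue_times),
    )


class TestClopperPearson:
    def test_boundary_cases_are_exact(self):
        assert clopper_pearson(0, 20).lo == 0.0
        assert clopper_pearson(20, 20).hi == 1.0

    def test_printed_interval_for_103_of_131(self):
        ci = clopper_pearson(103, 131, 0.95)
        assert round(ci.lo, 3) == 0.706
        assert round(ci.hi, 3) == 0.853

    def test_interval_brackets_the_point_estimate(self):
        for n in (1, 7, 30):
            for k in range(n + 1):
                ci = clopper_pearson(k, n)
                assert 0 <= ci.lo <= k / n <= ci.hi <= 1

    def test_contract_violations(self):
        with pytest.raises(ContractError):
            clopper_pearson(5, 4)
        with pytest.raises(ContractError):
            clopper_pearson(1, 4, level=1.2)


class TestNoRescueProportion:
    def test_degenerate_arms(self):
        nobody = TrialDataset(
            participants=tuple(
                participant_with_rescues(f"a{i}", "placebo", []) for i in range(6)
            )
        )
        out = no_rescue_proportion(nobody)
        assert out["proportion"].iloc[0] == 1.0 and out["ci_hi"].iloc[0] == 1.0
        everybody = TrialDataset(
            participants=tuple(
                participant_with_rescues(f"b{i}", "placebo", [Fraction(2)])
                for i in range(6)
            )
        )
        out = no_rescue_proportion(everybody)
        assert out["proportion"].iloc[0] == 0.0 and out["ci_lo"].iloc[0] == 0.0

    def test_fisher_p_matches_exhaustive_enumeration(self):
        # arms with 103/131 vs 53/130 no-rescue counts
        from paintrial import fisher_exact_2x2

        a, b, c, d = 103, 28, 53, 77
        p_pkg = fisher_exact_2x2([[a, b], [c, d]])
        row1, col1, n = a + b, a + c, a + b + c + d
        probs = []
        for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
            probs.append((x, stats.hypergeom.pmf(x, n, col1, row1)))
        p_obs = dict(probs)[a]
        p_brute = sum(pr for _, pr in probs if pr <= p_obs * (1 + 1e-9))
        assert p_pkg == pytest.approx(p_brute, rel=1e-8)


class TestTimeToFirstRescue:
    def test_first_event_censoring_and_late_rescue(self):
        ps = (
            participant_with_rescues("p1", "placebo", [Fraction(5), Fraction(9)]),
            participant_with_rescues("p2", "placebo", []),
            participant_with_rescues(
                "p3", "placebo", [Fraction(24) + Fraction(1, 12)]
            ),
        )
        out = time_to_first_rescue(TrialDataset(participants=ps)).set_index("id")
        assert out.loc["p1", "time_h"] == 5.0 and out.loc["p1", "event"]
        assert out.loc["p2", "time_h"] == 24.0 and not out.loc["p2", "event"]
        assert out.loc["p3", "event"] and out.loc["p3", "time_h"] == pytest.approx(24 + 1 / 12)
        # p3 is an event beyond the 24 h window yet still a "no rescue in 24 h"
        assert ps[2].no_rescue_24h


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        sample = pd.DataFrame(
            {"time_h": [2.0, 4.0, 24.0, 24.0], "event": [True, True, False, False]}
        )
        est = km_estimate(sample).set_index("time")
        assert est.loc[2.0, "survival"] == pytest.approx(0.75)
        assert est.loc[4.0, "survival"] == pytest.approx(0.5)

    def test_all_censored_curve_stays_at_one(self):
        sample = pd.DataFrame({"time_h": [24.0] * 5, "event": [False] * 5})
        assert (km_estimate(sample)["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        times = rng.uniform(1, 23, size=25)
        sample = pd.DataFrame({"time_h": times, "event": True})
        est = km_estimate(sample)
        for t, s in zip(est["time"], est["survival"]):
            if t > 0:
                assert s == pytest.approx(np.mean(times > t))


class TestLogrank:
    def test_identical_samples_are_null(self):
        a = pd.DataFrame({"time_h": [2.0, 5.0, 24.0], "event": [True, True, False]})
        stat, p = logrank_test(a, a.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_samples_reject(self):
        a = pd.DataFrame({"time_h": [1.0, 2.0, 3.0], "event": True})
        b = pd.DataFrame({"time_h": [24.0] * 3, "event": False})
        stat, p = logrank_test(a, b)
        assert stat > 0 and p < 0.05

    def test_label_swap_symmetry(self):
        a = pd.DataFrame({"time_h": [1.0, 3.0, 24.0], "event": [True, True, False]})
        b = pd.DataFrame({"time_h": [2.0, 24.0, 24.0], "event": [True, False, False]})
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_chi_square_p_close_to_permutation_p(self):
        rng = np.random.default_rng(12)
        a = pd.DataFrame({"time_h": rng.uniform(1, 20, 9), "event": True})
        b = pd.DataFrame({"time_h": rng.uniform(4, 24, 9), "event": True})
        _, p_chi = logrank_test(a, b)
        pooled = pd.concat([a, b], ignore_index=True)
        stat_obs, _ = logrank_test(a, b)
        hits = 0
        reps = 600
        for _ in range(reps):
            idx = rng.permutation(len(pooled))
            pa, pb = pooled.iloc[idx[:9]], pooled.iloc[idx[9:]]
            s, _ = logrank_test(pa, pb)
            hits += s >= stat_obs - 1e-12
        p_perm = hits / reps
        mc_se = math.sqrt(p_perm * (1 - p_perm) / reps) + 1e-3
        assert abs(p_chi - p_perm) < 4 * mc_se + 0.03


class TestConsumption:
    def test_zero_fill_mean(self):
        ps = (
            participant_with_rescues("p1", "placebo", []),
            participant_with_rescues("p2", "placebo", []),
            participant_with_rescues("p3", "placebo", [Fraction(2)], dose=2.0),
            participant_with_rescues("p4", "placebo", [Fraction(3)], dose=2.0),
        )
        out = cumulative_rescue_consumption(TrialDataset(participants=ps))
        row = out[(out["arm"] == "placebo") & (out["drug"] == "parecoxib")].iloc[0]
        assert row["mean"] == 1.0 and row["n"] == 4

    def test_single_user_and_nonusers(self):
        ps = tuple(
            participant_with_rescues(f"p{i}", "placebo", [Fraction(2)] if i == 0 else [], dose=5.0)
            for i in range(5)
        )
        out = cumulative_rescue_consumption(TrialDataset(participants=ps))
        row = out[(out["arm"] == "placebo") & (out["drug"] == "parecoxib")].iloc[0]
        assert row["mean"] == 1.0

    def test_unused_drug_mean_and_sd_zero(self):
        ps = (participant_with_rescues("p1", "placebo", []),)
        out = cumulative_rescue_consumption(TrialDataset(participants=ps))
        suf = out[out["drug"] == "sufentanil"].iloc[0]
        assert suf["mean"] == 0.0 and suf["sd"] == 0.0
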