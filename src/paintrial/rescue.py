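"""Rescue-medication outcomes.

No-rescue proportions with exact (Clopper-Pearson) binomial intervals and
Fisher tests against a reference arm; time to first rescue as a
right-censored survival sample (non-users censored at 24 h) with
Kaplan-Meier estimation and log-rank comparisons; cumulative consumption
per drug with the zero-fill convention (non-users count as 0 in the arm
mean and SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .records import ContractError, RESCUE_DRUGS, TrialDataset, TrialValidationError

__all__ = [
    "ProportionCI",
    "clopper_pearson",
    "no_rescue_proportion",
    "time_to_first_rescue",
    "km_estimate",
    "logrank_test",
    "cumulative_rescue_consumption",
]


@dataclass(frozen=True)
class ProportionCI:
    """An exact binomial proportion k/n with its confidence bounds."""

    k: int
    n: int
    level: float
    lo: float
    hi: float

    @property
    def proportion(self) -> float:
        return self.k / self.n


def clopper_pearson(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact binomial interval from beta quantiles.

    The lower bound is the beta(k, n-k+1) quantile at (1-level)/2 (exactly 0
    when k = 0) and the upper the beta(k+1, n-k) quantile at 1-(1-level)/2
    (exactly 1 when k = n).
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ContractError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ContractError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < level < 1:
        raise ContractError(f"level {level} outside (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(k=int(k), n=int(n), level=level, lo=lo, hi=hi)


def no_rescue_proportion(
    dataset: TrialDataset,
    level: float = 0.95,
    reference_arm: str = "placebo",
) -> pd.DataFrame:
    """Per-arm proportion of participants with no rescue use in (0, 24].

    Returns one row per arm present in the dataset, with the exact interval
    and a Fisher exact p against the reference arm (NaN for the reference
    itself).  The denominator is the full analysis-set arm size.
    """
    from .inference import fisher_exact_2x2

    by_arm = {a: ps for a, ps in dataset.by_arm().items() if ps}
    if not by_arm:
        raise ContractError("dataset has no participants")
    if reference_arm not in by_arm:
        raise ContractError(f"reference arm {reference_arm!r} is empty or absent")
    counts = {a: sum(1 for p in ps if p.no_rescue_24h) for a, ps in by_arm.items()}
    sizes = {a: len(ps) for a, ps in by_arm.items()}
    rows = []
    for arm in by_arm:
        ci = clopper_pearson(counts[arm], sizes[arm], level)
        if arm == reference_arm:
            p = float("nan")
        else:
            table = [
                [counts[arm], sizes[arm] - counts[arm]],
                [counts[reference_arm], sizes[reference_arm] - counts[reference_arm]],
            ]
            if table[0][0] + table[1][0] == 0 or table[0][1] + table[1][1] == 0:
                p = 1.0  # all users or all non-users in both arms: no information
            else:
                p = fisher_exact_2x2(table)
        rows.append(
            {
                "arm": arm,
                "k": ci.k,
                "n": ci.n,
                "proportion": ci.proportion,
                "ci_lo": ci.lo,
                "ci_hi": ci.hi,
                "fisher_p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows)


def time_to_first_rescue(dataset: TrialDataset) -> pd.DataFrame:
    """Per-participant first rescue time; non-users censored at 24 h.

    A rescue recorded slightly beyond 24 h counts as an event at its
    recorded time (it stays in the analysis even though it falls outside
    the 24 h no-rescue window).
    """
    rows = []
    for p in dataset.participants:
        first = p.first_rescue
        if first is not None and first.time_h <= 0:
            raise ContractError(f"{p.id}: rescue at time {first.time_h} <= 0")
        if first is None:
            rows.append({"id": p.id, "arm": p.arm, "time_h": 24.0, "event": False})
        else:
            rows.append(
                {"id": p.id, "arm": p.arm, "time_h": float(first.time_h), "event": True}
            )
    return pd.DataFrame(rows, columns=["id", "arm", "time_h", "event"])


def km_estimate(sample: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate of a (time_h, event) sample.

    Returns the right-continuous step function as rows (time, survival,
    at_risk), one per distinct event/censoring time, beginning at t=0 with
    survival 1.
    """
    if len(sample) == 0:
        raise ContractError("survival sample is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(sample["time_h"].to_numpy(), sample["event"].to_numpy().astype(bool))
    surv = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    return pd.DataFrame(
        {"time": surv.index.to_numpy(float), "survival": surv.to_numpy(float),
         "at_risk": at_risk.to_numpy(float)}
    )


def logrank_test(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Unstratified two-sample log-rank test (chi-square, 1 df, two-sided).

    Returns ``(statistic, p)``.  Identical samples give statistic 0, p 1.
    """
    if len(a) == 0 or len(b) == 0:
        raise ContractError("both survival samples must be non-empty")
    res = _ll_logrank(
        a["time_h"].to_numpy(),
        b["time_h"].to_numpy(),
        event_observed_A=a["event"].to_numpy().astype(int),
        event_observed_B=b["event"].to_numpy().astype(int),
    )
    return float(res.test_statistic), float(res.p_value)


def cumulative_rescue_consumption(dataset: TrialDataset) -> pd.DataFrame:
    """Per-arm, per-drug mean (SD) cumulative dose over (0, 24], zero-filled.

    Every participant contributes to the denominator; non-users contribute
    a total of 0, so the mean is total consumption divided by the arm size.
    """
    by_arm = {a: ps for a, ps in dataset.by_arm().items() if ps}
    rows = []
    for arm, ps in by_arm.items():
        for drug in RESCUE_DRUGS:
            totals = []
            for p in ps:
                doses = [r.dose for r in p.rescues if r.drug == drug and 0 < r.time_h <= 24]
                if any(d <= 0 for d in doses):
                    raise TrialValidationError(f"{p.id}: non-positive rescue dose")
                totals.append(sum(doses))
            arr = np.asarray(totals, dtype=float)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            rows.append(
                {"arm": arm, "drug": drug, "n": len(arr), "mean": float(arr.mean()), "sd": sd}
            )
    return pd.DataFrame(rows)
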