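"""Comparative statistics for the trial endpoints.

The primary analysis is a fixed-sequence (gatekeeping) procedure: the high
dose is tested against placebo by a two-sample t test at the full two-sided
alpha; the low dose is tested confirmatorily only if the first test
rejects, otherwise its result is exploratory.  This controls the
familywise type-I error at alpha without adjusting the individual p
values.

"Group t test" is read as the pooled-variance two-sample t (a single SE
per contrast, as the trial's tables report); Welch's unequal-variance form
is available by flag.  Rank and exact tests cover the secondary outcomes:
Wilcoxon rank-sum for consumption and satisfaction, Fisher's exact test
for the no-rescue proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .records import ContractError

__all__ = [
    "ComparisonResult",
    "GatekeepingPlan",
    "two_sample_t",
    "two_sample_t_from_summary",
    "gatekept_primary_analysis",
    "wilcoxon_rank_sum",
    "fisher_exact_2x2",
]

CONFIRMATORY = "confirmatory"
EXPLORATORY = "exploratory"
NOMINAL = "nominal"


@dataclass(frozen=True)
class ComparisonResult:
    """One contrast: difference, its SE, CI, two-sided p and testing status."""

    endpoint: str
    arm: str
    reference: str
    difference: float
    se: float
    ci: tuple[float, float]
    p: float
    status: str = NOMINAL
    n_arm: int = 0
    n_reference: int = 0

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class GatekeepingPlan:
    """Fixed-sequence testing plan: ordered (test arm, reference arm) pairs
    tested each at the full familywise two-sided alpha."""

    hypotheses: tuple[tuple[str, str], ...] = (
        ("tegileridine_1_0", "placebo"),
        ("tegileridine_0_75", "placebo"),
    )
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ContractError(f"alpha {self.alpha} outside (0, 1)")
        if not self.hypotheses:
            raise ContractError("plan must contain at least one hypothesis")


def _t_core(mx, vx, nx, my, vy, ny, variance_mode: str):
    """Difference, SE and df for a two-sample t from summary statistics."""
    if variance_mode == "pooled":
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(sp2 * (1 / nx + 1 / ny))
    elif variance_mode == "welch":
        a, b = vx / nx, vy / ny
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (nx - 1) + b**2 / (ny - 1)) if a + b > 0 else nx + ny - 2
    else:
        raise ContractError(f"variance_mode {variance_mode!r} not in {{pooled, welch}}")
    return mx - my, se, df


def _t_result(diff, se, df, level, endpoint, arm, reference, nx, ny) -> ComparisonResult:
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
        ci = (diff, diff)
    else:
        t = diff / se
        p = float(2 * stats.t.sf(abs(t), df))
        q = float(stats.t.ppf(1 - (1 - level) / 2, df))
        ci = (diff - q * se, diff + q * se)
    return ComparisonResult(
        endpoint=endpoint, arm=arm, reference=reference, difference=diff, se=se,
        ci=ci, p=p, n_arm=nx, n_reference=ny,
    )


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variance_mode: str = "pooled",
    level: float = 0.95,
    endpoint: str = "",
    arm: str = "x",
    reference: str = "y",
) -> ComparisonResult:
    """Two-sample t test of mean(x) - mean(y) with CI at the stated level.

    With zero variance in both samples the p value is 1 when the means are
    equal (and 0 otherwise, the degenerate limit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ContractError("each sample needs at least 2 observations")
    diff, se, df = _t_core(
        x.mean(), x.var(ddof=1), len(x), y.mean(), y.var(ddof=1), len(y), variance_mode
    )
    return _t_result(diff, se, df, level, endpoint, arm, reference, len(x), len(y))


def two_sample_t_from_summary(
    mean_x: float, sd_x: float, n_x: int,
    mean_y: float, sd_y: float, n_y: int,
    variance_mode: str = "pooled",
    level: float = 0.95,
    endpoint: str = "",
    arm: str = "x",
    reference: str = "y",
) -> ComparisonResult:
    """Same contrast computed from printed summary statistics."""
    if n_x < 2 or n_y < 2:
        raise ContractError("each sample needs at least 2 observations")
    diff, se, df = _t_core(mean_x, sd_x**2, n_x, mean_y, sd_y**2, n_y, variance_mode)
    return _t_result(diff, se, df, level, endpoint, arm, reference, n_x, n_y)


def gatekept_primary_analysis(
    panel: Mapping[str, Sequence[float]],
    plan: Optional[GatekeepingPlan] = None,
    variance_mode: str = "pooled",
    endpoint: str = "spid_24",
) -> list[ComparisonResult]:
    """Run the fixed-sequence procedure on per-arm endpoint values.

    *panel* maps arm label to that arm's endpoint values.  Each hypothesis
    is tested in order; a hypothesis is confirmatory only while every
    earlier one rejected at alpha, after which results are exploratory.
    The p values themselves are never adjusted.
    """
    plan = plan or GatekeepingPlan()
    for arm, ref in plan.hypotheses:
        if arm not in panel or ref not in panel:
            raise ContractError(f"arm {arm!r} or {ref!r} missing from the panel")
    results = []
    gate_open = True
    for arm, ref in plan.hypotheses:
        res = two_sample_t(
            panel[arm], panel[ref], variance_mode=variance_mode,
            level=1 - plan.alpha, endpoint=endpoint, arm=arm, reference=ref,
        )
        res = replace(res, status=CONFIRMATORY if gate_open else EXPLORATORY)
        if gate_open and not res.p < plan.alpha:
            gate_open = False
        results.append(res)
    return results


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for the rank-sum, midranks for ties.

    Enumerates all assignments of the midranks to the two groups and sums
    the probability of rank sums at least as far from the null mean as the
    observed one; identical samples give exactly 1.
    """
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined).tolist()
    nx = len(x)
    w_obs = sum(ranks[:nx])
    mu = nx * (len(combined) + 1) / 2.0
    d_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(ranks, nx):
        total += 1
        if abs(sum(idx) - mu) >= d_obs - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank sum of x, two-sided p).

    Exact by enumeration (midranks under ties) when the combined sample is
    at most 20; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ContractError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    nx, ny = len(x), len(y)
    n = nx + ny
    w = float(ranks[:nx].sum())
    if n <= 20:
        return w, _exact_rank_sum_p(x, y)
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    return w, float(2 * stats.norm.sf(max(z, 0.0)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    tables (fixed margins) no more probable than the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ContractError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ContractError("cells must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ContractError("all margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
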