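"""End-to-end orchestration and publication-style reporting.

``run_full_analysis`` drives the whole pipeline — simulate (or load),
select the analysis set, impute, score, analyse, tabulate — and writes
CSV/JSON artefacts plus a run log recording the policy mode, analysis set,
imputation-provenance tallies and software versions.  Rounding mirrors the
usual trial-report conventions: score summaries to 2 decimals, percentages
to 1, p values to 3 with a "<0.001" floor; the reference arm's contrast
cells render as "ND".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .design import DesignSpec, inflate_for_dropout, planned_total, power_at_n, sample_size_two_groups
from .impute import ImputationPolicy, impute_series
from .inference import (
    ComparisonResult,
    GatekeepingPlan,
    NOMINAL,
    gatekept_primary_analysis,
    two_sample_t,
    wilcoxon_rank_sum,
)
from .io import read_trial_csv, write_trial_csv
from .records import (
    ARMS,
    AnalysisSet,
    ContractError,
    TrialDataset,
    arm_sizes,
    select_analysis_set,
)
from .rescue import (
    cumulative_rescue_consumption,
    km_estimate,
    logrank_test,
    no_rescue_proportion,
    time_to_first_rescue,
)
from .scores import SPID_HORIZONS, compute_endpoint_panel
from .simulate import SimulationConfig, default_config, simulate_trial

__all__ = [
    "RunConfig",
    "consort_accounting",
    "make_summary_table",
    "run_full_analysis",
]

_ENDPOINTS = [f"spid_{lbl}" for lbl, _, _ in SPID_HORIZONS] + [
    f"totpar_{lbl}" for lbl, _, _ in SPID_HORIZONS
]


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: either input CSVs or a simulation, plus policies."""

    input_path: Optional[Union[str, Path]] = None
    simulation: Optional[SimulationConfig] = None
    policy: ImputationPolicy = field(default_factory=ImputationPolicy)
    plan: GatekeepingPlan = field(default_factory=GatekeepingPlan)
    design: DesignSpec = field(default_factory=DesignSpec)
    analysis_set: AnalysisSet = AnalysisSet.FAS
    reference_arm: str = "placebo"
    seed: int = 0
    score_decimals: int = 2
    percent_decimals: int = 1

    def __post_init__(self):
        if (self.input_path is None) == (self.simulation is None):
            raise ContractError("exactly one of input_path / simulation must be given")


def consort_accounting(dataset: TrialDataset) -> dict:
    """Disposition counts: randomized, treated, completed per arm plus
    FAS/ITT/SAFETY analysis-set sizes."""
    per_arm = {}
    for arm in ARMS:
        ps = [p for p in dataset.participants if p.arm == arm]
        per_arm[arm] = {
            "randomized": sum(p.randomized for p in ps),
            "treated": sum(p.treated for p in ps),
            "completed": sum(p.completed for p in ps),
        }
    return {
        "total_records": len(dataset),
        "randomized": sum(p.randomized for p in dataset.participants),
        "treated": sum(p.treated for p in dataset.participants),
        "completed": sum(p.completed for p in dataset.participants),
        "per_arm": per_arm,
        "analysis_sets": {
            s.value: len(select_analysis_set(dataset, s)) for s in AnalysisSet
        },
    }


def _fmt_p(p: float, decimals: int = 3) -> str:
    if np.isnan(p):
        return "ND"
    floor = 10**-decimals
    if p < floor:
        return f"<{floor:.{decimals}f}"
    return f"{p:.{decimals}f}"


def make_summary_table(
    comparisons: Sequence[ComparisonResult],
    panels: pd.DataFrame,
    reference_arm: str = "placebo",
    score_decimals: int = 2,
) -> pd.DataFrame:
    """Format the endpoint table: per-arm mean (SD), difference with the
    reference arm (SE), CI and p per endpoint; reference cells are "ND"."""
    d = score_decimals
    by_key = {(c.endpoint, c.arm): c for c in comparisons}
    arms = [a for a in ARMS if a in set(panels["arm"])]
    rows = []
    for ep in _ENDPOINTS:
        if ep not in panels.columns:
            continue
        row = {"endpoint": ep}
        for arm in arms:
            vals = panels.loc[panels["arm"] == arm, ep]
            row[f"{arm}_mean_sd"] = f"{vals.mean():.{d}f} ({vals.std(ddof=1):.{d}f})"
            c = by_key.get((ep, arm))
            if arm == reference_arm or c is None:
                row[f"{arm}_diff_se"] = "ND"
                row[f"{arm}_ci_p"] = "ND"
            else:
                row[f"{arm}_diff_se"] = f"{c.difference:.{d}f} ({c.se:.{d}f})"
                row[f"{arm}_ci_p"] = (
                    f"({c.ci[0]:.{d}f} to {c.ci[1]:.{d}f}); p = {_fmt_p(c.p)} [{c.status}]"
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _compare_endpoints(
    panel: pd.DataFrame, plan: GatekeepingPlan, reference_arm: str
) -> list[ComparisonResult]:
    """Primary endpoint through the gate; all other endpoints nominal."""
    arms = [a for a in ARMS if a in set(panel["arm"])]
    values = {
        ep: {a: panel.loc[panel["arm"] == a, ep].to_numpy() for a in arms}
        for ep in _ENDPOINTS
        if ep in panel.columns
    }
    results = list(gatekept_primary_analysis(values["spid_24"], plan, endpoint="spid_24"))
    gated = {(r.endpoint, r.arm) for r in results}
    for ep, per_arm in values.items():
        for arm in arms:
            if arm == reference_arm or (ep, arm) in gated:
                continue
            results.append(
                two_sample_t(
                    per_arm[arm], per_arm[reference_arm],
                    endpoint=ep, arm=arm, reference=reference_arm,
                )
            )
    return results


def run_full_analysis(config: RunConfig, out_dir: Union[str, Path]) -> dict:
    """Run the full pipeline and write its artefacts under *out_dir*.

    Deterministic given the seed: the same config and seed produce
    byte-identical CSVs.  Returns a bundle of the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        dataset = simulate_trial(config.simulation, seed=config.seed)
        write_trial_csv(dataset, out / "dataset")
    else:
        dataset = read_trial_csv(config.input_path)

    analysis = select_analysis_set(dataset, config.analysis_set)
    consort = consort_accounting(dataset)

    panel = compute_endpoint_panel(analysis, config.policy)
    comparisons = _compare_endpoints(panel, config.plan, config.reference_arm)
    table = make_summary_table(
        comparisons, panel, config.reference_arm, config.score_decimals
    )

    proportions = no_rescue_proportion(analysis, reference_arm=config.reference_arm)
    surv = time_to_first_rescue(analysis)
    curves = []
    logrank_rows = []
    ref_sample = surv[surv["arm"] == config.reference_arm]
    for arm in sorted(set(surv["arm"])):
        est = km_estimate(surv[surv["arm"] == arm])
        est.insert(0, "arm", arm)
        curves.append(est)
        if arm != config.reference_arm and len(ref_sample):
            stat, p = logrank_test(surv[surv["arm"] == arm], ref_sample)
            logrank_rows.append({"arm": arm, "statistic": stat, "p": p})
    consumption = cumulative_rescue_consumption(analysis)
    wilcoxon_rows = []
    for drug in sorted(set(r.drug for p in analysis.participants for r in p.rescues) | set()):
        totals = {
            arm: [
                sum(r.dose for r in p.rescues if r.drug == drug and 0 < r.time_h <= 24)
                for p in analysis.participants
                if p.arm == arm
            ]
            for arm in sorted(set(p.arm for p in analysis.participants))
        }
        for arm, vals in totals.items():
            if arm == config.reference_arm:
                continue
            w, p = wilcoxon_rank_sum(vals, totals[config.reference_arm])
            wilcoxon_rows.append({"endpoint": f"consumption_{drug}", "arm": arm, "p": p})

    design_summary = {
        "evaluable_per_group": sample_size_two_groups(config.design),
        "planned_per_group": inflate_for_dropout(
            sample_size_two_groups(config.design), config.design.dropout_rate
        ),
        "planned_total": planned_total(
            inflate_for_dropout(
                sample_size_two_groups(config.design), config.design.dropout_rate
            ),
            config.design.arms,
        ),
        "power_at_evaluable_n": power_at_n(
            config.design, sample_size_two_groups(config.design)
        ),
    }

    comp_df = pd.DataFrame(
        [
            {
                "endpoint": c.endpoint, "arm": c.arm, "reference": c.reference,
                "difference": c.difference, "se": c.se,
                "ci_lo": c.ci[0], "ci_hi": c.ci[1], "p": c.p, "status": c.status,
            }
            for c in comparisons
        ]
    )
    fmt = "%.10g"
    panel.to_csv(out / "endpoints.csv", index=False, float_format=fmt)
    comp_df.to_csv(out / "comparisons.csv", index=False, float_format=fmt)
    table.to_csv(out / "summary_table.csv", index=False)
    proportions.to_csv(out / "rescue_proportions.csv", index=False, float_format=fmt)
    pd.concat(curves, ignore_index=True).to_csv(out / "survival.csv", index=False, float_format=fmt)
    pd.DataFrame(logrank_rows).to_csv(out / "logrank.csv", index=False, float_format=fmt)
    consumption.to_csv(out / "consumption.csv", index=False, float_format=fmt)
    (out / "design_summary.json").write_text(json.dumps(design_summary, indent=2))

    prov_cols = [c for c in panel.columns if c.startswith("n_")]
    log = {
        "paintrial_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "analysis_set": config.analysis_set.value,
        "imputation_mode": config.policy.mode,
        "strict_rescue": config.policy.strict_rescue,
        "arm_sizes": arm_sizes(analysis),
        "provenance_tallies": {c: int(panel[c].sum()) for c in prov_cols},
    }
    (out / "run_log.txt").write_text(
        "\n".join(f"{k}: {v}" for k, v in log.items()) + "\n"
    )

    return {
        "dataset": dataset,
        "analysis": analysis,
        "consort": consort,
        "panel": panel,
        "comparisons": comparisons,
        "summary_table": table,
        "proportions": proportions,
        "survival": surv,
        "logrank": pd.DataFrame(logrank_rows),
        "consumption": consumption,
        "wilcoxon": pd.DataFrame(wilcoxon_rows),
        "design": design_summary,
    }
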