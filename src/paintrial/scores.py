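"""Time-weighted composite pain endpoints: SPID and TOTPAR.

SPID over a window (s, e] is the sum, over grid points t in that window, of
the pain-intensity difference from baseline (PID_t = PI_t - PI_0) weighted
by the preceding interval length (t - t_prev); TOTPAR weights the pain
relief score PR_t the same way.  On the full protocol grid the weights
telescope to 24 h, so with PI in [0, 10] the theoretical SPID_24 range is
[-240, 240] and with PR in [0, 4] TOTPAR_24 lies in [0, 96].

All interval arithmetic is exact (Fractions); conversion to float happens
only when a panel is rendered to a DataFrame.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional, Union

import pandas as pd

from .impute import ImputationPolicy, ScoreSeries, impute_series
from .records import ContractError, TrialDataset

__all__ = [
    "SPID_HORIZONS",
    "compute_spid",
    "compute_totpar",
    "compute_endpoint_panel",
    "responder_proportion",
]

#: Protocol horizons: (start, end] windows, with plain labels for panels.
SPID_HORIZONS: tuple[tuple[str, Fraction, Fraction], ...] = (
    ("6", Fraction(0), Fraction(6)),
    ("12", Fraction(0), Fraction(12)),
    ("18", Fraction(0), Fraction(18)),
    ("24", Fraction(0), Fraction(24)),
    ("12_24", Fraction(12), Fraction(24)),
)


def _window_terms(series: ScoreSeries, t_start, t_end):
    t_start, t_end = Fraction(t_start), Fraction(t_end)
    if not t_start < t_end:
        raise ContractError(f"t_start {t_start} must be < t_end {t_end}")
    if t_start not in series.times or t_end not in series.times:
        raise ContractError(f"window ({t_start}, {t_end}] endpoints must lie on the grid")
    for prev, t in zip(series.times, series.times[1:]):
        if t_start < t <= t_end:
            yield series.times.index(t), t - prev


def compute_spid(series: ScoreSeries, t_start, t_end) -> Fraction:
    """Summed pain intensity difference over (t_start, t_end], exact."""
    base = series.baseline_pi
    return sum(
        (Fraction(series.pi[i] - base) * w for i, w in _window_terms(series, t_start, t_end)),
        Fraction(0),
    )


def compute_totpar(series: ScoreSeries, t_start, t_end) -> Fraction:
    """Total pain relief over (t_start, t_end], exact and non-negative."""
    return sum(
        (Fraction(series.pr[i]) * w for i, w in _window_terms(series, t_start, t_end)),
        Fraction(0),
    )


def _responder_columns(series: ScoreSeries, threshold: int, upto: Fraction) -> dict[str, bool]:
    cols = {}
    for t, pi in zip(series.times, series.pi):
        if 0 < t <= upto:
            cols[f"resp_{int(t * 60)}min"] = pi <= threshold
    return cols


def compute_endpoint_panel(
    dataset: TrialDataset,
    policy: Optional[ImputationPolicy] = None,
    responder_threshold: int = 3,
    responder_upto: Union[int, Fraction] = Fraction(6),
) -> pd.DataFrame:
    """Per-participant endpoint panel: SPID/TOTPAR at all protocol horizons,
    responder indicators through the stated window, rescue-use flags and the
    (possibly censored) time to first rescue.

    Imputation failures propagate tagged with the participant id.
    """
    policy = policy or ImputationPolicy()
    rows = []
    for p in dataset.participants:
        series = impute_series(p, policy)
        row: dict = {"id": p.id, "arm": p.arm, "completed": p.completed}
        for label, s, e in SPID_HORIZONS:
            row[f"spid_{label}"] = float(compute_spid(series, s, e))
            row[f"totpar_{label}"] = float(compute_totpar(series, s, e))
        row.update(_responder_columns(series, responder_threshold, Fraction(responder_upto)))
        row["no_rescue"] = p.no_rescue_24h
        first = p.first_rescue
        row["time_to_first_rescue"] = float(first.time_h) if first is not None else 24.0
        row["rescued"] = first is not None
        for prov, count in series.provenance_counts().items():
            row[f"n_{prov}"] = count
        rows.append(row)
    panel = pd.DataFrame(rows)
    for col in panel.columns:
        if col.startswith("n_"):
            panel[col] = panel[col].fillna(0).astype(int)
    return panel


def responder_proportion(
    dataset: TrialDataset,
    time,
    threshold: int = 3,
    policy: Optional[ImputationPolicy] = None,
) -> pd.Series:
    """Per-arm fraction of participants whose imputed PI at *time* is <= threshold."""
    time = Fraction(time)
    if time not in dataset.schedule:
        raise ContractError(f"time {time} h is not on the protocol grid")
    if not 0 <= threshold <= 10:
        raise ContractError("threshold must be an NRS value in [0, 10]")
    policy = policy or ImputationPolicy()
    hits: dict[str, int] = {}
    totals: dict[str, int] = {}
    for p in dataset.participants:
        series = impute_series(p, policy)
        idx = series.times.index(time)
        totals[p.arm] = totals.get(p.arm, 0) + 1
        hits[p.arm] = hits.get(p.arm, 0) + (1 if series.pi[idx] <= threshold else 0)
    return pd.Series({arm: hits[arm] / totals[arm] for arm in totals}, name="responder_proportion")
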