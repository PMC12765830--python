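"""Protocol imputation of PI/PR series.

Missing scores are filled by three rules, applied point by point in time
order with this precedence:

1. **rescue-window rule** — points inside ``(rescue_time, rescue_time + w]``
   (``w`` = 6 h for parecoxib, 2 h for sufentanil) take the last score on
   record before that rescue, so analgesia delivered by the rescue drug is
   not credited to the study drug.  When two rescue windows overlap, the
   later rescue's pre-rescue score governs from its own event time.
2. **night-sleep rule** — a PI missed during night sleep is set to NRS 3; a
   PR missed during night sleep carries the previous PR forward.
3. **LOCF** — any other missing score carries the last observation forward.

In the primary mode the rescue rule fills *missing* points only (a strict
variant that overwrites observed post-rescue points too is available); in
the sensitivity mode (``sensitivity_no_rescue_imputation``) the rescue rule
is disabled and post-rescue scores are used as recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Optional

from .records import AssessmentRecord, ContractError, ParticipantRecord, TrialValidationError

__all__ = ["ImputationPolicy", "ImputationError", "ScoreSeries", "impute_series"]

PRIMARY = "primary"
SENSITIVITY = "sensitivity_no_rescue_imputation"


class ImputationError(ValueError):
    """A participant cannot be imputed (e.g. missing baseline PI)."""


@dataclass(frozen=True)
class ImputationPolicy:
    """Parameters of the imputation regimes.

    ``night_pi_value`` is the NRS imputed for PI missed during night sleep;
    the two windows (hours) bound the carry-back after each rescue drug.
    ``strict_rescue`` extends the rescue rule to observed points inside the
    window.
    """

    night_pi_value: int = 3
    parecoxib_window_h: Fraction = Fraction(6)
    sufentanil_window_h: Fraction = Fraction(2)
    mode: str = PRIMARY
    strict_rescue: bool = False

    def __post_init__(self):
        object.__setattr__(self, "parecoxib_window_h", Fraction(self.parecoxib_window_h))
        object.__setattr__(self, "sufentanil_window_h", Fraction(self.sufentanil_window_h))
        if self.parecoxib_window_h <= 0 or self.sufentanil_window_h <= 0:
            raise ContractError("imputation windows must be > 0")
        if not (isinstance(self.night_pi_value, int) and 0 <= self.night_pi_value <= 10):
            raise ContractError("night_pi_value must be an integer NRS in [0, 10]")
        if self.mode not in (PRIMARY, SENSITIVITY):
            raise ContractError(f"unknown mode {self.mode!r}")

    def window_for(self, drug: str) -> Fraction:
        return self.parecoxib_window_h if drug == "parecoxib" else self.sufentanil_window_h


@dataclass(frozen=True)
class ScoreSeries:
    """A complete, time-ordered (time, PI, PR) series after imputation.

    PR is undefined at time 0 (``pr[0] is None``).  Provenance per point is
    one of ``observed``, ``night_rule``, ``rescue_rule``, ``locf`` — tracked
    separately for PI and PR since the rules can differ between the scales.
    """

    times: tuple[Fraction, ...]
    pi: tuple[int, ...]
    pr: tuple[Optional[int], ...]
    pi_provenance: tuple[str, ...]
    pr_provenance: tuple[str, ...]

    def __post_init__(self):
        n = len(self.times)
        if not (len(self.pi) == len(self.pr) == len(self.pi_provenance) == len(self.pr_provenance) == n):
            raise ContractError("series fields must have equal length")
        if n == 0 or self.times[0] != 0:
            raise ContractError("series must start at time 0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ContractError("series times must be strictly increasing")
        if any(v is None for v in self.pi):
            raise ContractError("PI series must be complete after imputation")
        if any(v is None for v in self.pr[1:]):
            raise ContractError("PR series must be complete after time 0")

    @property
    def baseline_pi(self) -> int:
        return self.pi[0]

    def as_records(self) -> tuple[AssessmentRecord, ...]:
        """Render back to assessment records (origin marks imputed points)."""
        recs = []
        for t, pi, pr, ppi in zip(self.times, self.pi, self.pr, self.pi_provenance):
            recs.append(
                AssessmentRecord(
                    time_h=t,
                    pi=pi,
                    pr=pr,
                    night_sleep=False,
                    origin="observed" if ppi == "observed" else "imputed",
                )
            )
        return tuple(recs)

    def provenance_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.pi_provenance + self.pr_provenance[1:]:
            out[p] = out.get(p, 0) + 1
        return out


def _last_before(values: list[Optional[int]], times: list[Fraction], cutoff: Fraction):
    """Last non-missing value at a grid time <= cutoff, else None."""
    out = None
    for t, v in zip(times, values):
        if t > cutoff:
            break
        if v is not None:
            out = v
    return out


def impute_series(participant: ParticipantRecord, policy: ImputationPolicy) -> ScoreSeries:
    """Fill a participant's PI/PR series per the protocol's imputation rules."""
    assess = sorted(participant.assessments, key=lambda a: a.time_h)
    if not assess or assess[0].time_h != 0 or assess[0].pi is None:
        raise ImputationError(f"participant {participant.id}: missing baseline PI — unevaluable")

    times = [a.time_h for a in assess]
    rescue_windows = []
    if policy.mode == PRIMARY:
        rescue_windows = sorted(
            ((r.time_h, r.time_h + policy.window_for(r.drug)) for r in participant.rescues),
            key=lambda w: w[0],
        )

    def governing_rescue(t: Fraction) -> Optional[Fraction]:
        """Event time of the latest rescue whose window contains t."""
        hits = [start for start, end in rescue_windows if start < t <= end]
        return max(hits) if hits else None

    pi_out: list[Optional[int]] = []
    pr_out: list[Optional[int]] = []
    ppi: list[str] = []
    ppr: list[str] = []

    for a in assess:
        t = a.time_h
        if t == 0:
            pi_out.append(a.pi)
            pr_out.append(None)
            ppi.append("observed")
            ppr.append("observed")
            continue

        r = governing_rescue(t)

        # --- PI ---
        if r is not None and (a.pi is None or policy.strict_rescue):
            v = _last_before(pi_out, times, r)
            pi_out.append(v if v is not None else assess[0].pi)
            ppi.append("rescue_rule")
        elif a.pi is None and a.night_sleep:
            pi_out.append(policy.night_pi_value)
            ppi.append("night_rule")
        elif a.pi is None:
            pi_out.append(_last_before(pi_out, times, t))
            ppi.append("locf")
        else:
            pi_out.append(a.pi)
            ppi.append("observed")

        # --- PR ---
        if r is not None and (a.pr is None or policy.strict_rescue):
            v = _last_before(pr_out, times, r)
            pr_out.append(v if v is not None else 0)
            ppr.append("rescue_rule")
        elif a.pr is None and a.night_sleep:
            v = _last_before(pr_out, times, t)
            if v is None:
                raise ImputationError(
                    f"participant {participant.id}: night-sleep PR at {t} h has no "
                    "prior PR to carry forward"
                )
            pr_out.append(v)
            ppr.append("night_rule")
        elif a.pr is None:
            v = _last_before(pr_out, times, t)
            # no PR exists before the first post-baseline point: no relief yet
            pr_out.append(v if v is not None else 0)
            ppr.append("locf")
        else:
            pr_out.append(a.pr)
            ppr.append("observed")

    return ScoreSeries(
        times=tuple(times),
        pi=tuple(pi_out),
        pr=tuple(pr_out),
        pi_provenance=tuple(ppi),
        pr_provenance=tuple(ppr),
    )
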