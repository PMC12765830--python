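"""Domain records for an acute-pain PCA trial and analysis-set selection.

The trial observes each participant on a fixed nominal assessment grid over
the first 24 h from Time 0 (start of the loading-dose infusion): pain
intensity (PI) on a 0-10 numerical rating scale and pain relief (PR) on a
0-4 Likert scale, plus rescue-medication events, PCA demand presses and
24 h satisfaction scores.

All times are hours from Time 0, held as exact :class:`fractions.Fraction`
values so that interval weights on the grid sum to exactly 24 and the
time-weighted scores are computed without float drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction
from typing import Optional

__all__ = [
    "ARMS",
    "PROTOCOL_SCHEDULE",
    "RESCUE_DRUGS",
    "AnalysisSet",
    "AssessmentRecord",
    "ContractError",
    "ParticipantRecord",
    "PcaEvent",
    "RescueEvent",
    "TrialDataset",
    "TrialFormatError",
    "TrialValidationError",
    "arm_sizes",
    "select_analysis_set",
]

#: Randomised arms: placebo, two doses of the investigational analgesic, and
#: the active comparator.
ARMS = ("placebo", "tegileridine_0_75", "tegileridine_1_0", "morphine")

RESCUE_DRUGS = ("parecoxib", "sufentanil")

#: Nominal assessment grid (hours from Time 0): baseline, end of the 10-min
#: loading infusion, then 20 min, 30 min, 45 min, 1, 1.5, 2, 3, 4, 5, 6, 8,
#: 10, 12, 18 and 24 h.  Interval weights telescope to exactly 24 h.
PROTOCOL_SCHEDULE: tuple[Fraction, ...] = tuple(
    Fraction(m, 60)
    for m in (0, 10, 20, 30, 45, 60, 90, 120, 180, 240, 300, 360, 480, 600, 720, 1080, 1440)
)


class TrialValidationError(ValueError):
    """A record violates a typed invariant (out-of-range score, bad ordering...)."""


class TrialFormatError(ValueError):
    """An input file does not match the documented long-format dialect."""


class ContractError(ValueError):
    """An operation was called outside its stated precondition."""


def as_hours(value) -> Fraction:
    """Coerce a time value to an exact Fraction of hours."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(3600)
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"cannot interpret {value!r} as hours")


@dataclass(frozen=True)
class AssessmentRecord:
    """One scheduled observation: (time, PI, PR) plus the night-sleep flag.

    ``pi``/``pr`` are ``None`` when the assessment was missed; ``night_sleep``
    marks assessments missed because the participant was asleep, which the
    imputation rules treat specially. ``origin`` distinguishes raw
    observations from values written back by the imputation engine.
    """

    time_h: Fraction
    pi: Optional[int] = None
    pr: Optional[int] = None
    night_sleep: bool = False
    origin: str = "observed"

    def __post_init__(self):
        object.__setattr__(self, "time_h", as_hours(self.time_h))
        if self.time_h < 0:
            raise TrialValidationError(f"assessment time {self.time_h} < 0")
        if self.pi is not None and not (isinstance(self.pi, int) and 0 <= self.pi <= 10):
            raise TrialValidationError(f"PI {self.pi!r} not an integer in [0, 10]")
        if self.pr is not None and not (isinstance(self.pr, int) and 0 <= self.pr <= 4):
            raise TrialValidationError(f"PR {self.pr!r} not an integer in [0, 4]")
        if self.origin not in ("observed", "imputed"):
            raise TrialValidationError(f"origin {self.origin!r} not in {{observed, imputed}}")


@dataclass(frozen=True)
class RescueEvent:
    """A rescue-analgesia administration: parecoxib first line, sufentanil second.

    Doses are mg for parecoxib and µg for sufentanil.  Times slightly beyond
    24 h are valid records (they fall outside the (0, 24] no-rescue window
    but stay in the time-to-event analysis at their recorded time).
    """

    time_h: Fraction
    drug: str
    dose: float

    def __post_init__(self):
        object.__setattr__(self, "time_h", as_hours(self.time_h))
        if self.drug not in RESCUE_DRUGS:
            raise TrialValidationError(f"rescue drug {self.drug!r} not in {RESCUE_DRUGS}")
        if not self.dose > 0:
            raise TrialValidationError(f"rescue dose {self.dose!r} must be > 0")
        if self.time_h < 0:
            raise TrialValidationError(f"rescue time {self.time_h} < 0")


@dataclass(frozen=True)
class PcaEvent:
    """One PCA demand press and whether the pump accepted it."""

    time_h: Fraction
    accepted: bool

    def __post_init__(self):
        object.__setattr__(self, "time_h", as_hours(self.time_h))
        if self.time_h < 0:
            raise TrialValidationError(f"PCA press time {self.time_h} < 0")


@dataclass(frozen=True)
class ParticipantRecord:
    """One randomised subject with their full 24 h observation record."""

    id: str
    arm: str
    baseline_pi: int
    assessments: tuple[AssessmentRecord, ...] = ()
    rescues: tuple[RescueEvent, ...] = ()
    pca_presses: tuple[PcaEvent, ...] = ()
    randomized: bool = True
    treated: bool = True
    completed: bool = True
    satisfaction_participant: Optional[int] = None
    satisfaction_investigator: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "assessments", tuple(self.assessments))
        object.__setattr__(self, "rescues", tuple(self.rescues))
        object.__setattr__(self, "pca_presses", tuple(self.pca_presses))

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise TrialValidationError(f"{self.id}: arm {self.arm!r} not in {ARMS}")
        if not (isinstance(self.baseline_pi, int) and 0 <= self.baseline_pi <= 10):
            raise TrialValidationError(f"{self.id}: baseline PI {self.baseline_pi!r} invalid")
        if self.randomized and self.baseline_pi < 4:
            # inclusion criterion: NRS >= 4 at rest before dosing
            raise TrialValidationError(
                f"{self.id}: baseline PI {self.baseline_pi} < 4 violates the inclusion criterion"
            )
        times = [a.time_h for a in self.assessments]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrialValidationError(f"{self.id}: assessment times not strictly increasing")
        for sat in (self.satisfaction_participant, self.satisfaction_investigator):
            if sat is not None and not (isinstance(sat, int) and 0 <= sat <= 10):
                raise TrialValidationError(f"{self.id}: satisfaction score {sat!r} invalid")

    @property
    def first_rescue(self) -> Optional[RescueEvent]:
        if not self.rescues:
            return None
        return min(self.rescues, key=lambda r: r.time_h)

    @property
    def no_rescue_24h(self) -> bool:
        """True when no rescue medication was taken in (0, 24]."""
        return not any(0 < r.time_h <= 24 for r in self.rescues)


@dataclass(frozen=True)
class TrialDataset:
    """A collection of participants plus the protocol's nominal grid."""

    participants: tuple[ParticipantRecord, ...]
    schedule: tuple[Fraction, ...] = PROTOCOL_SCHEDULE

    def __post_init__(self):
        object.__setattr__(self, "participants", tuple(self.participants))
        object.__setattr__(self, "schedule", tuple(as_hours(t) for t in self.schedule))

    def validate(self) -> None:
        if not self.schedule or self.schedule[0] != 0 or self.schedule[-1] != 24:
            raise TrialValidationError("schedule must start at 0 and end at 24 h")
        if any(b <= a for a, b in zip(self.schedule, self.schedule[1:])):
            raise TrialValidationError("schedule must be strictly increasing")
        seen = set()
        for p in self.participants:
            if p.id in seen:
                raise TrialValidationError(f"duplicate participant id {p.id!r}")
            seen.add(p.id)
            p.validate()

    def __len__(self) -> int:
        return len(self.participants)

    def by_arm(self) -> dict[str, list[ParticipantRecord]]:
        out: dict[str, list[ParticipantRecord]] = {a: [] for a in ARMS}
        for p in self.participants:
            out.setdefault(p.arm, []).append(p)
        return out


class AnalysisSet(Enum):
    """Analysis populations: FAS = randomised & treated, ITT = randomised,
    SAFETY = treated."""

    FAS = "FAS"
    ITT = "ITT"
    SAFETY = "SAFETY"


def select_analysis_set(dataset: TrialDataset, analysis_set: AnalysisSet) -> TrialDataset:
    """Subset a dataset to the participants belonging to an analysis population."""
    if isinstance(analysis_set, str):
        analysis_set = AnalysisSet(analysis_set)
    if analysis_set is AnalysisSet.FAS:
        keep = [p for p in dataset.participants if p.randomized and p.treated]
    elif analysis_set is AnalysisSet.ITT:
        keep = [p for p in dataset.participants if p.randomized]
    else:
        keep = [p for p in dataset.participants if p.treated]
    return replace(dataset, participants=tuple(keep))


def arm_sizes(dataset: TrialDataset) -> dict[str, int]:
    """Participant count per arm (zero for empty arms)."""
    counts = {a: 0 for a in ARMS}
    for p in dataset.participants:
        counts[p.arm] = counts.get(p.arm, 0) + 1
    return counts
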