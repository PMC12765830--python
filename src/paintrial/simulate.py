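"""Synthetic 4-arm acute-pain trial generator.

Emulates the statistical structure the analysis machinery assumes: a
moderate-to-severe baseline (NRS >= 4), arm-ordered exponential-onset
analgesia with integer rounding and clamping, rescue medication triggered
by inadequate analgesia, PCA demand presses filtered by the pump's window /
lockout / hourly-cap rules, night-sleep missingness, and a small dropout
rate.

Defaults are chosen to mirror the trial being emulated: 132 participants
per arm, baseline NRS centred near 5, arm effects ordered
placebo < low dose < high dose ~ comparator so that mean SPID_24 lands in
the -50 to -71 range, ~1.5% dropout, and a PCA pump with a 10-min lockout
and a 6-dose hourly cap open from 30 min to 24 h.

Randomness is counter-based: participant *i* of arm *j* draws from
``SeedSequence([master_seed, j, i])``, so per-arm results are reproducible
independently of arm order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np

from .records import (
    ARMS,
    PROTOCOL_SCHEDULE,
    AssessmentRecord,
    ContractError,
    ParticipantRecord,
    PcaEvent,
    RescueEvent,
    TrialDataset,
)

__all__ = [
    "ArmSpec",
    "SimulationConfig",
    "apply_pca_rules",
    "default_config",
    "simulate_participant",
    "simulate_trial",
]

#: PCA pump demand window (h): open from 30 min to 24 h after the loading dose.
PCA_WINDOW = (Fraction(1, 2), Fraction(24))
#: Lockout between accepted presses: 10 min.
PCA_LOCKOUT = Fraction(1, 6)

_PARECOXIB_DOSE_MG = 40.0
_SUFENTANIL_DOSE_UG = 5.0
_PARECOXIB_DAILY_MAX_MG = 80.0


@dataclass(frozen=True)
class ArmSpec:
    """Treatment-arm parameters of the patient trajectory model.

    ``effect`` is the maximal expected PI reduction (NRS units) reached
    asymptotically; ``onset_tau`` the exponential onset time constant in
    hours.  ``pca_dose`` is the pump's single demand dose in the arm's drug
    units and ``hourly_cap`` the maximum accepted presses in any trailing
    hour (0.3 mg/h at 0.05 mg per dose = 6).
    """

    label: str
    effect: float
    onset_tau: float = 0.8
    pca_dose: float = 0.05
    hourly_cap: int = 6

    def __post_init__(self):
        if not 0 <= self.effect <= 10:
            raise ContractError(f"effect {self.effect} outside [0, 10]")
        if not self.onset_tau > 0:
            raise ContractError("onset_tau must be > 0")
        if self.hourly_cap < 1:
            raise ContractError("hourly_cap must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    arms: tuple[ArmSpec, ...]
    n_per_arm: int = 132
    #: P(baseline = k) for k = 4..10, truncated at the inclusion criterion.
    baseline_probs: tuple[float, ...] = (0.45, 0.27, 0.14, 0.07, 0.04, 0.02, 0.01)
    noise_sd: float = 1.0
    rescue_threshold: int = 5
    #: hazard of a rescue being given at an assessment where PI >= threshold
    rescue_prob: float = 0.25
    rescue_effect: int = 2
    night_window: tuple[Fraction, Fraction] = (Fraction(10), Fraction(16))
    missing_rate_night: float = 0.4
    missing_rate_other: float = 0.02
    dropout_rate: float = 0.015
    #: optional coupling of accepted PCA presses to a small PI decrement
    pca_pi_decrement: float = 0.0
    schedule: tuple[Fraction, ...] = PROTOCOL_SCHEDULE
    seed: int = 0

    def __post_init__(self):
        for name in ("rescue_prob", "missing_rate_night", "missing_rate_other", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ContractError(f"{name} = {v} outside [0, 1]")
        if self.n_per_arm < 1:
            raise ContractError("n_per_arm must be >= 1")
        if abs(sum(self.baseline_probs) - 1) > 1e-9:
            raise ContractError("baseline_probs must sum to 1")


def default_config(n_per_arm: int = 132, seed: int = 0, **overrides) -> SimulationConfig:
    """The reference 4-arm configuration with arm-ordered analgesic effects."""
    arms = (
        ArmSpec("placebo", effect=1.85),
        ArmSpec("tegileridine_0_75", effect=2.45),
        ArmSpec("tegileridine_1_0", effect=2.8),
        ArmSpec("morphine", effect=2.95, pca_dose=1.0),
    )
    return SimulationConfig(arms=arms, n_per_arm=n_per_arm, seed=seed, **overrides)


def apply_pca_rules(
    press_times: Sequence,
    window_start=PCA_WINDOW[0],
    window_end=PCA_WINDOW[1],
    lockout=PCA_LOCKOUT,
    hourly_cap: int = 6,
) -> list[PcaEvent]:
    """Mark each demand press accepted or rejected under the pump's rules.

    A press is accepted iff it falls inside ``(window_start, window_end]``,
    is at least ``lockout`` hours after the last *accepted* press, and
    accepting it keeps the count of accepted presses within the trailing
    one-hour window at or below ``hourly_cap``.
    """
    times = [Fraction(t) if not isinstance(t, Fraction) else t for t in press_times]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ContractError("press_times must be sorted ascending")
    window_start, window_end = Fraction(window_start), Fraction(window_end)
    lockout = Fraction(lockout)
    events: list[PcaEvent] = []
    accepted: list[Fraction] = []
    for t in times:
        ok = window_start < t <= window_end
        if ok and accepted and t - accepted[-1] < lockout:
            ok = False
        if ok and sum(1 for a in accepted if t - 1 < a <= t) + 1 > hourly_cap:
            ok = False
        if ok:
            accepted.append(t)
        events.append(PcaEvent(time_h=t, accepted=ok))
    return events


def _rng_for(seed: Union[int, np.random.SeedSequence]) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def _rescue_window(drug: str) -> Fraction:
    return Fraction(6) if drug == "parecoxib" else Fraction(2)


def simulate_participant(
    config: SimulationConfig,
    arm: ArmSpec,
    seed: Union[int, np.random.SeedSequence],
    participant_id: Optional[str] = None,
) -> ParticipantRecord:
    """Draw one participant's full 24 h record.

    The latent PI trajectory is
    ``clamp(round(baseline - effect * (1 - exp(-t / tau)) + noise), 0, 10)``
    with iid Gaussian noise per assessment; an active rescue subtracts
    ``rescue_effect`` inside the rescue drug's window.  PR is the monotone
    map ``clamp(baseline - PI, 0, 4)``.  Assessments falling in the night
    window go missing (flagged ``night_sleep``) with ``missing_rate_night``;
    others with ``missing_rate_other``.
    """
    rng = _rng_for(seed)
    pid = participant_id or f"{arm.label}-{rng.integers(10**8):08d}"
    ks = np.arange(4, 11)
    baseline = int(rng.choice(ks, p=np.asarray(config.baseline_probs)))

    times = list(config.schedule)
    rescues: list[RescueEvent] = []
    parecoxib_total = 0.0
    assess: list[AssessmentRecord] = [
        AssessmentRecord(time_h=times[0], pi=baseline, pr=None, night_sleep=False)
    ]
    pi_values = [baseline]

    noise = rng.normal(0.0, config.noise_sd, size=len(times) - 1)
    u_rescue = rng.random(size=len(times) - 1)
    u_missing = rng.random(size=len(times) - 1)

    for j, t in enumerate(times[1:]):
        tf = float(t)
        mu = baseline - arm.effect * (1.0 - math.exp(-tf / arm.onset_tau))
        level = mu + noise[j]
        for r in rescues:
            if r.time_h < t <= r.time_h + _rescue_window(r.drug):
                level -= config.rescue_effect
        pi = int(min(10, max(0, round(level))))
        pr = int(min(4, max(0, baseline - pi)))
        pi_values.append(pi)

        # rescue decision: inadequate analgesia at this assessment
        if pi >= config.rescue_threshold and u_rescue[j] < config.rescue_prob:
            if parecoxib_total < _PARECOXIB_DAILY_MAX_MG:
                drug, dose = "parecoxib", _PARECOXIB_DOSE_MG
                parecoxib_total += dose
            else:
                drug, dose = "sufentanil", _SUFENTANIL_DOSE_UG
            rescues.append(RescueEvent(time_h=t + Fraction(1, 12), drug=drug, dose=dose))

        in_night = config.night_window[0] < t <= config.night_window[1]
        p_miss = config.missing_rate_night if in_night else config.missing_rate_other
        if u_missing[j] < p_miss:
            assess.append(
                AssessmentRecord(time_h=t, pi=None, pr=None, night_sleep=in_night)
            )
        else:
            assess.append(AssessmentRecord(time_h=t, pi=pi, pr=pr, night_sleep=False))

    # PCA demand presses: Poisson demand driven by average residual pain
    mean_pi = float(np.mean(pi_values[1:])) if len(pi_values) > 1 else float(baseline)
    rate = 0.25 * max(mean_pi - 2.0, 0.0)  # presses per hour
    span = float(PCA_WINDOW[1] - PCA_WINDOW[0])
    n_press = int(rng.poisson(rate * span))
    press_times = sorted(
        Fraction(round(float(PCA_WINDOW[0]) * 60 + u * span * 60), 60)
        for u in rng.random(n_press)
    )
    # deduplicate minute-resolution collisions to keep times strictly sorted
    press_times = sorted(set(press_times))
    pca = apply_pca_rules(press_times, *PCA_WINDOW, PCA_LOCKOUT, arm.hourly_cap)

    relief = baseline - mean_pi
    sat = int(min(10, max(0, round(6 + 1.5 * relief + rng.normal(0, 1)))))
    sat_inv = int(min(10, max(0, round(6 + 1.5 * relief + rng.normal(0, 1)))))
    completed = bool(rng.random() >= config.dropout_rate)

    return ParticipantRecord(
        id=pid,
        arm=arm.label,
        baseline_pi=baseline,
        assessments=tuple(assess),
        rescues=tuple(rescues),
        pca_presses=tuple(pca),
        completed=completed,
        satisfaction_participant=sat,
        satisfaction_investigator=sat_inv,
    )


def simulate_trial(config: SimulationConfig, seed: Optional[int] = None) -> TrialDataset:
    """Simulate the full 4-arm trial; deterministic given the seed."""
    master = config.seed if seed is None else seed
    participants = []
    for j, arm in enumerate(config.arms):
        for i in range(config.n_per_arm):
            ss = np.random.SeedSequence([int(master), j, i])
            participants.append(
                simulate_participant(config, arm, ss, participant_id=f"{arm.label}-{i:04d}")
            )
    ds = TrialDataset(participants=tuple(participants), schedule=config.schedule)
    ds.validate()
    return ds
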