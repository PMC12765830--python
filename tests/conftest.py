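"""Shared fixtures: hand-built participants and small simulated trials."""

from fractions import Fraction

import pytest

from paintrial import (
    AssessmentRecord,
    ParticipantRecord,
    RescueEvent,
    TrialDataset,
    default_config,
    simulate_trial,
)
from paintrial.records import ARMS, PROTOCOL_SCHEDULE


def make_participant(
    times,
    pi,
    pr=None,
    *,
    pid="p1",
    arm="placebo",
    rescues=(),
    night=(),
    **kwargs,
):
    """Build a participant from parallel (time, PI, PR) lists.

    ``pi``/``pr`` entries of None are missing; times in ``night`` are
    flagged night-sleep.  PR at time 0 is always None.
    """
    times = [Fraction(t) for t in times]
    pr = pr if pr is not None else [None] * len(times)
    night = {Fraction(t) for t in night}
    assessments = tuple(
        AssessmentRecord(
            time_h=t,
            pi=v,
            pr=None if t == 0 else r,
            night_sleep=t in night,
        )
        for t, v, r in zip(times, pi, pr)
    )
    return ParticipantRecord(
        id=pid,
        arm=arm,
        baseline_pi=pi[0],
        assessments=assessments,
        rescues=tuple(rescues),
        **kwargs,
    )


def grid_participant(pi_value, baseline=None, **kwargs):
    """A participant observed at every protocol grid point with constant PI."""
    times = list(PROTOCOL_SCHEDULE)
    baseline = pi_value if baseline is None else baseline
    pi = [baseline] + [pi_value] * (len(times) - 1)
    pr = [None] + [max(0, min(4, baseline - pi_value))] * (len(times) - 1)
    return make_participant(times, pi, pr, **kwargs)


@pytest.fixture(scope="session")
def small_trial():
    """A compact simulated 4-arm trial (20 per arm) used across tests."""
    return simulate_trial(default_config(n_per_arm=20, seed=11))


@pytest.fixture(scope="session")
def consort_like_dataset():
    """528 randomized across 4 arms with one untreated participant in the
    placebo and high-dose arms, mirroring a typical disposition flow."""
    participants = []
    untreated = {("placebo", 0), ("tegileridine_1_0", 0)}
    for arm in ARMS:
        for i in range(132):
            participants.append(
                grid_participant(
                    4,
                    baseline=5,
                    pid=f"{arm}-{i}",
                    arm=arm,
                    treated=(arm, i) not in untreated,
                )
            )
    return TrialDataset(participants=tuple(participants))
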