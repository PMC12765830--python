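"""Delimited-text I/O for trial datasets.

A dataset on disk is a directory of four CSV files plus a JSON manifest:

``assessments.csv``
    one row per (participant, assessment): ``id, arm, randomized, treated,
    time_h, pi, pr, night_sleep``.  The baseline PI is the ``pi`` of the
    ``time_h = 0`` row.
``rescues.csv``
    ``id, time_h, drug, dose``
``pca.csv``
    ``id, time_h, accepted``
``participants.csv``
    ``id, completed, satisfaction_participant, satisfaction_investigator``
``config.json``
    names the four files and records the nominal schedule.

Times are serialised as exact fractions of hours (``"1/6"`` for 10 min) so
reading back a written dataset reproduces it value-for-value.  Missing
scores are empty fields — never 0 or a sentinel numeral.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .records import (
    AssessmentRecord,
    ParticipantRecord,
    PcaEvent,
    RescueEvent,
    TrialDataset,
    TrialFormatError,
    TrialValidationError,
)

_ASSESS_COLS = ["id", "arm", "randomized", "treated", "time_h", "pi", "pr", "night_sleep"]
_RESCUE_COLS = ["id", "time_h", "drug", "dose"]
_PCA_COLS = ["id", "time_h", "accepted"]
_PART_COLS = ["id", "completed", "satisfaction_participant", "satisfaction_investigator"]

_MANIFEST = "config.json"


def _fmt_time(t: Fraction) -> str:
    return str(t)


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(s: str, where: str) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise TrialFormatError(f"{where}: boolean field must be 'true'/'false', got {s!r}")


def _parse_opt_int(s: str, lo: int, hi: int, where: str) -> Optional[int]:
    if s == "":
        return None
    try:
        v = int(s)
    except ValueError:
        raise TrialValidationError(f"{where}: expected an integer, got {s!r}") from None
    if not lo <= v <= hi:
        raise TrialValidationError(f"{where}: value {v} outside [{lo}, {hi}]")
    return v


def write_trial_csv(dataset: TrialDataset, path: Union[str, Path]) -> None:
    """Write a dataset to *path* (a directory, created if needed)."""
    dataset.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    arows, rrows, prows, partrows = [], [], [], []
    for p in dataset.participants:
        for a in p.assessments:
            arows.append(
                {
                    "id": p.id,
                    "arm": p.arm,
                    "randomized": _fmt_bool(p.randomized),
                    "treated": _fmt_bool(p.treated),
                    "time_h": _fmt_time(a.time_h),
                    "pi": "" if a.pi is None else str(a.pi),
                    "pr": "" if a.pr is None else str(a.pr),
                    "night_sleep": _fmt_bool(a.night_sleep),
                }
            )
        for r in p.rescues:
            rrows.append(
                {"id": p.id, "time_h": _fmt_time(r.time_h), "drug": r.drug, "dose": repr(r.dose)}
            )
        for e in p.pca_presses:
            prows.append(
                {"id": p.id, "time_h": _fmt_time(e.time_h), "accepted": _fmt_bool(e.accepted)}
            )
        partrows.append(
            {
                "id": p.id,
                "completed": _fmt_bool(p.completed),
                "satisfaction_participant": ""
                if p.satisfaction_participant is None
                else str(p.satisfaction_participant),
                "satisfaction_investigator": ""
                if p.satisfaction_investigator is None
                else str(p.satisfaction_investigator),
            }
        )

    pd.DataFrame(arows, columns=_ASSESS_COLS).to_csv(path / "assessments.csv", index=False)
    pd.DataFrame(rrows, columns=_RESCUE_COLS).to_csv(path / "rescues.csv", index=False)
    pd.DataFrame(prows, columns=_PCA_COLS).to_csv(path / "pca.csv", index=False)
    pd.DataFrame(partrows, columns=_PART_COLS).to_csv(path / "participants.csv", index=False)
    manifest = {
        "assessments": "assessments.csv",
        "rescues": "rescues.csv",
        "pca": "pca.csv",
        "participants": "participants.csv",
        "schedule": [_fmt_time(t) for t in dataset.schedule],
    }
    (path / _MANIFEST).write_text(json.dumps(manifest, indent=2))


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise TrialFormatError(f"missing file {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise TrialFormatError(f"{path.name}: missing required column {col!r}")
    return df


def read_trial_csv(path: Union[str, Path]) -> TrialDataset:
    """Read a dataset directory written by :func:`write_trial_csv`.

    Malformed rows are reported with their (1-based, header-exclusive) row
    numbers; all offending rows in a file are listed in one error.
    """
    path = Path(path)
    if path.is_file() and path.name.endswith(".json"):
        path = path.parent
    manifest = json.loads((path / _MANIFEST).read_text())
    schedule = tuple(Fraction(t) for t in manifest["schedule"])

    adf = _read_csv(path / manifest["assessments"], _ASSESS_COLS)
    rdf = _read_csv(path / manifest["rescues"], _RESCUE_COLS)
    pdf = _read_csv(path / manifest["pca"], _PCA_COLS)
    partdf = _read_csv(path / manifest["participants"], _PART_COLS)

    errors: list[str] = []

    assessments: dict[str, list[AssessmentRecord]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(adf.itertuples(index=False), start=1):
        where = f"assessments.csv row {i}"
        try:
            pid = row.id
            if pid not in meta:
                order.append(pid)
                meta[pid] = {
                    "arm": row.arm,
                    "randomized": _parse_bool(row.randomized, where),
                    "treated": _parse_bool(row.treated, where),
                }
                assessments[pid] = []
            assessments[pid].append(
                AssessmentRecord(
                    time_h=Fraction(row.time_h),
                    pi=_parse_opt_int(row.pi, 0, 10, where + " (pi)"),
                    pr=_parse_opt_int(row.pr, 0, 4, where + " (pr)"),
                    night_sleep=_parse_bool(row.night_sleep, where),
                )
            )
        except (TrialValidationError, TrialFormatError, ValueError) as exc:
            errors.append(str(exc) if str(exc).startswith(where) else f"{where}: {exc}")
    if errors:
        raise TrialValidationError("; ".join(errors))

    rescues: dict[str, list[RescueEvent]] = {}
    for i, row in enumerate(rdf.itertuples(index=False), start=1):
        try:
            rescues.setdefault(row.id, []).append(
                RescueEvent(time_h=Fraction(row.time_h), drug=row.drug, dose=float(row.dose))
            )
        except (TrialValidationError, ValueError) as exc:
            errors.append(f"rescues.csv row {i}: {exc}")
    presses: dict[str, list[PcaEvent]] = {}
    for i, row in enumerate(pdf.itertuples(index=False), start=1):
        try:
            presses.setdefault(row.id, []).append(
                PcaEvent(
                    time_h=Fraction(row.time_h),
                    accepted=_parse_bool(row.accepted, f"pca.csv row {i}"),
                )
            )
        except (TrialValidationError, TrialFormatError, ValueError) as exc:
            errors.append(f"pca.csv row {i}: {exc}")
    extra: dict[str, dict] = {}
    for i, row in enumerate(partdf.itertuples(index=False), start=1):
        where = f"participants.csv row {i}"
        try:
            extra[row.id] = {
                "completed": _parse_bool(row.completed, where),
                "satisfaction_participant": _parse_opt_int(
                    row.satisfaction_participant, 0, 10, where
                ),
                "satisfaction_investigator": _parse_opt_int(
                    row.satisfaction_investigator, 0, 10, where
                ),
            }
        except (TrialValidationError, TrialFormatError) as exc:
            errors.append(str(exc))
    if errors:
        raise TrialValidationError("; ".join(errors))

    participants = []
    for pid in order:
        recs = sorted(assessments[pid], key=lambda a: a.time_h)
        baseline = next((a.pi for a in recs if a.time_h == 0), None)
        if baseline is None:
            raise TrialValidationError(f"participant {pid}: no baseline PI at time 0")
        participants.append(
            ParticipantRecord(
                id=pid,
                arm=meta[pid]["arm"],
                baseline_pi=baseline,
                assessments=tuple(recs),
                rescues=tuple(sorted(rescues.get(pid, []), key=lambda r: r.time_h)),
                pca_presses=tuple(sorted(presses.get(pid, []), key=lambda e: e.time_h)),
                randomized=meta[pid]["randomized"],
                treated=meta[pid]["treated"],
                **extra.get(pid, {}),
            )
        )
    dataset = TrialDataset(participants=tuple(participants), schedule=schedule)
    dataset.validate()
    return dataset
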