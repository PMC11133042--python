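"""CSV/JSON persistence for schedules, trial logs, BRUMS forms and reports.

All files are comma-separated UTF-8 with a header row.  Reaction times and
onsets are integer milliseconds; absent values (omitted responses) are empty
fields.  A session log written and re-read reproduces the in-memory data
exactly, so analyses are identical either way.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .brums import BrumsForm
from .quality import ExclusionReport
from .schedule import BatterySchedule, Block, trials_for_block
from .simulate import SessionData, TrialRecord

SESSION_COLUMNS = [
    "participant",
    "block",
    "task",
    "trial_index",
    "stimulus",
    "trial_type",
    "correct_key",
    "response",
    "correct",
    "rt_ms",
    "onset_ms",
]


def write_schedule_csv(schedule: BatterySchedule, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"index": b.index, "task_id": b.task_id, "duration_s": b.duration_s, "seed": b.seed}
            for b in schedule.blocks
        ]
    ).to_csv(path, index=False)


def read_schedule_csv(path: str | Path) -> BatterySchedule:
    df = pd.read_csv(path)
    return BatterySchedule(
        blocks=tuple(
            Block(
                index=int(r["index"]),
                task_id=str(r["task_id"]),
                duration_s=int(r["duration_s"]),
                seed=int(r["seed"]),
            )
            for _, r in df.iterrows()
        )
    )


def write_schedule_json(schedule: BatterySchedule, path: str | Path) -> None:
    payload = [
        {"index": b.index, "task_id": b.task_id, "duration_s": b.duration_s, "seed": b.seed}
        for b in schedule.blocks
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_schedule_json(path: str | Path) -> BatterySchedule:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return BatterySchedule(
        blocks=tuple(Block(**{k: b[k] for k in ("index", "task_id", "duration_s", "seed")}) for b in payload)
    )


def write_trials_csv(
    schedule: BatterySchedule, path: str | Path, n_per_block: int = 120
) -> None:
    """Export generated trial lists for external experiment software."""
    rows = []
    for block in schedule.blocks:
        for i, t in enumerate(trials_for_block(block, n_per_block)):
            rows.append(
                {
                    "block": block.index,
                    "task": block.task_id,
                    "trial_index": i,
                    "stimulus": t.descriptor,
                    "correct_key": t.correct_key,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def sessions_to_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "participant": s.participant_id,
                    "block": t.block_index,
                    "task": t.task,
                    "trial_index": t.trial_index,
                    "stimulus": t.stimulus,
                    "trial_type": t.trial_type,
                    "correct_key": t.correct_key,
                    "response": t.response,
                    "correct": int(t.correct),
                    "rt_ms": t.rt_ms,
                    "onset_ms": t.onset_ms,
                }
            )
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    df["rt_ms"] = df["rt_ms"].astype("Int64")
    return df


def write_sessions_csv(sessions: Sequence[SessionData], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def write_brums_csv(sessions: Sequence[SessionData], path: str | Path) -> None:
    rows = []
    for s in sessions:
        for timepoint, form in (("pre", s.pre_brums), ("post", s.post_brums)):
            for label, rating in zip(form.item_order, form.item_ratings):
                rows.append(
                    {
                        "participant": s.participant_id,
                        "timepoint": timepoint,
                        "item_label": label,
                        "rating": rating,
                        "completion_time": form.completion_time_s,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_sessions(sessions_csv: str | Path, brums_csv: str | Path) -> list[SessionData]:
    """Rebuild SessionData objects from a trial log and a BRUMS item log."""
    trials = pd.read_csv(
        sessions_csv, dtype={"rt_ms": "Int64"}, keep_default_na=True
    )
    brums = pd.read_csv(brums_csv)

    forms: dict[tuple[str, str], BrumsForm] = {}
    for (participant, timepoint), grp in brums.groupby(
        ["participant", "timepoint"], sort=False
    ):
        forms[(str(participant), str(timepoint))] = BrumsForm(
            item_order=tuple(grp["item_label"].astype(str)),
            item_ratings=tuple(int(r) for r in grp["rating"]),
            completion_time_s=float(grp["completion_time"].iloc[0]),
        )

    sessions = []
    for participant, grp in trials.groupby("participant", sort=False):
        pid = str(participant)
        records = [
            TrialRecord(
                block_index=int(r.block),
                task=str(r.task),
                trial_index=int(r.trial_index),
                stimulus=str(r.stimulus),
                trial_type=str(r.trial_type),
                correct_key=str(r.correct_key),
                response=None if pd.isna(r.response) else str(r.response),
                correct=bool(r.correct),
                rt_ms=None if pd.isna(r.rt_ms) else int(r.rt_ms),
                onset_ms=int(r.onset_ms),
            )
            for r in grp.itertuples()
        ]
        sessions.append(
            SessionData(
                participant_id=pid,
                pre_brums=forms[(pid, "pre")],
                post_brums=forms[(pid, "post")],
                trials=records,
            )
        )
    return sessions


def write_exclusions_csv(reports: Sequence[ExclusionReport], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "participant": r.participant_id,
                "excluded": int(r.excluded),
                "reasons": "|".join(sorted(r.reasons)),
            }
            for r in reports
        ]
    ).to_csv(path, index=False)


def read_exclusions_csv(path: str | Path) -> list[ExclusionReport]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        ExclusionReport(
            participant_id=str(r["participant"]),
            excluded=bool(int(r["excluded"])),
            reasons=frozenset(str(r["reasons"]).split("|")) if r["reasons"] else frozenset(),
        )
        for _, r in df.iterrows()
    ]


def write_report(report, path_json: str | Path) -> None:
    """Write the analysis report as JSON plus CSV and plain-text siblings."""
    path_json = Path(path_json)
    path_json.write_text(
        json.dumps(report.to_dict(), indent=2, allow_nan=True) + "\n", encoding="utf-8"
    )
    report.to_frame().to_csv(path_json.with_suffix(".csv"), index=False)
    path_json.with_suffix(".txt").write_text(
        report.summary_text() + "\n", encoding="utf-8"
    )
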