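"""CSV/JSON readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import OUTCOMES, BlockSchedule, ParticipantRecord, Recording

__all__ = [
    "participants_to_frame",
    "frame_to_participants",
    "write_participants_csv",
    "read_participants_csv",
    "write_recordings",
    "read_recordings",
    "write_activity_csv",
    "read_activity_csv",
]


def participants_to_frame(participants: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for p in participants:
        row = {"id": p.id, "group": p.group, "sex": p.sex, "age": p.age}
        for name in OUTCOMES:
            pre, post = p.scores[name]
            row[f"{name}_pre"] = pre
            row[f"{name}_post"] = post
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_participants(df: pd.DataFrame) -> list[ParticipantRecord]:
    out = []
    for _, row in df.iterrows():
        scores = {name: (float(row[f"{name}_pre"]), float(row[f"{name}_post"]))
                  for name in OUTCOMES}
        out.append(ParticipantRecord(str(row["id"]), str(row["group"]),
                                     str(row["sex"]), float(row["age"]), scores))
    return out


def write_participants_csv(participants: Iterable[ParticipantRecord],
                           path: str | Path) -> None:
    participants_to_frame(participants).to_csv(path, index=False)


def read_participants_csv(path: str | Path) -> list[ParticipantRecord]:
    return frame_to_participants(pd.read_csv(path))


def write_recordings(recordings: Sequence[Recording], csv_path: str | Path,
                     sidecar_path: str | Path) -> None:
    """Long-format signal CSV plus a JSON sidecar for schedule/fs/ground truth."""
    frames = []
    meta: dict = {"fs": None, "schedule": None, "true_neural_amplitude": {}}
    for rec in recordings:
        t = np.arange(len(rec.deep)) / rec.fs
        frames.append(pd.DataFrame({
            "id": rec.participant_id, "side": rec.side, "t": t,
            "shallow": rec.shallow, "deep": rec.deep,
        }))
        meta["fs"] = rec.fs
        meta["schedule"] = rec.schedule.to_dict()
        if rec.true_neural_amplitude is not None:
            meta["true_neural_amplitude"].setdefault(rec.participant_id, {})[
                rec.side] = rec.true_neural_amplitude
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    Path(sidecar_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_recordings(csv_path: str | Path,
                    sidecar_path: str | Path) -> list[Recording]:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(sidecar_path).read_text())
    schedule = BlockSchedule.from_dict(meta["schedule"])
    fs = float(meta["fs"])
    truths = meta.get("true_neural_amplitude", {})
    out = []
    for (pid, side), sub in df.groupby(["id", "side"], sort=True):
        sub = sub.sort_values("t")
        amp = truths.get(str(pid), {}).get(str(side))
        out.append(Recording(str(pid), str(side), fs,
                             sub["shallow"].to_numpy(float),
                             sub["deep"].to_numpy(float),
                             schedule,
                             None if amp is None else float(amp)))
    return out


def write_activity_csv(activity: pd.DataFrame, path: str | Path) -> None:
    activity[["id", "side", "activity"]].to_csv(path, index=False)


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
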