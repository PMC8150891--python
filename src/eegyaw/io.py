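"""Plain-text IO: recordings, schedules and labels as CSV, reports as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import EvalReport
from .synth import CHANNELS, EventSchedule, LabelTrace, Recording
from .transfer import TransferMatrix

__all__ = [
    "save_recording_csv",
    "load_recording_csv",
    "save_schedule_csv",
    "load_schedule_csv",
    "save_labels_csv",
    "load_labels_csv",
    "save_report_json",
    "save_matrix_csv",
]


def save_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write `time_s,O1,O2,CZ` rows (volts)."""
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for name, row in zip(rec.channels, rec.data):
        df[name] = row
    df.to_csv(path, index=False, float_format="%.8g")


def load_recording_csv(
    path: str | Path, subject_id: str = "", file_id: str = ""
) -> Recording:
    df = pd.read_csv(path)
    channels = tuple(c for c in df.columns if c != "time_s")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    fs = 1.0 / np.median(np.diff(t))
    return Recording(
        channels=channels,
        fs=float(round(fs, 6)),
        data=df[list(channels)].to_numpy().T,
        subject_id=subject_id,
        file_id=file_id,
    )


def save_schedule_csv(schedule: EventSchedule, path: str | Path) -> None:
    df = pd.DataFrame(
        schedule.events, columns=["onset_s", "duration_s", "side"]
    )
    df.attrs["session_length_s"] = schedule.session_length_s
    with open(path, "w") as fh:
        fh.write(f"# session_length_s={schedule.session_length_s}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def load_schedule_csv(path: str | Path) -> EventSchedule:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# session_length_s="):
            raise ValueError(f"{path}: missing session_length_s header")
        length = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    events = [
        (float(r.onset_s), float(r.duration_s), str(r.side))
        for r in df.itertuples()
    ]
    return EventSchedule(events=events, session_length_s=length)


def save_labels_csv(labels: LabelTrace, path: str | Path) -> None:
    t = np.arange(labels.y.size) / labels.fs
    pd.DataFrame({"time_s": t, "y": labels.y}).to_csv(
        path, index=False, float_format="%.8g"
    )


def load_labels_csv(path: str | Path) -> LabelTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return LabelTrace(y=df["y"].to_numpy(), fs=float(round(fs, 6)))


def save_report_json(report: EvalReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def save_matrix_csv(m: TransferMatrix, out_dir: str | Path, stem: str = "transfer") -> None:
    """One CSV per metric (r, mse, band), rows = training units."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(m.r_grid, index=m.sources, columns=m.targets).to_csv(
        out / f"{stem}_r.csv", float_format="%.4f"
    )
    pd.DataFrame(m.mse_grid, index=m.sources, columns=m.targets).to_csv(
        out / f"{stem}_mse.csv", float_format="%.4f"
    )
    pd.DataFrame(m.band_grid, index=m.sources, columns=m.targets).to_csv(
        out / f"{stem}_band.csv"
    )
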