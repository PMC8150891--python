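"""End-to-end entry points: roster simulation and the two analyses.

These functions wire the modules together exactly as the experiment ran:
simulate (or load) a roster of sessions, preprocess, window, then either
train/test within each file (first analysis) or build the participant x
participant transfer matrix (second analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .config import RunConfig
from .evaluate import EvalReport
from .synth import (
    LabelTrace,
    Recording,
    SubjectProfile,
    make_labels,
    make_schedule,
    random_profile,
    synthesize_recording,
)
from .transfer import TransferMatrix, cross_matrix, within_file_analysis

__all__ = [
    "Session",
    "generate_session",
    "generate_roster",
    "simulate_roster",
    "load_roster",
    "run_first_analysis",
    "run_second_analysis",
]

logger = logging.getLogger(__name__)


@dataclass
class Session:
    participant_id: str
    file_id: str
    recording: Recording
    labels: LabelTrace
    profile: SubjectProfile
    schedule: "object | None" = None


def generate_session(
    participant_id: str,
    file_id: str,
    config: RunConfig,
    seed: int,
    profile: SubjectProfile | None = None,
    session_length_s: float | None = None,
    balanced: bool = True,
) -> Session:
    """One synthetic session; the profile carries the subject idiosyncrasy.

    With ``balanced`` (the default, matching the protocol's guarantee that
    training material covers all three head positions) the schedule is
    redrawn until both stimulus sides occur in the first half of the
    session as well as in the session overall.
    """
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = random_profile(
            participant_id,
            int(rng.integers(0, 2**31 - 1)),
            noise_sd=config.noise_sd,
            line_amp=config.line_amp,
            drift_amp=config.drift_amp,
        )
    if session_length_s is None:
        lo, hi = config.session_length_range_s
        session_length_s = float(rng.uniform(lo, hi))
    for _ in range(100):
        schedule = make_schedule(session_length_s, int(rng.integers(0, 2**31 - 1)))
        if not balanced:
            break
        half = session_length_s / 2
        first = {s for o, _, s in schedule.events if o < half}
        whole = {s for _, _, s in schedule.events}
        if first == {"left", "right"} and whole == {"left", "right"}:
            break
    else:
        raise RuntimeError("could not draw a side-balanced schedule")
    labels = make_labels(schedule, config.fs, config.reaction_lag_s)
    rec = synthesize_recording(schedule, labels, profile, config.fs)
    rec.file_id = file_id
    return Session(participant_id, file_id, rec, labels, profile, schedule)


def generate_roster(
    config: RunConfig, seed: int, session_length_s: float | None = None
) -> list[Session]:
    """All roster sessions; one profile per participant, shared across files."""
    ss = np.random.SeedSequence(seed)
    part_seeds = ss.spawn(len(config.roster))
    sessions = []
    for (pid, n_files), pseed in zip(config.roster.items(), part_seeds):
        child = np.random.default_rng(pseed)
        profile = random_profile(
            pid,
            int(child.integers(0, 2**31 - 1)),
            noise_sd=config.noise_sd,
            line_amp=config.line_amp,
            drift_amp=config.drift_amp,
        )
        for f in range(1, n_files + 1):
            sessions.append(
                generate_session(
                    pid,
                    f"F{f}",
                    config,
                    seed=int(child.integers(0, 2**31 - 1)),
                    profile=profile,
                    session_length_s=session_length_s,
                )
            )
    return sessions


def simulate_roster(config: RunConfig, out_dir: str | Path, seed: int) -> pd.DataFrame:
    """Write every roster session (recording/events/labels CSV) + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    ss = np.random.SeedSequence(seed)
    part_seeds = ss.spawn(len(config.roster))
    for (pid, n_files), pseed in zip(config.roster.items(), part_seeds):
        child = np.random.default_rng(pseed)
        profile = random_profile(
            pid,
            int(child.integers(0, 2**31 - 1)),
            noise_sd=config.noise_sd,
            line_amp=config.line_amp,
            drift_amp=config.drift_amp,
        )
        for f in range(1, n_files + 1):
            fid = f"F{f}"
            file_seed = int(child.integers(0, 2**31 - 1))
            sess = generate_session(
                pid, fid, config, seed=file_seed, profile=profile
            )
            stem = f"{pid}_{fid}"
            eio.save_recording_csv(sess.recording, out / f"{stem}_eeg.csv")
            eio.save_schedule_csv(sess.schedule, out / f"{stem}_events.csv")
            eio.save_labels_csv(sess.labels, out / f"{stem}_labels.csv")
            rows.append(
                {
                    "participant": pid,
                    "file": fid,
                    "length_s": sess.labels.y.size / config.fs,
                    "seed": file_seed,
                    "eeg_csv": f"{stem}_eeg.csv",
                    "events_csv": f"{stem}_events.csv",
                    "labels_csv": f"{stem}_labels.csv",
                }
            )
            logger.info("simulated %s (%.0f s)", stem, rows[-1]["length_s"])
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_roster(data_dir: str | Path) -> list[Session]:
    """Load sessions back from a simulate_roster output directory."""
    data = Path(data_dir)
    manifest_path = data / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {data}")
    manifest = pd.read_csv(manifest_path)
    sessions = []
    for row in manifest.itertuples():
        rec = eio.load_recording_csv(
            data / row.eeg_csv, subject_id=row.participant, file_id=row.file
        )
        labels = eio.load_labels_csv(data / row.labels_csv)
        sessions.append(
            Session(
                participant_id=row.participant,
                file_id=row.file,
                recording=rec,
                labels=labels,
                profile=SubjectProfile(subject_id=row.participant),
            )
        )
    return sessions


def run_first_analysis(
    sessions: list[Session], config: RunConfig, seed: int = 0
) -> pd.DataFrame:
    """Half/half split per file; returns participant, file, n, mse, r, band."""
    if not sessions:
        raise ValueError("no sessions to analyse")
    reports = within_file_analysis(
        [(s.recording, s.labels) for s in sessions],
        lag=config.lag,
        spec=config.filter,
        gain=config.gain,
        smooth_window=config.smooth_window,
        train_config=config.training,
        seed=seed,
    )
    return pd.DataFrame(
        {
            "participant": [s.participant_id for s in sessions],
            "file": [s.file_id for s in sessions],
            "n": [rep.n for rep in reports],
            "mse": [rep.mse for rep in reports],
            "mse_raw": [rep.mse_raw for rep in reports],
            "r": [rep.r for rep in reports],
            "band": [rep.band for rep in reports],
        }
    )


def run_second_analysis(
    sessions: list[Session], config: RunConfig, seed: int = 0
) -> TransferMatrix:
    """Participant x participant transfer grid on concatenated data."""
    by_participant: dict[str, list] = {}
    for s in sessions:
        by_participant.setdefault(s.participant_id, []).append(
            (s.recording, s.labels)
        )
    if len(by_participant) < 2:
        raise ValueError("second analysis needs at least 2 participants")
    units = list(by_participant.items())
    return cross_matrix(
        units,
        units,
        mode="per_participant",
        lag=config.lag,
        spec=config.filter,
        gain=config.gain,
        smooth_window=config.smooth_window,
        train_config=config.training,
        seed=seed,
    )
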