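"""Within-file and cross-unit transfer analyses.

Two experiment layouts:

* within-file: each recording is split chronologically in half, the
  decoding function is identified on the first half and verified on the
  second half;
* cross matrix: a function is identified per training unit (a single file,
  or all of a participant's files concatenated) and verified on every test
  unit, yielding a sources x targets grid of scores.  Diagonal entries in
  per-participant mode are in-sample (same data used to identify and
  verify), mirroring how such grids are conventionally reported; a warning
  notes this.

Concatenation in per-participant mode windows each file separately before
stacking, so no feature window straddles a file boundary.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .dataset import WindowedDataset, build_windows, split_halves
from .evaluate import EvalReport, band, evaluate_model
from .model_lm import TrainConfig, train
from .preprocess import (
    DEFAULT_SMOOTH_WINDOW,
    FilterSpec,
    preprocess_recording,
    smooth_labels,
)
from .synth import LabelTrace, Recording

__all__ = [
    "TransferMatrix",
    "prepare_file",
    "within_file_analysis",
    "cross_matrix",
    "band_counts",
]


@dataclass
class TransferMatrix:
    sources: list[str]
    targets: list[str]
    r_grid: np.ndarray
    mse_grid: np.ndarray
    band_grid: list[list[str | None]]

    def __post_init__(self) -> None:
        shape = (len(self.sources), len(self.targets))
        if self.r_grid.shape != shape or self.mse_grid.shape != shape:
            raise ValueError("grid shapes inconsistent with unit lists")


def prepare_file(
    rec: Recording,
    labels: LabelTrace,
    lag: int = 10,
    spec: FilterSpec = FilterSpec(),
    gain: float = 1e5,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> WindowedDataset:
    """Preprocess one recording + label trace into a windowed dataset."""
    proc = preprocess_recording(rec, spec, gain)
    y = smooth_labels(labels, smooth_window)
    return build_windows(proc, y, lag)


def _concat(datasets: list[WindowedDataset]) -> WindowedDataset:
    return WindowedDataset(
        X=np.concatenate([d.X for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        index_map=np.concatenate([d.index_map for d in datasets]),
    )


def within_file_analysis(
    files: list[tuple[Recording, LabelTrace]],
    lag: int = 10,
    spec: FilterSpec = FilterSpec(),
    gain: float = 1e5,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    train_config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> list[EvalReport]:
    """First analysis: per file, train on the first half, test on the second."""
    if not files:
        raise ValueError("need at least one file")
    reports = []
    for i, (rec, labels) in enumerate(files):
        ds = prepare_file(rec, labels, lag, spec, gain, smooth_window)
        pair = split_halves(ds)
        model, _ = train(pair.train, train_config, seed=seed + i)
        reports.append(evaluate_model(model, pair.test, smooth_window))
    return reports


def cross_matrix(
    train_units: list[tuple[str, list[tuple[Recording, LabelTrace]]]],
    test_units: list[tuple[str, list[tuple[Recording, LabelTrace]]]],
    mode: str = "per_participant",
    lag: int = 10,
    spec: FilterSpec = FilterSpec(),
    gain: float = 1e5,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    train_config: TrainConfig = TrainConfig(),
    seed: int = 0,
    train_on_half: bool = False,
) -> TransferMatrix:
    """Second analysis: train per unit, test on every unit.

    ``mode='per_file'`` expects one file per unit; ``'per_participant'``
    concatenates a unit's files before training.  With
    ``train_on_half=True`` the training unit contributes only its first
    half and the diagonal is evaluated on the matching second half (so the
    per-file diagonal reproduces the within-file analysis); otherwise full
    units are used on both sides and diagonal entries are in-sample.
    """
    if mode not in ("per_file", "per_participant"):
        raise ValueError(f"unknown mode {mode!r}")
    if not train_units or not test_units:
        raise ValueError("unit lists must be non-empty")
    if mode == "per_file":
        for uid, files in list(train_units) + list(test_units):
            if len(files) != 1:
                raise ValueError(f"per_file mode: unit {uid} has {len(files)} files")
    if not train_on_half:
        warnings.warn(
            "diagonal entries are in-sample (identified and verified on the "
            "same data)",
            stacklevel=2,
        )

    test_ds = {
        uid: _concat(
            [prepare_file(r, l, lag, spec, gain, smooth_window) for r, l in files]
        )
        for uid, files in test_units
    }

    sources = [uid for uid, _ in train_units]
    targets = [uid for uid, _ in test_units]
    r_grid = np.full((len(sources), len(targets)), np.nan)
    mse_grid = np.full_like(r_grid, np.nan)
    band_grid: list[list[str | None]] = []

    for i, (uid, files) in enumerate(train_units):
        ds = _concat(
            [prepare_file(r, l, lag, spec, gain, smooth_window) for r, l in files]
        )
        if train_on_half:
            ds = split_halves(ds).train
        model, _ = train(ds, train_config, seed=seed + i)
        row_bands: list[str | None] = []
        for j, tid in enumerate(targets):
            target = test_ds[tid]
            if train_on_half and tid == uid:
                target = split_halves(target).test
            rep = evaluate_model(model, target, smooth_window)
            r_grid[i, j] = rep.r
            mse_grid[i, j] = rep.mse
            row_bands.append(rep.band)
        band_grid.append(row_bands)
    return TransferMatrix(
        sources=sources,
        targets=targets,
        r_grid=r_grid,
        mse_grid=mse_grid,
        band_grid=band_grid,
    )


def band_counts(m: TransferMatrix | np.ndarray | list) -> Counter:
    """Tally correlation bands over a grid (or any array of r values)."""
    if isinstance(m, TransferMatrix):
        values = [b for row in m.band_grid for b in row]
    else:
        values = [band(r) for r in np.asarray(m, dtype=float).ravel()]
    counts = Counter(values)
    if None in counts:
        counts["missing"] = counts.pop(None)
    return counts
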