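"""Lagged-window regression dataset and the chronological half split.

The decoding function maps the ``lag`` most recent multichannel EEG samples
to the head position at the next sample: the feature row for target index t
is the concatenation x(t-1), x(t-2), ..., x(t-lag), each x a C-vector in
channel order (lag-major layout, most recent first).  With the defaults
(lag 10, 3 channels) each example has 30 features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import ProcessedRecording
from .synth import LabelTrace

__all__ = ["WindowedDataset", "SplitPair", "build_windows", "split_halves"]

DEFAULT_LAG = 10


@dataclass
class WindowedDataset:
    X: np.ndarray          # (n_examples, lag * n_channels)
    y: np.ndarray          # (n_examples,)
    index_map: np.ndarray  # example k -> target sample index t in the trace

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.index_map = np.asarray(self.index_map, dtype=int)
        if not (len(self.X) == len(self.y) == len(self.index_map)):
            raise ValueError("X, y and index_map must have equal length")

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class SplitPair:
    train: WindowedDataset
    test: WindowedDataset
    boundary_index: int    # first target sample index belonging to the test set


def build_windows(
    rec: ProcessedRecording, labels: LabelTrace, lag: int = DEFAULT_LAG
) -> WindowedDataset:
    """Build the (n - lag) x (lag * C) feature matrix with aligned targets.

    Feature columns for example with target index t are
    ``[x_O1(t-1), x_O2(t-1), x_CZ(t-1), x_O1(t-2), ..., x_CZ(t-lag)]``.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n = rec.n_samples
    if labels.y.size != n:
        raise ValueError(
            f"recording has {n} samples but labels have {labels.y.size}"
        )
    if n < lag + 1:
        raise ValueError(f"need at least lag+1={lag + 1} samples, got {n}")
    x = rec.data.T                          # (n, C)
    n_ex = n - lag
    blocks = [x[lag - d : n - d] for d in range(1, lag + 1)]
    X = np.concatenate(blocks, axis=1)      # (n_ex, lag*C), lag-major
    idx = np.arange(lag, n)
    return WindowedDataset(X=X, y=labels.y[idx], index_map=idx)


def split_halves(ds: WindowedDataset) -> SplitPair:
    """Chronological half split: first floor(n/2) examples train, rest test.

    Warns when the training half does not contain all three head states
    (left, forward, right), since the decoding function can only be
    identified for states it has seen.
    """
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 examples to split")
    n_train = n // 2
    train = WindowedDataset(
        X=ds.X[:n_train], y=ds.y[:n_train], index_map=ds.index_map[:n_train]
    )
    test = WindowedDataset(
        X=ds.X[n_train:], y=ds.y[n_train:], index_map=ds.index_map[n_train:]
    )
    states = {
        "left": np.any(ds.y[:n_train] < -0.9),
        "forward": np.any(np.abs(ds.y[:n_train]) < 0.1),
        "right": np.any(ds.y[:n_train] > 0.9),
    }
    missing = [s for s, present in states.items() if not present]
    if missing:
        warnings.warn(
            f"training half lacks head state(s): {', '.join(missing)}",
            stacklevel=2,
        )
    return SplitPair(train=train, test=test, boundary_index=int(ds.index_map[n_train]))
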