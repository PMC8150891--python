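"""EEG preprocessing: line-noise notch, detrending, amplification, clipping.

The chain is fixed and order-deterministic: 49-51 Hz band-stop (mains
removal) -> 1 Hz high-pass (drift removal) -> x1e5 amplification with
clipping to [-1, 1].  Filters are 4th-order Butterworth IIR applied
forward-backward (zero phase) by default, independently per channel.

Head-position labels are smoothed with a trailing moving average over the
current and preceding ``window - 1`` samples (default 300 samples = 0.6 s at
500 Hz), turning the step-coded +-1 trace into ramped transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synth import LabelTrace, Recording

__all__ = [
    "FilterSpec",
    "ProcessedRecording",
    "remove_line_noise",
    "remove_trend",
    "amplify_and_clip",
    "smooth_labels",
    "trailing_mean",
    "preprocess_recording",
]

DEFAULT_GAIN = 1.0e5
DEFAULT_SMOOTH_WINDOW = 300


@dataclass(frozen=True)
class FilterSpec:
    """IIR filter design parameters for the preprocessing chain."""

    stop_band: tuple[float, float] = (49.0, 51.0)
    highpass_cut: float = 1.0
    family: str = "butter"
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        lo, hi = self.stop_band
        if not (0 < self.highpass_cut < lo < hi < fs / 2):
            raise ValueError(
                f"require 0 < highpass_cut < {lo} < {hi} < fs/2={fs / 2}"
            )


class ProcessedRecording(Recording):
    """Recording after the full chain; values are unitless in [-1, 1]."""


def _apply_sos(rec: Recording, sos: np.ndarray, zero_phase: bool) -> Recording:
    if zero_phase:
        data = sps.sosfiltfilt(sos, rec.data, axis=1)
    else:
        data = sps.sosfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def remove_line_noise(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Suppress 50 Hz mains interference with a 49-51 Hz band-stop filter."""
    if rec.fs <= 2 * spec.stop_band[1]:
        raise ValueError(
            f"fs={rec.fs} too low for a {spec.stop_band} Hz stop band"
        )
    spec.validate(rec.fs)
    sos = sps.iirfilter(
        spec.order,
        spec.stop_band,
        btype="bandstop",
        ftype=spec.family,
        fs=rec.fs,
        output="sos",
    )
    return _apply_sos(rec, sos, spec.zero_phase)


def remove_trend(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Remove DC offset and slow drift with a high-pass (default 1 Hz)."""
    if rec.fs <= 2 * spec.highpass_cut:
        raise ValueError(f"fs={rec.fs} too low for highpass at {spec.highpass_cut} Hz")
    sos = sps.iirfilter(
        spec.order,
        spec.highpass_cut,
        btype="highpass",
        ftype=spec.family,
        fs=rec.fs,
        output="sos",
    )
    return _apply_sos(rec, sos, spec.zero_phase)


def amplify_and_clip(rec: Recording, gain: float = DEFAULT_GAIN) -> ProcessedRecording:
    """Scale by ``gain`` (default 1e5) and clip to [-1, 1]."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    data = np.clip(gain * rec.data, -1.0, 1.0)
    return ProcessedRecording(
        channels=rec.channels,
        fs=rec.fs,
        data=data,
        subject_id=rec.subject_id,
        file_id=rec.file_id,
    )


def trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Causal moving average over the current and preceding window-1 samples.

    The first ``window - 1`` outputs average over the available prefix, so
    no samples are discarded and constants are preserved exactly.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    if window == 1:
        return x.copy()
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def smooth_labels(labels: LabelTrace, window: int = DEFAULT_SMOOTH_WINDOW) -> LabelTrace:
    """Linearly smooth position transitions with the trailing moving mean.

    At the default 300 samples and 500 Hz the smoothing spans 0.6 s.
    """
    return LabelTrace(y=trailing_mean(labels.y, window), fs=labels.fs)


def preprocess_recording(
    rec: Recording,
    spec: FilterSpec = FilterSpec(),
    gain: float = DEFAULT_GAIN,
) -> ProcessedRecording:
    """Full chain: band-stop 49-51 Hz -> high-pass -> amplify and clip."""
    return amplify_and_clip(remove_trend(remove_line_noise(rec, spec), spec), gain)
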