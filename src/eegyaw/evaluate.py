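"""Prediction smoothing, MSE / Pearson-r scoring and correlation banding.

Raw network predictions are noisy sample-by-sample; they are stabilised
with a trailing moving mean over the current and preceding 299 samples
(0.6 s at 500 Hz) before scoring.  Performance is summarised by the mean
squared error and the Pearson correlation between the true head-position
trace and the smoothed prediction, and the correlation is banded:

    strong    0.50 <= r <= 1
    moderate  0.30 <= r < 0.50
    weak      r < 0.30   (negative r is weak)

A Pearson coefficient is undefined when either trace is constant; it is
then reported as NaN with band ``None``, never silently as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import WindowedDataset
from .model_lm import MLPModel, forward
from .preprocess import trailing_mean

__all__ = [
    "EvalReport",
    "smooth_predictions",
    "mse",
    "pearson_r",
    "band",
    "evaluate_model",
    "DEFAULT_PRED_WINDOW",
]

DEFAULT_PRED_WINDOW = 300

STRONG_MIN = 0.50
MODERATE_MIN = 0.30


@dataclass
class EvalReport:
    y_true: np.ndarray
    y_pred_raw: np.ndarray
    y_pred_smooth: np.ndarray
    mse: float            # against the smoothed prediction
    mse_raw: float        # secondary: against the raw prediction
    r: float              # Pearson r against the smoothed prediction (NaN if undefined)
    band: str | None
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mse": self.mse,
            "mse_raw": self.mse_raw,
            "r": self.r,
            "band": self.band,
        }


def smooth_predictions(
    y_pred_raw: np.ndarray, window: int = DEFAULT_PRED_WINDOW
) -> np.ndarray:
    """Trailing moving mean including the current sample.

    The leading ``window - 1`` outputs use the available partial window, so
    the first 0.6 s of predictions is kept rather than discarded.
    """
    return trailing_mean(np.asarray(y_pred_raw, dtype=float), window)


def mse(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared prediction error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_true.size != y_hat.size:
        raise ValueError("length mismatch")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    return float(np.mean((y_true - y_hat) ** 2))


def pearson_r(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation cov(y, yhat) / (sigma_y sigma_yhat).

    Returns NaN (with a warning) when either input is constant, for which
    the coefficient is undefined.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_true.size != y_hat.size:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least two samples")
    a = y_true - y_true.mean()
    b = y_hat - y_hat.mean()
    denom = np.sqrt(a @ a) * np.sqrt(b @ b)
    if denom == 0:
        warnings.warn("Pearson r undefined for constant input", stacklevel=2)
        return float("nan")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def band(r: float) -> str | None:
    """Band a correlation coefficient; NaN (undefined r) maps to None."""
    if r is None or np.isnan(r):
        return None
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r={r} outside [-1, 1]")
    if r >= STRONG_MIN:
        return "strong"
    if r >= MODERATE_MIN:
        return "moderate"
    return "weak"


def evaluate_model(
    model: MLPModel, ds: WindowedDataset, window: int = DEFAULT_PRED_WINDOW
) -> EvalReport:
    """Forward pass, smoothing, scoring and banding on one dataset."""
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    y_raw = forward(model, ds.X)
    y_smooth = smooth_predictions(y_raw, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant predictions yield NaN r by design
        r = pearson_r(ds.y, y_smooth) if len(ds) >= 2 else float("nan")
    return EvalReport(
        y_true=ds.y,
        y_pred_raw=y_raw,
        y_pred_smooth=y_smooth,
        mse=mse(ds.y, y_smooth),
        mse_raw=mse(ds.y, y_raw),
        r=r,
        band=band(r),
        n=len(ds),
    )
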