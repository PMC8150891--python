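"""Figures: predicted-vs-actual traces and banded transfer grids.

matplotlib is imported lazily so the core pipeline has no hard plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluate import EvalReport
from .transfer import TransferMatrix

__all__ = ["plot_prediction_trace", "plot_transfer_matrix"]

_BAND_SHADE = {"strong": "white", "moderate": "0.8", "weak": "0.5", None: "0.3"}


def plot_prediction_trace(
    report: EvalReport, path: str | Path, fs: float = 500.0, title: str = ""
) -> None:
    """Smoothed prediction against the true head-position trace."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(report.n) / fs
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(t, report.y_true, lw=1.2, label="actual", color="k")
    ax.plot(t, report.y_pred_smooth, lw=1.0, label="predicted (smoothed)", color="C1")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("head position")
    ax.set_ylim(-1.4, 1.4)
    label = f"r={report.r:.2f}  MSE={report.mse:.2f}"
    ax.set_title(f"{title}  {label}".strip())
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_transfer_matrix(m: TransferMatrix, path: str | Path, metric: str = "r") -> None:
    """Gray-banded grid of transfer scores (white/gray/dark = strong/moderate/weak)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = m.r_grid if metric == "r" else m.mse_grid
    n_s, n_t = grid.shape
    fig, ax = plt.subplots(figsize=(1 + 0.6 * n_t, 1 + 0.5 * n_s))
    for i in range(n_s):
        for j in range(n_t):
            ax.add_patch(
                plt.Rectangle(
                    (j, n_s - 1 - i), 1, 1,
                    facecolor=_BAND_SHADE[m.band_grid[i][j]],
                    edgecolor="k", lw=0.5,
                )
            )
            ax.text(
                j + 0.5, n_s - 0.5 - i, f"{grid[i, j]:.2f}",
                ha="center", va="center", fontsize=7,
            )
    ax.set_xlim(0, n_t)
    ax.set_ylim(0, n_s)
    ax.set_xticks(np.arange(n_t) + 0.5, m.targets, fontsize=7)
    ax.set_yticks(np.arange(n_s) + 0.5, m.sources[::-1], fontsize=7)
    ax.set_xlabel("test unit")
    ax.set_ylabel("training unit")
    ax.set_title(f"transfer {metric} (shading: correlation band)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
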