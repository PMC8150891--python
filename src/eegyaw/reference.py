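"""Reference performance figures from the original ten-participant study.

The pipeline re-implements a published head-yaw decoding experiment whose
recordings are not publicly available.  The study's printed summary scores
are kept here as plain data so that threshold logic (correlation banding,
band tallies) can be exercised against them:

* ``FIRST_ANALYSIS_SCORES`` -- per-file (MSE, r) on the held-out second half
  of each of the 29 recordings (10 participants; P1 and P2 contributed 10
  files each, P10 two, the rest one).
* ``P1_CROSS_FILE_R`` -- the 10x10 grid of r values obtained by training on
  each P1 file and testing on every P1 file (rows = training file).
* ``HEAD_POSITION_OCCUPANCY`` -- per-file percentage of session time spent
  left / forward / right.
"""

from __future__ import annotations

__all__ = [
    "FIRST_ANALYSIS_SCORES",
    "P1_CROSS_FILE_R",
    "HEAD_POSITION_OCCUPANCY",
]

# (participant, file, mse, r) on the test half, first analysis
FIRST_ANALYSIS_SCORES: list[tuple[str, str, float, float]] = [
    ("P1", "F1", 0.12, 0.86),
    ("P1", "F2", 0.20, 0.80),
    ("P1", "F3", 0.32, 0.78),
    ("P1", "F4", 0.14, 0.84),
    ("P1", "F5", 0.26, 0.78),
    ("P1", "F6", 0.21, 0.71),
    ("P1", "F7", 0.30, 0.61),
    ("P1", "F8", 0.37, 0.48),
    ("P1", "F9", 0.42, 0.79),
    ("P1", "F10", 0.38, 0.38),
    ("P2", "F1", 0.31, 0.71),
    ("P2", "F2", 0.19, 0.86),
    ("P2", "F3", 0.12, 0.88),
    ("P2", "F4", 0.16, 0.86),
    ("P2", "F5", 0.16, 0.82),
    ("P2", "F6", 0.29, 0.82),
    ("P2", "F7", 0.30, 0.78),
    ("P2", "F8", 0.28, 0.57),
    ("P2", "F9", 0.27, 0.76),
    ("P2", "F10", 0.35, 0.87),
    ("P3", "F1", 0.31, 0.82),
    ("P4", "F1", 0.02, 0.98),
    ("P5", "F1", 0.13, 0.91),
    ("P6", "F1", 0.37, 0.59),
    ("P7", "F1", 0.35, 0.66),
    ("P8", "F1", 0.33, 0.76),
    ("P9", "F1", 0.33, 0.78),
    ("P10", "F1", 0.18, 0.89),
    ("P10", "F2", 0.32, 0.93),
]

# r values: train on P1 file (row) -> test on P1 file (column), F1..F10
P1_CROSS_FILE_R: list[list[float]] = [
    [0.90, -0.18, -0.21, -0.73, -0.39, -0.74, 0.40, -0.17, -0.35, -0.15],
    [-0.23, 0.78, 0.59, -0.79, -0.70, -0.78, -0.32, -0.21, -0.42, -0.47],
    [-0.33, 0.52, 0.71, -0.80, -0.65, -0.81, -0.19, -0.35, -0.10, -0.14],
    [0.01, -0.59, -0.56, 0.84, 0.73, 0.82, 0.04, 0.57, 0.15, 0.19],
    [0.06, -0.53, -0.50, 0.84, 0.82, 0.84, 0.49, -0.09, -0.01, 0.08],
    [0.17, -0.54, -0.47, 0.84, 0.76, 0.85, 0.37, -0.15, 0.13, 0.13],
    [0.70, -0.14, -0.14, 0.70, 0.60, 0.70, 0.67, 0.27, -0.07, -0.02],
    [-0.11, -0.48, -0.40, 0.80, 0.68, 0.81, 0.35, 0.55, 0.31, 0.08],
    [-0.69, -0.06, 0.22, 0.41, 0.33, 0.45, 0.39, 0.07, 0.80, 0.68],
    [-0.66, -0.32, 0.00, 0.78, 0.52, 0.77, 0.20, 0.31, 0.83, 0.79],
]

# (participant, file, %left, %forward, %right)
HEAD_POSITION_OCCUPANCY: list[tuple[str, str, float, float, float]] = [
    ("P1", "F1", 14.2, 59.5, 26.3),
    ("P1", "F2", 28.9, 60.7, 10.5),
    ("P1", "F3", 18.0, 59.9, 22.1),
    ("P1", "F4", 12.0, 60.3, 27.7),
    ("P1", "F5", 11.9, 60.3, 27.8),
    ("P1", "F6", 18.5, 60.9, 20.6),
    ("P1", "F7", 17.9, 61.5, 20.6),
    ("P1", "F8", 20.2, 59.6, 20.2),
    ("P1", "F9", 16.7, 59.9, 23.4),
    ("P1", "F10", 22.8, 61.1, 16.1),
    ("P2", "F1", 21.6, 60.7, 17.7),
    ("P2", "F2", 19.1, 59.8, 21.2),
    ("P2", "F3", 12.7, 60.3, 27.1),
    ("P2", "F4", 22.9, 61.7, 15.4),
    ("P2", "F5", 17.5, 61.3, 21.2),
    ("P2", "F6", 11.0, 60.4, 28.6),
    ("P2", "F7", 17.0, 59.5, 23.5),
    ("P2", "F8", 30.5, 60.9, 8.7),
    ("P2", "F9", 23.3, 62.0, 14.7),
    ("P2", "F10", 17.0, 60.1, 22.9),
    ("P3", "F1", 19.1, 59.6, 21.3),
    ("P4", "F1", 25.9, 59.3, 14.8),
    ("P5", "F1", 16.8, 60.0, 23.2),
    ("P6", "F1", 11.0, 60.7, 28.4),
    ("P7", "F1", 23.0, 61.7, 15.8),
    ("P8", "F1", 25.5, 61.7, 12.8),
    ("P9", "F1", 19.7, 60.4, 19.9),
    ("P10", "F1", 24.8, 59.6, 15.6),
    ("P10", "F2", 22.1, 59.9, 18.0),
]
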