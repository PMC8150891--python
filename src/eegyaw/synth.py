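"""Synthetic lamp-stimulus EEG sessions.

Emulates the acquisition protocol of a head-yaw decoding experiment: a lamp
on the participant's left or right switches on for 6-9 s, the participant
turns the head towards it, the lamp switches off and the head returns to the
forward position.  Three EEG channels (O1, O2, Cz) are synthesized at 500 Hz
with a planted, subject-specific coupling between head position and the
signal, plus EEG-like background noise, 50 Hz mains interference and slow
drift.

The planted coupling amplitude-modulates a subject-specific beta-band
carrier (15-35 Hz) with a saturating (tanh) transform of the lagged, ramped
head-position trace; the left and right turn directions load the channels
through spatial patterns 30 degrees apart.  Sustained posture therefore
appears as sustained in-band rhythmic power -- a stylised stand-in for
posture-locked mu/EMG activity -- which survives the 1 Hz high-pass of the
preprocessing chain and is exactly recoverable by a static nonlinear map of
a short sample window.  A dominant waxing-waning alpha rhythm (8-13 Hz,
subject-specific direction and frequency) plays the role of the main
task-irrelevant background; it is what makes decoders subject-specific in
practice.  See docs/methods.md for the full generative model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubjectProfile",
    "EventSchedule",
    "Recording",
    "LabelTrace",
    "make_schedule",
    "clean_profile",
    "make_labels",
    "synthesize_recording",
    "random_profile",
    "schedule_occupancy",
]

#: default sampling rate of the acquisition system, Hz
DEFAULT_FS = 500.0
#: channel names, International 10/20 system
CHANNELS = ("O1", "O2", "CZ")

# stimulus timing (seconds)
ON_MIN, ON_MAX = 6.0, 9.0         # lamp-on duration range
GAP_MIN = 5.0                     # enforced inactive period after lamp-off
GAP_EXTRA_MAX = 12.5              # random idle extension; E[gap] = 11.25 s
                                  # -> E[forward occupancy] = 0.60

# planted-coupling constants
AMP_SCALE = 1.0e-5                # volts; x1e5 amplification maps to [-1, 1]
DRIVE_GAIN = 1.5                  # tanh saturation of the +-1 drive
RAMP_S = 0.1                      # head-movement ramp, s (quick head turn)
CARRIER_LO, CARRIER_HI = 15.0, 35.0  # per-subject carrier band (beta), Hz
CARRIER_MIN_SEP = 4.0             # min separation of left/right carriers, Hz
CHANNEL_PHASES = (0.0, np.pi / 2, np.pi / 4)  # quadrature diversity


@dataclass
class SubjectProfile:
    """Subject-specific generative parameters.

    ``mixing_weights`` scales the movement-locked component per channel
    (O1, O2, Cz); ``carrier_freqs`` are the (right, left) carrier
    frequencies in Hz (``random_profile`` draws a single shared frequency;
    distinct values are allowed).  ``response_lag`` is an idiosyncratic
    extra motor delay in samples on top of the schedule-level reaction
    lag.
    """

    subject_id: str
    mixing_weights: tuple[float, float, float] = (0.9, 0.8, 0.7)
    response_lag: int = 0
    noise_sd: float = 4.0e-6       # volts, background (pink+white) RMS
    line_amp: float = 1.0e-5       # volts, 50 Hz mains amplitude
    drift_amp: float = 2.0e-5      # volts, slow-drift scale
    seed: int = 0
    carrier_freqs: tuple[float, float] = (18.0, 27.0)
    phase_offset: float = 0.0
    # signed per-channel loading of each side's component; turning activates
    # lateralised (contralateral) sources, so the two patterns differ
    side_pattern_right: tuple[float, float, float] = (0.9, -0.35, 0.55)
    side_pattern_left: tuple[float, float, float] = (-0.35, 0.9, 0.55)
    # ongoing occipital alpha: the dominant background rhythm; its amplitude
    # waxes and wanes on a seconds scale, uncorrelated with the task
    alpha_amp: float = 1.2e-5      # volts (median envelope)
    alpha_freq: float = 10.0       # Hz
    alpha_pattern: tuple[float, float, float] = (0.75, 0.6, 0.3)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.response_lag < 500:
            raise ValueError("response_lag must be in [0, 500) samples")


@dataclass
class EventSchedule:
    """Lamp on/off schedule: (onset_s, duration_s, side) per stimulus."""

    events: list[tuple[float, float, str]]
    session_length_s: float

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for onset, dur, side in self.events:
            if side not in ("left", "right"):
                raise ValueError(f"unknown side {side!r}")
            if onset < prev_end:
                raise ValueError("events overlap or are unsorted")
            prev_end = onset + dur


@dataclass
class Recording:
    """Multichannel EEG trace in volts."""

    channels: tuple[str, ...]
    fs: float
    data: np.ndarray               # shape (n_channels, n_samples)
    subject_id: str = ""
    file_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class LabelTrace:
    """Head-position trace: -1 left, 0 forward, +1 right (then smoothed)."""

    y: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1:
            raise ValueError("y must be 1-D")
        if np.any(np.abs(self.y) > 1 + 1e-12):
            raise ValueError("labels must lie in [-1, 1]")


def make_schedule(session_length_s: float, rng_seed: int) -> EventSchedule:
    """Draw a random lamp schedule.

    Lamp-on durations are uniform on [6, 9] s; after each event the lamp is
    inactive for at least 5 s, extended by a uniform idle period so that the
    expected forward (no-lamp) occupancy is ~60% of the session, matching
    the head-position occupancy statistics of the protocol.  Sides are
    uniform.  Deterministic for a given seed.
    """
    min_cycle = GAP_MIN + ON_MIN + GAP_MIN
    if session_length_s < 30:
        raise ValueError(
            f"session_length_s={session_length_s} too short: need >= 30 s "
            f"for one full on+off cycle ({min_cycle:.0f} s)"
        )
    rng = np.random.default_rng(rng_seed)
    events: list[tuple[float, float, str]] = []
    t = 0.0
    while True:
        gap = GAP_MIN + rng.uniform(0.0, GAP_EXTRA_MAX)
        dur = rng.uniform(ON_MIN, ON_MAX)
        side = "left" if rng.uniform() < 0.5 else "right"
        onset = t + gap
        if onset + dur > session_length_s:
            break
        events.append((onset, dur, side))
        t = onset + dur
    return EventSchedule(events=events, session_length_s=session_length_s)


def schedule_occupancy(schedule: EventSchedule) -> dict[str, float]:
    """Fraction of session time in each head state implied by the lamp."""
    total = schedule.session_length_s
    left = sum(d for _, d, s in schedule.events if s == "left")
    right = sum(d for _, d, s in schedule.events if s == "right")
    return {
        "left": left / total,
        "right": right / total,
        "forward": 1.0 - (left + right) / total,
    }


def make_labels(
    schedule: EventSchedule, fs: float, reaction_lag_s: float = 0.25
) -> LabelTrace:
    """Per-sample head position: +-1 during (lagged) lamp-on, 0 otherwise.

    left -> -1, right -> +1.  ``reaction_lag_s`` shifts the response after
    the lamp transition (default 0.25 s, a typical visuomotor latency).
    Intervals are half-open on 0-based sample indices.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if reaction_lag_s < 0:
        raise ValueError("reaction_lag_s must be >= 0")
    n = int(round(schedule.session_length_s * fs))
    y = np.zeros(n)
    for onset, dur, side in schedule.events:
        a = int(round((onset + reaction_lag_s) * fs))
        b = int(round((onset + dur + reaction_lag_s) * fs))
        y[max(a, 0) : min(b, n)] = -1.0 if side == "left" else 1.0
    return LabelTrace(y=y, fs=fs)


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    # local copy to avoid importing preprocess (which imports nothing here,
    # but synth must stay dependency-free within the package)
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(1, x.size + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]                      # avoid division by zero at DC
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def latent_drive(labels: LabelTrace, profile: SubjectProfile) -> np.ndarray:
    """Smooth, lagged, saturated movement drive u(t) in (-1, 1).

    The ramp is a *centered* moving average: the physical head position
    (and the posture-locked activity it drives) transitions symmetrically
    around each lamp event, whereas the label coding smooths causally and
    therefore trails it by about half the ramp.
    """
    ramp = max(int(round(RAMP_S * labels.fs)), 1)
    kernel = np.ones(ramp) / ramp
    u = np.convolve(labels.y, kernel, mode="same")
    if profile.response_lag > 0:
        u = np.concatenate([np.zeros(profile.response_lag), u])[: u.size]
    return np.tanh(DRIVE_GAIN * u)


def _alpha_rhythm(
    n: int, fs: float, profile: SubjectProfile, rng: np.random.Generator
) -> np.ndarray:
    """Waxing-waning background alpha, (3, n), volts.

    Log-normal envelope from an Ornstein-Uhlenbeck process with a ~2 s
    correlation time; the rhythm occupies a fixed per-subject spatial
    direction with quadrature-offset channel phases.
    """
    if profile.alpha_amp == 0:
        return np.zeros((3, n))
    from scipy.signal import lfilter

    tau = 2.0 * fs                       # envelope correlation time, samples
    a = np.exp(-1.0 / tau)
    innov = rng.standard_normal(n) * np.sqrt(1 - a**2)
    innov[0] = rng.standard_normal()     # stationary start
    z = lfilter([1.0], [1.0, -a], innov)
    envelope = np.exp(0.6 * z - 0.18)    # median ~0.84, mean ~1
    t = np.arange(n) / fs
    psi = rng.uniform(0, 2 * np.pi)
    out = np.empty((3, n))
    for c in range(3):
        out[c] = (
            profile.alpha_amp
            * profile.alpha_pattern[c]
            * envelope
            * np.cos(2 * np.pi * profile.alpha_freq * t + psi + CHANNEL_PHASES[c])
        )
    return out


def synthesize_recording(
    schedule: EventSchedule,
    labels: LabelTrace,
    profile: SubjectProfile,
    fs: float = DEFAULT_FS,
) -> Recording:
    """Render the three-channel EEG trace for one session.

    Each channel is

        w_c * A * [aR_c u+(t) cos(2 pi fR t + phi_c)
                   + aL_c u-(t) cos(2 pi fL t + phi_c)]
        + noise_sd * (0.7 pink + 0.3 white)
        + line_amp * sin(2 pi 50 t + phase)
        + drift_amp * slow random walk

    where ``u`` is the tanh-saturated, ramped, lagged label, ``u+/u-`` its
    rectified right/left parts, A = 1e-5 V, and the side patterns (aR, aL),
    carriers (fR, fL) and phases phi_c come from the subject profile.  The
    side-specific spatial patterns are what make the mapping decodable with
    sign within a subject yet idiosyncratic across subjects.  Deterministic
    per profile seed.
    """
    n = labels.y.size
    expected = int(round(schedule.session_length_s * fs))
    if n != expected:
        raise ValueError(
            f"labels length {n} inconsistent with schedule "
            f"({expected} samples at {fs} Hz)"
        )
    t = np.arange(n) / fs
    u = latent_drive(labels, profile)
    u_r = np.maximum(u, 0.0)
    u_l = np.maximum(-u, 0.0)
    f_r, f_l = profile.carrier_freqs

    ss = np.random.SeedSequence(profile.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]

    data = np.empty((3, n))
    line_phase = rngs[3].uniform(0, 2 * np.pi)
    alpha = _alpha_rhythm(n, fs, profile, rngs[4])
    for c in range(3):
        phi = CHANNEL_PHASES[c] + profile.phase_offset
        signal = (
            AMP_SCALE
            * profile.mixing_weights[c]
            * (
                profile.side_pattern_right[c]
                * u_r
                * np.cos(2 * np.pi * f_r * t + phi)
                + profile.side_pattern_left[c]
                * u_l
                * np.cos(2 * np.pi * f_l * t + phi)
            )
        )
        noise = profile.noise_sd * (
            0.7 * _pink_noise(n, rngs[0]) + 0.3 * rngs[0].standard_normal(n)
        )
        drift = profile.drift_amp * _trailing_mean(
            np.cumsum(rngs[1].standard_normal(n)) / np.sqrt(n), int(fs)
        )
        line = profile.line_amp * np.sin(2 * np.pi * 50.0 * t + line_phase)
        data[c] = signal + alpha[c] + noise + line + drift
    return Recording(
        channels=CHANNELS,
        fs=fs,
        data=data,
        subject_id=profile.subject_id,
    )


def clean_profile(subject_id: str = "clean", seed: int = 0) -> SubjectProfile:
    """Noise-free planted subject: coupling only, no background activity.

    Used for exact-recovery checks: background noise, mains, drift and
    alpha are all off and the motor lag is zero.
    """
    return SubjectProfile(
        subject_id=subject_id,
        response_lag=0,
        noise_sd=0.0,
        line_amp=0.0,
        drift_amp=0.0,
        seed=seed,
        alpha_amp=0.0,
    )


def random_profile(
    subject_id: str,
    seed: int,
    noise_sd: float = 4.0e-6,
    line_amp: float = 1.0e-5,
    drift_amp: float = 2.0e-5,
) -> SubjectProfile:
    """Draw an idiosyncratic subject: random weights, carrier, patterns, lag.

    The movement-locked rhythm sits at one subject-specific beta frequency
    for both sides; the sides differ only by a 30 degree rotation of the
    spatial loading pattern.  A decoder identified on the subject's own
    data amplifies exactly that small spatial difference, while a decoder
    identified on another subject responds to both sides almost equally --
    and its slow output fluctuations are dominated by the (much stronger,
    subject-specific) waxing-waning alpha background.  Together these are
    the planted basis of cross-subject transfer failure.
    """
    rng = np.random.default_rng(seed)
    w = tuple(rng.uniform(0.6, 1.0, size=3).round(6))
    f_s = float(rng.uniform(CARRIER_LO, CARRIER_HI))
    # side patterns: random unit vector and its 30-degree rotation
    p = rng.standard_normal(3)
    p /= np.linalg.norm(p)
    o = rng.standard_normal(3)
    o -= (o @ p) * p
    o /= np.linalg.norm(o)
    theta = np.deg2rad(30.0)
    q = np.cos(theta) * p + np.sin(theta) * o
    alpha_dir = rng.standard_normal(3)
    alpha_dir /= np.linalg.norm(alpha_dir)
    return SubjectProfile(
        subject_id=subject_id,
        mixing_weights=w,
        response_lag=int(rng.integers(0, 50)),
        noise_sd=noise_sd,
        line_amp=line_amp,
        drift_amp=drift_amp,
        seed=int(rng.integers(0, 2**31 - 1)),
        carrier_freqs=(f_s, f_s),
        phase_offset=float(rng.uniform(0, 2 * np.pi)),
        side_pattern_right=tuple(p.round(6)),
        side_pattern_left=tuple(q.round(6)),
        alpha_amp=float(rng.uniform(1.6e-5, 2.8e-5)),
        alpha_freq=float(rng.uniform(8.0, 13.0)),
        alpha_pattern=tuple(alpha_dir.round(6)),
    )
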