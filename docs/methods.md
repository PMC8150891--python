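# Methods

## The decoding model

Head position is treated as a continuous regression target
y(t) ∈ [−1, 1] (−1 left, 0 forward, +1 right after 0.6 s linear
smoothing). The decoder is a static windowed map: the 10 most recent
preprocessed EEG sample vectors (3 channels → 30 features) predict the
label at the next sample. The map is a one-hidden-layer perceptron with 10
tanh units and a linear output (321 parameters), a deliberately small
architecture: with a 20 ms input window the decodable information is the
instantaneous amplitude/pattern of in-band oscillations, and a shallow
nonlinear map suffices for that demodulation.

Training is full-batch Levenberg–Marquardt on the sum of squared errors.
The residual Jacobian J = ∂ŷ/∂θ is computed analytically in one
backpropagation pass; each iteration solves (JᵀJ + μI)Δθ = Jᵀe (Cholesky;
JᵀJ is 321², trivially small) and accepts the candidate only if the SSE
decreases, dividing μ by 10 on acceptance and multiplying by 10 on
rejection. Stopping: gradient ∞-norm < 1e−7, SSE < 1e−12, μ > 1e10, or the
accepted-step budget. Initial weights are uniform in [−0.5, 0.5] scaled by
1/√fan-in, drawn from the training seed; training is deterministic given
data and seed. There is no internal validation split or early stopping —
the only held-out structure is the chronological half split of each file.

Sign convention: J is the Jacobian of the *predictions*, so with
e = y − ŷ the update +(JᵀJ + μI)⁻¹Jᵀe is a descent direction,
interpolating between Gauss–Newton (μ→0) and a scaled gradient step
(μ→∞).

## Preprocessing

Fixed order, per channel, zero-phase (forward–backward) 4th-order
Butterworth IIR filters:

1. 49–51 Hz band-stop. Its purpose is mains removal, so it is a *stop*
   band; a pass-band there would retain only line noise. Whether the
   original acquisition used a causal or zero-phase filter is unknown;
   zero-phase is the default and both are available via `FilterSpec`.
2. 1 Hz high-pass (drift/DC removal).
3. Amplification ×10⁵ and clipping to [−1, 1]. Raw synthetic EEG is
   treated as volts (tens of µV), so ×10⁵ places typical amplitudes in the
   clip range rather than saturating it.

Labels and predictions are smoothed with the same *trailing* moving mean:
the average of the current and preceding window−1 samples (window 300 =
0.6 s at 500 Hz; the prediction smoother's summation bounds include the
current sample). Partial windows at the sequence start use the available
prefix mean, so no samples are discarded. Sample indexing is 0-based with
half-open intervals throughout.

The dataset split is strictly causal: features end at t−1, the target sits
at t, the first ⌊n/2⌋ windowed examples form the training set and the
remainder (including the extra example of odd-length files) the test set.
Windowing is applied per file before any concatenation, so no feature
window straddles a file boundary.

## The synthetic session generator

The generator defines the study conditions; everything below is a fixed
default, not a tuning knob.

**Stimulus schedule.** Lamp-on durations are uniform on [6, 9] s and sides
uniform. After each event the lamp is inactive for 5 s plus a uniform idle
extension on [0, 12.5] s, giving an expected forward occupancy of 60% —
the occupancy actually observed in the protocol (~59–62% forward, ~20%
per side). A fixed 5 s gap would instead put the head at a side 60% of the
time, contradicting those statistics, so the 5 s figure is read as the
*minimum* inactive period. Session-level generation redraws schedules
until both sides occur in each half of the session, mirroring the
protocol's guarantee that training material covers all three positions.

**Labels.** y = ±1 during lamp-on intervals shifted by a 0.25 s reaction
lag (typical visuomotor latency; configurable), 0 otherwise.

**Planted coupling.** The head-movement drive is
u(t) = tanh(1.5 · m(t − ℓ)), where m is the label convolved with a
*centered* 0.1 s box (a quick head turn, symmetric around the event
boundary) and ℓ an idiosyncratic motor lag drawn per subject from
[0, 0.1] s. The drive amplitude-modulates a subject-specific beta-band
carrier (one frequency per subject, uniform on 15–35 Hz): each channel
receives

    A · w_c · [a_c^R u⁺(t) + a_c^L u⁻(t)] · cos(2π f_s t + φ_c)

with A = 1e−5 V, per-channel gains w_c ∈ [0.6, 1], and side-specific
spatial patterns a^R, a^L — random unit vectors 30° apart. Physically this
is a stylised stand-in for posture-locked rhythmic (mu/EMG-like) activity:
sustained in-band power while the head is held turned, lateralised
contralaterally. Three design facts matter:

- *Why oscillatory*: a plateau-coded coupling cannot survive the 1 Hz
  high-pass (a 6–9 s plateau is attenuated by ~70 dB), leaving only edge
  transients that a 20 ms window cannot convert into sustained
  predictions. Amplitude modulation of an in-band carrier passes both
  filters and is exactly demodulable by a static nonlinear window map.
- *Why a centered movement ramp*: the physical position (and the neural
  activity locked to it) leads the causally smoothed label by half the
  0.6 s smoothing window; the trailing prediction smoother then re-aligns
  the decoder output with the label. This is precisely the regime in which
  the prediction smoothing is beneficial rather than a pure delay.
- *Why a 30° pattern rotation*: a subject's own decoder amplifies the
  small spatial difference between the sides, while a decoder identified
  on another subject responds to both sides nearly equally — the planted
  basis of cross-subject failure.

**Background activity.** Each subject carries a dominant waxing-waning
alpha rhythm (8–13 Hz, fixed random spatial direction, lognormal envelope
from an Ornstein–Uhlenbeck process with ~2 s correlation time, median
amplitude 1.6–2.8e−5 V — deliberately stronger than the coupling, as real
occipital alpha is), plus a 0.7/0.3 pink/white noise mixture
(default RMS 4e−6 V), a 50 Hz mains sine (1e−5 V) and a slow drift random
walk (2e−5 V scale). The within-subject decoder learns to reject its own
alpha (different frequency and direction from the coupling); a foreign
decoder does not, and its slow output fluctuations become alpha-dominated,
deflating cross-subject correlations towards zero. The default noise level
places within-file held-out r in ~0.9–0.97, the strong end of the regime
the protocol reports.

All session randomness derives from one seed via `numpy.random.SeedSequence`
spawning; identical seeds give byte-identical sessions.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis depends on: sampling
rate and montage, stimulus timing and occupancy, ternary smoothed labels,
subject-specific decodable coupling, dominant task-irrelevant rhythms,
1/f noise, mains interference and drift. It does **not** attempt
physiological realism: no evoked-potential morphology, no ocular/cardiac
artifacts, no electrode-contact or impedance effects, no time-varying
coupling within a session. Passing tests therefore demonstrate that the
*pipeline* is correct and that the experimental logic (within-file
identifiability, cross-subject specificity) behaves as designed — not that
real EEG would yield the same numbers. In particular the default synthetic
regime is cleaner than real recordings, whose published per-file r values
spread over 0.38–0.98.

## Numerical choices

- Trailing means are computed via cumulative sums (O(n)); window 1 is an
  exact identity, and constants are preserved to ~1e−16 relative error.
- Band thresholds implement the published table literally: strong
  r ∈ [0.50, 1], moderate [0.30, 0.50), weak below — negative r is weak.
- Pearson r is undefined for constant inputs and is returned as NaN with a
  warning (band `None`), never silently 0.
- The Cholesky solve of the damped normal equations falls back to raising
  μ when the matrix is numerically singular (μ = 0 is the caller's risk).
- MSE is reported against the smoothed prediction (the primary score) and
  against the raw prediction (`mse_raw`, secondary), since the two
  published error definitions differ in which trace they use.
- Transfer grids train one model per source unit with seed = base + row
  index, so the whole matrix is reproducible from one seed.
- In the per-participant transfer layout the diagonal is in-sample
  (identified and verified on the same data), replicating how such grids
  are conventionally reported; the code emits a warning noting it.

## Problem sizes

Roster simulation defaults to the study's conditions: 29 files over 10
subjects (P1, P2: 10 each; P10: 2; P3–P9: 1), 300–400 s per file at
500 Hz. The published table labels these 300–400 values a duration in
seconds while the accompanying text calls them sample counts; they are
consistent with 5-minute sessions only as seconds, which is how the
simulator reads them. The acceptance tests and `scripts/acceptance.py`
exercise the identical pipeline at reduced sizes chosen as the smallest
that leave the phenomena comfortably measurable: 120 s sessions
(~30 000 training windows) for within-file recovery and 60 s sessions with
a 50-step budget for the 10×10 transfer grid. LM training cost is dominated
by the n·321² JᵀJ accumulation, linear in session length.

## Known limitations

- The 30-10-1 architecture and LM hyperparameters (μ₀ = 1e−3, ×÷10,
  μ_max = 1e10) are fixed defaults; no architecture search is provided.
- Cross-subject failure is *planted* (carriers, patterns and alpha differ
  per subject); the package demonstrates the phenomenon, it cannot prove
  it for real EEG.
- The per-file transfer layout trains on a file's first half; whether the
  original grids were built that way or from full files is not specified,
  so `cross_matrix` exposes both (`train_on_half`).
- Statistical significance of r is not computed; banding is the only
  qualitative summary.
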