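# Methods

## The problem

A brain-state-dependent stimulation system must act at a *specific phase*
of an ongoing EEG oscillation — for example, deliver a visual stimulus at
the peak (0 rad) or trough (π rad) of the occipital alpha rhythm
(8–13 Hz). Doing so in real time is hard because causal filtering and the
Hilbert transform both need future data: a zero-phase bandpass and an
analytic-signal phase are only trustworthy away from the edges of the
analysed window. The standard remedy is to filter a recent window, discard
its unreliable edges, and *forward-predict* the filtered signal with an
autoregressive (AR) model so that the instant of interest ("time-zero",
the most recent acquired sample) is again covered by data.

`phaseloop` is a desk-scale, fully software re-creation of such a
closed loop: a synthetic EEG source with known ground-truth phase, the
causal online pipeline, two AR forecasters (conventional Yule–Walker and
adaptive least-mean-squares), phase-crossing trigger logic, and the
circular statistics used to score the result. Everything is deterministic
given a seed.

## The online pipeline

Per newly acquired sample at the 500 Hz processing rate (one-sample hop):

1. **Decimation** — raw input at 2 kHz is low-passed (101-tap FIR, cutoff
   200 Hz, Hamming) and every 4th sample kept. Filter state is carried
   across chunks; chunked and whole-record decimation agree bit-for-bit.
2. **Windowing** — the most recent 500 samples (1 s) form the analysis
   window; processing starts once the window has filled.
3. **Demeaning** — the window mean is subtracted.
4. **Two-pass bandpass** — a 129-tap (order 128) linear-phase FIR,
   8–13 Hz, windowed-sinc design with a Hamming window, applied forward
   then backward over the window. The two passes cancel the phase lag
   exactly; no padding is used, and the filter transients are removed by
   the next step. The design is normalised to unity gain at the band
   centre (10.5 Hz); the 85-sample trim comfortably exceeds the 64-sample
   group delay of a single pass.
5. **Edge trim** — 85 samples are dropped from each side, leaving 330
   valid samples that end 85 samples (170 ms) before time-zero.
6. **Forward prediction** — an AR(30) model extrapolates the trimmed
   window. The prediction spans the 85 samples back up to time-zero
   *plus* a further 85-sample pad (see below), i.e. 170 samples.
7. **Phase readout** — the analytic signal (FFT Hilbert transform) of the
   known + predicted concatenation is evaluated at the time-zero index
   and its argument taken as the instantaneous phase estimate. The
   convention is that of a cosine: 0 rad at a positive peak, π at a
   trough.
8. **Trigger** — a trigger fires when the wrapped distance of the
   estimate to the target phase crosses zero from below, provided the
   per-sample phase advance is plausible (|Δθ| < π/2, rejecting wrap
   artefacts) and a refractory interval (default 500 ms) has elapsed
   since the last trigger. Triggers are suppressed during a 2 s warm-up
   so the adaptive filter has converged.

In the hot loop the phase readout uses a cached single row of the
analytic-signal operator (the analytic signal is a circular convolution,
so one output sample is a fixed inner product). This is numerically
identical to running the full transform — the test suite asserts
agreement to 1e-10 — and makes each pipeline step O(n) rather than
O(n log n).

### Why the readout is interior, not terminal

If the forecast stops exactly at time-zero, the phase must be read at the
*last* sample of the analytic window. The argument of a finite window's
analytic signal at its terminal sample is severely biased by spectral
leakage — measured here at +0.5 to +0.9 rad on 10 dB synthetic alpha and
up to 2.6 rad on a pure 10 Hz tone, with the sign and size depending on
the fractional number of cycles in the window. A trigger rule driven by
that estimate places triggers ~40 ms away from the true peak even on a
noiseless tone. Extending the forecast one trim margin (85 samples,
`forecast_pad`) past time-zero and reading the phase at the (now
interior) time-zero index removes this bias at the cost of 85 more
predicted samples; on a noiseless tone the triggers then land within one
sample of the true peaks, and on 10 dB alpha the mean targeting error
drops below 0.25 rad. The pad is therefore the default. Setting
`forecast_pad=0` restores the strictly terminal readout (prediction ends
exactly at time-zero) for comparison; expect a large constant phase
offset in that mode. A pleasant side effect of the default is that the
analytic window length is 500 samples.

## Forecasters

**Yule–Walker (yw).** Each window, AR(30) coefficients are fitted to the
330 trimmed samples by solving the Yule–Walker normal equations with the
*biased* sample autocovariance (divide by n) via the Levinson–Durbin
recursion. The biased estimator keeps the Toeplitz system positive
semidefinite, so all reflection coefficients have magnitude < 1 and the
fitted recursion is stable: forecasts of bounded windows stay bounded
(the suite checks a 10× guard). The cost of that built-in regularisation
is pole-radius shrinkage on nearly deterministic inputs: on a noiseless
sinusoid the fitted poles sit at radius ≈ 0.94 for a 330-sample window,
so long forecasts decay toward zero. This is inherent to the biased
estimator (the same behaviour as MATLAB's `aryule`), one more reason the
phase readout must not sit at the very end of the forecast.

**Adaptive LMS (lms).** A persistent weight vector A(t) (zero-initialised,
K = 30) is updated by the stochastic-gradient rule
y(t) = A(t)ᵀX(t), e(t) = x(t+1) − y(t), A(t+1) = A(t) + 2μ e(t) X(t),
once per newly acquired valid sample (the newest trimmed sample is
predicted from the 30 preceding it), so adaptation accumulates across
windows rather than being refitted per window. Plain LMS stability
depends on input power, so by default the update operates on the window
normalised by its RMS, making the default step size μ = 0.001 scale-free
(an effective step of 2μK ≈ 0.06 per update for unit-power input; time
constant of a few hundred updates, hence the 2 s warm-up). The
un-normalised rule is available (`lms_normalize=False`) but then μ must
be chosen against the signal scale — the classic LMS divergence knob.
Weights are frozen while a forecast is rolled out.

Both forecasters feed the same recursion
x̂(t+1) = Σₖ αₖ x(t−k), predictions fed back as inputs, implemented as
the zero-input response of the corresponding all-pole filter
(`scipy.signal.lfiltic`/`lfilter`) and verified against the naive loop.

## Synthetic EEG

The generator emulates a single occipital channel in microvolts at 2 kHz:

* **Alpha component** — white Gaussian noise shaped in the Fourier domain
  to a Gaussian spectral peak at `alpha_center` (default 10 Hz) with
  `alpha_fwhm` (default 1.0 Hz FWHM), RMS `amplitude` (default 5 µV).
  This is the "sinusoid with slowly drifting amplitude and frequency"
  picture of alpha: a ~1 Hz-wide peak has a coherence time of the order
  of a second, which matches the published width of individual resting
  alpha peaks and is what makes 170 ms forecasting feasible at all. A
  flat 8–13 Hz band would have ~200 ms coherence and be essentially
  unpredictable at this horizon regardless of method — that is a property
  of the process, not of the predictor. The width is a configuration
  field, so harder regimes can be studied deliberately.
* **Background** — 1/f^exponent-shaped Gaussian noise (default exponent
  1.0, DC bin zeroed), rescaled so that the ratio of alpha-band
  (8–13 Hz) powers of the two components, measured on the realisation,
  equals `snr_db` exactly. `snr_db=inf` disables it. SNR is defined
  in-band because in-band noise is what limits phase estimation.
* **Deterministic mode** — `alpha_mode="cosine"` produces a pure cosine
  at `alpha_center` with truth phase known in closed form; used for
  exact tests.

`truth_phase` stores the analytic-signal phase of the noiseless alpha
component. For scoring triggers, however, the *offline convention* is
used instead: the mixed record is decimated to 500 Hz, band-passed with
the same 129-tap FIR applied forward-backward over the whole record
(`scipy.signal.filtfilt`), and the Hilbert phase taken; the first and
last 128 samples are flagged edge-unreliable and triggers falling there
are excluded from scoring. This mirrors how a real experiment evaluates
its online predictor (it has no access to the clean component), and
keeps the evaluation independent of the causal pipeline.

What the generator does *not* model: eye blinks and EMG artefacts,
visually evoked responses (so the "visual task" regime of a real
experiment, with its evoked component ~100 ms after the stimulus, has no
analogue here), multi-channel structure, amplifier-mode effects, and
nonstationarity beyond the stochastic amplitude/frequency drift of the
peak. Passing tests therefore demonstrate correct mechanics and
calibrated statistics under a realistic stationary alpha model, not
robustness to artefact-laden recordings.

## Evaluation statistics

For N scored triggers with ground-truth phases θₙ:

* PLF = |Σ e^{iθₙ}| / N; Z = N·PLF² (Rayleigh), significant when
  Z > −ln(0.05) = 2.9957 (displayed 2.995, the conventional truncation).
* Condition averages follow the participant-averaging convention:
  arithmetic mean of Z values, circular mean (atan2 of mean sine and
  cosine) of mean angles.
* Two conditions are compared by the two-sample Watson U² on *recentered*
  samples (circular mean subtracted from each), so only dispersion is
  compared. Significance uses the asymptotic critical value, the root of
  2 Σ (−1)^{k−1} exp(−2k²π²u) = α (0.18688 at α = 0.05, displayed
  0.187). Ties in the pooled sort are processed as a group. Both critical
  values are recomputed analytically, not tabulated, and both are
  verified against seeded Monte-Carlo type-I error in the suite
  (Rayleigh: 10⁵ replicates of N = 1000 uniform phases; Watson: 10⁴
  replicates of two von Mises(κ=2) samples with n = m = 50).
* The phase-triggered response (PTR) averages 1001-sample epochs of the
  raw (unfiltered) 500 Hz signal centred on each trigger; a correct
  peak-targeting run shows a positive local maximum at the centre index,
  a trough-targeting run a negative minimum. Amplitudes are reported in
  the record's native microvolts with no baseline correction.

## Numerical choices and degenerate inputs

* Phases are wrapped to (−π, π] everywhere; the wrap maps −π to +π.
* The Yule–Walker fit demeans its input and rejects zero-variance
  windows (`DegenerateInputError`); Levinson–Durbin aborts if the
  prediction-error power becomes non-positive.
* The circular mean raises `UndefinedMeanError` below a 1e-12 resultant.
* Crossing detection uses half-open logic (previous distance < 0 ≤
  current), so a trigger lands on the first sample at or past the
  target; on a noiseless tone this is a +1-sample (2 ms, 0.126 rad)
  quantisation delay, visible as a small positive mean offset.
* The refractory default of 500 ms (≈ one trigger per 5 alpha cycles) is
  a density knob, not a claim about any real protocol; tests that need
  dense triggers shorten it.
* Filter designs are cached by specification; records are generated with
  `numpy.random.default_rng(seed)` only — no global random state.

## Problem sizes used by the test suite

Deterministic identities are tested at exact or float tolerance. Sizes
for the stochastic checks were fixed in advance of running them: the
closed-loop targeting property uses 300 s of 10 dB alpha per condition
(~550 triggers at the 0.5 s refractory); estimator-recovery checks use
10⁵–10⁶ samples; Monte-Carlo calibrations use the replicate counts given
above; shorter (8–60 s) runs exercise determinism, refractory bounds,
comparison power and the CLI.

## Known limitations

* The alpha-peak width strongly controls attainable phase-locking; the
  shipped default represents a clean resting recording. Real data with
  weak or split alpha peaks will do worse, as will any recording whose
  in-band SNR falls below ~0 dB.
* The simulator scores triggers against an offline filtered phase, which
  is itself an estimate; at very low SNR both the predictor and the
  reference degrade together.
* The LMS route shares the Yule–Walker pipeline's filtered window; a
  streaming LMS on unfiltered data (no per-window refiltering) is not
  modelled.
* Stimulus delivery latency (hardware trigger-to-screen delays) is out of
  scope; triggers are scored at the sample where they are emitted.
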