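# Methods

## Problem and scope

`hrvstage` infers sleep stages from heart-rate variability alone. The input
is a whole night's sequence of inter-beat intervals (IBIs, also called RR
intervals); the output is one label per 30-s epoch from the 4-class alphabet
W (wake), R (REM), N1N2 (light non-REM) and N3 (slow-wave sleep), together
with per-epoch class posteriors. The package covers the full pipeline —
IBI file IO and artifact masking, a 132-feature HRV battery per epoch, a
bidirectional LSTM sequence classifier trained on soft (multi-annotator)
labels, per-night and cohort-level evaluation, and a synthetic whole-night
cohort generator that makes every stage testable without clinical data.
ECG processing (R-peak detection) is out of scope: the package consumes
beat-level data.

Conventions shared by all modules: time starts at 0 s at recording start;
epoch *e* covers the half-open interval [30·e, 30·e+30) seconds; the class
order (W, R, N1N2, N3) is fixed project-wide and every argmax tie breaks
toward the earlier column.

## Feature extraction

Features are computed from windows centred on the epoch's midpoint: 270 s by
default, 510 s for multiscale entropy, 330 s for windowed DFA. At recording
edges the window is truncated (no padding) and used if at least half of its
nominal length remains; otherwise the family is missing for that epoch. A
family is also missing when fewer than 80 % of the window's beats are valid
after cleaning. Missing values are NaN and are never imputed by the
extractor — imputation belongs to the model, which must use training-fold
statistics only.

Cleaning marks beats invalid when RR lies outside [300, 2000] ms or deviates
from the median of the 5 nearest valid neighbours by more than 30 %
(config-overridable; values are retained, only the validity mask changes).

The 15 families (132 columns, order fixed by `hrvstage.registry`):

* **basic (4), variability (12), percentiles (28).** Standard time-domain
  HRV statistics of RR and HR = 60000/RR: means/medians on the raw signal;
  SDNN, range, pNN50, RMSSD, SDSD and MAD on the raw and the linearly
  detrended signal (ordinary least squares versus beat index); percentiles
  5–95 with linear interpolation. Means and medians are reported for the raw
  signal only — after linear detrending they are ≈ 0 and carry no
  information, which is how the 4-count of this family is honoured.
* **DFA (6).** Detrended fluctuation analysis of the RR sequence:
  the profile (cumulative sum of the mean-centred series, with a leading
  zero) is divided into non-overlapping boxes taken from both ends, a line
  is removed per box, and F(n) is the RMS residual. The leading zero plus
  both-ends boxing makes F exactly invariant under time reversal. F(n) is
  divided by √(1 − 4/n²) before the log–log fit: for uncorrelated input
  E[F²(n)] = σ²(n²−4)/(15n) exactly (verified by simulation to 0.5 %), so
  this correction removes the well-known small-scale bias of linear
  detrending and restores α = 0.5 for white noise when fitting from n = 4.
  Emitted: α over scales 4–64, α_short (4–16), α_long (16–64), F(16), WDFA
  (mean α over 270-s sub-windows stepped 30 s through the 330-s window) and
  PDFA (mean per-segment α over consecutive 64-beat segments, scales 4–16).
* **Spectral (4 + 4 + 4).** The RR series (invalid beats linearly
  interpolated, this path only) is resampled to a 4-Hz tachogram by cubic
  spline and analysed with Welch's method (120-s Hann segments, 50 %
  overlap). Logarithmic band powers in VLF 0.003–0.04, LF 0.04–0.15 and HF
  0.15–0.4 Hz plus the LF/HF ratio; a power floor of 1e-10 ms² keeps the
  logs finite, and the ratio is missing only when both bands sit at the
  floor. The boundary-adapted variants re-centre the HF band on the detected
  respiratory peak ± 0.1 Hz (clipped to [0.1, 0.5] Hz) and end LF at that
  band's lower edge. The respiratory frequency is the largest HF-band
  spectral peak and its power is integrated over ± 0.015 Hz. An AR(9) model
  (Levinson–Durbin on the biased autocorrelation) supplies the phase and
  modulus of the largest-modulus pole whose angle falls in the HF band;
  both are missing when no pole lands there.
* **Multiscale sample entropy (20).** SampEn(m, r) = −ln(A/B) with Chebyshev
  distance, self-matches excluded and both counts restricted to templates
  that admit an (m+1)-length extension, for m ∈ {1, 2} at scales 1–10
  (non-overlapping coarse-graining means). r = 0.2 × SD of the scale-1
  segment, frozen across scales. Scales with fewer than 30 coarse-grained
  points are missing.
* **Symbolic (1), phase coordination (2), phase synchronization (7).**
  Sign-based regularity measures on RR differences (zero differences count
  as '−' everywhere). Symbolic: SampEn(m = 2, exact matching) of the binary
  increase/decrease string. Coordination: fractions of positions inside
  back-to-back repeats of a sign pattern of length 3–8 (the repeated blocks
  after the first instance count as coordinated); exactly-2 repetitions feed
  the short-range fraction, ≥ 3 the long-range one. Synchronization: n:2
  locking for n ∈ {6..9} detected as any circular shift of ⌈n/2⌉ '+' then
  ⌊n/2⌋ '−'; per-ratio rates, the dominant ratio (ties to smaller n), mean
  synchronized-episode duration, and the fraction of window time in episodes
  ≥ 30 s.
* **Higuchi (1).** Fractal dimension of the z-scored IBI sequence,
  curve-length method with k_max = 10.
* **Teager (21).** ψ(x_i) = x_i² − x_{i−1}x_{i+1} on the z-scored IBIs (a
  constant segment is centred without scaling, so ψ ≡ 0); the mean energy
  plus, for the normalized IBIs and for their first intrinsic mode function
  (in-package EMD: cubic-spline envelopes, Cauchy criterion < 0.3, ≤ 100
  sifts), percentages of transition points (sign changes of the first
  difference of the 3-point moving average) and strict local maxima, and
  mean/SD of the intervals between and amplitudes at each event type.
* **Arousal surrogate (5).** A deliberately simple stand-in probability
  signal (the published arousal model is external to this package): per
  10-s step, the step's mean HR is z-scored against the trailing 120 s
  (SD floored at 0.1 bpm) and squashed through a logistic centred at z = 2
  with slope 0.5; max, mean, median, min and SD over the window are emitted.
  Its summaries behave like a probability signal (a 20-bpm surge saturates
  it; steady HR pins it near 0), which is the downstream contract.
* **Visibility graphs (13).** Natural visibility graph on (t, RR): nodes are
  beats, an edge connects two beats iff every intermediate beat lies
  strictly below the connecting line. From the NVG: degree assortativity,
  mean/SD of local clustering coefficients and degrees, the log–log
  degree-distribution slope, and the percentage of nodes with degree ≤ 3
  and ≥ 10; from the difference visibility graph (NVG of the first
  differences): the five degree-based statistics.

Hot kernels (template counting, visibility scan, DFA boxes, sign-pattern
scans, the IPFM integrator) are numba-compiled; extraction is fully
deterministic — two runs produce bit-identical tables.

## The classifier

Architecture: dense sigmoid layer of 32 units → stack of bidirectional LSTM
layers (default 3, each 64 units per direction, the two directions'
outputs concatenated between layers) → dense sigmoid of 32 → 4-way softmax.
With the defaults the network has exactly 255,812 trainable parameters
(2.6·10⁵ at two significant figures); the per-direction width is the only
reading of "64 cells per layer" consistent with that count, and narrower
readings remain available through `ModelConfig`.

Training minimizes the soft-label categorical cross-entropy
H = −(1/N) Σ_i Σ_c P(Y_i = C_c) · ln P̂(Y_i = C_c), where P is the fraction
of annotators who scored epoch i as class c — the network learns annotator
uncertainty rather than a hardened consensus. Optimizer: RMSprop
(lr 1e-3, ρ 0.9, ε 1e-7, global gradient-norm clip 5; softmax outputs are
clipped to [1e-7, 1−1e-7] inside the loss). Dropout: 20 % on the input
features, 50 % on LSTM outputs, 50 % variational (per-sequence mask) on the
recurrent connections, training only. Whole nights are single sequences,
padded per batch (default 8 nights) with a mask excluded from loss, metrics
and state updates. Missing features are imputed with per-feature training
medians and z-scored with training statistics; both are stored in the
checkpoint.

Everything is implemented in NumPy (forward pass and backpropagation
through time); a finite-difference check of every parameter block is part
of the development history, and training is exactly reproducible from the
seed on a single thread.

Evaluation protocol: participant-level k-fold cross-validation (default
k = 4; participants are shuffled by seed and dealt round-robin, so all
recordings of a participant share a fold). Early stopping (patience 100
passes) is monitored on an inner validation split of 10 % of the training
participants; monitoring the test fold instead — which leaks test
information but mirrors some published protocols — is available via
`TrainConfig(monitor_test_fold=True)`. The "pass" unit is one pass over the
training nights; the best-validation-loss weights are restored.

## Evaluation metrics

Per night: epoch-wise accuracy and Cohen's κ = (p_o − p_e)/(1 − p_e) from
the 4×4 confusion matrix (degenerate marginals: κ = 1 iff observed
agreement is perfect, else 0); per-stage precision, recall, accuracy and κ
from the one-vs-rest 2×2 collapse, missing when the stage is absent from
both sequences. Cohort level: mean ± SD over nights; Pearson correlation
(two-sided t test) of κ and accuracy with age and BMI; two-sided
Mann–Whitney U between sexes and between each clinical group and healthy
controls, computed on participant-level means (nights averaged first);
scipy's exact U distribution is used at small n without ties, otherwise the
tie-corrected normal approximation. An optional ≤ 50 / > 50 years split
compares every per-stage metric across age groups. No multiple-testing
correction is applied.

## Synthetic cohort generator

The generator emulates the statistical structure the classifier relies on,
not cardiac electrophysiology:

* **Hypnogram.** A semi-Markov chain over the 4 stages with gamma dwell
  times and a transition matrix favouring the W → N1N2 → N3 → N1N2 → R
  cycle with sparse awakenings (initial state W). Defaults: mean bouts
  7/9/6/7 min for W/N1N2/N3/R (gamma shape 0.8 for W, 2 otherwise);
  transitions N1N2 → {N3 .35, R .35, W .30}, N3 → {N1N2 .85, W .15},
  R → {N1N2 .70, W .30}. The implied equilibrium gives sleep efficiency
  ≈ 81 % and, of sleep time, ≈ 66 % N1N2, ≈ 16 % N3, ≈ 18 % REM — the
  shape of a mixed clinical cohort. Nights default to 8 h in bed
  (960 epochs).
* **IBI series.** An instantaneous RR(t) signal per night: stage-dependent
  mean RR (850/900/1000/1080 ms for W/R/N1N2/N3), a ~0.1-Hz Mayer-band
  modulation strongest in wake (40/35/25/15 ms) and a 0.25-Hz respiratory
  modulation strongest in deep sleep (10/15/30/45 ms) — heart rate falls
  and respiratory sinus arrhythmia rises with sleep depth — plus white
  noise (35/30/25/20 ms), with stage boundaries smoothed over 15 s. Beat
  times come from integral pulse frequency modulation: a beat fires
  whenever ∫ dt/RR(t) crosses the next integer, so the written intervals
  and beat times are exactly consistent.
* **Annotators.** k independent annotators (default 2) re-label each epoch:
  with probability 1 − error_rate (default 0.15) they keep the true stage,
  otherwise they draw a stage-adjacent confusion (W, N3, R confuse with
  N1N2; N1N2 confuses uniformly with its three neighbours). Fractions per
  epoch form the soft-label matrix.

The cohort is a pure function of (config, seed); regeneration is
byte-identical on disk. What the generator does **not** model: apnea or
arousal events, pathology-specific HRV phenotypes (clinical-group labels
are metadata only, drawn with the frequencies of a mixed sleep-lab cohort),
circadian drift, and annotator correlations. Passing tests therefore show
that the pipeline recovers stage structure whose feature signature is
present by construction — they do not certify performance on clinical
recordings, where class separations are weaker and artifacts more complex.

## Problem sizes and numerical choices

The held-out recovery check trains the reduced model (1 BiLSTM layer, 16
units per direction) on 40 synthetic nights and evaluates mean per-night κ
against the simulator's ground truth on 10 held-out participants' nights;
60 training passes with batch size 8 are ample at this class separation
(validation loss plateaus well before). Predictions are scored against the
true simulated hypnogram rather than the noisy annotator consensus because
the question is recovery of the generative stages.

Degenerate inputs are resolved explicitly rather than left to float
arithmetic: constant segments yield missing entropies/exponents (but zero
Teager energy), zero RR differences count as '−' in all sign-based
features, the spectral log floor is 1e-10 ms², and argmax ties follow the
fixed class order. All stochastic tests fix their seeds.

## Known limitations

* The arousal-probability features are a surrogate of matching shape, not a
  reimplementation of the published arousal model.
* The boundary-adapted spectral bands and the WDFA/PDFA internals follow
  reasonable readings of sources that define them only by citation; the
  exact definitions are documented above and in the registry.
* MSE at high scales on short windows rests on few coarse-grained points;
  values are reported but noisy (the m = 2 entropies at scales ≥ 6 are the
  least reliable, matching the usual 10^m guidance).
* The NumPy LSTM is single-threaded and CPU-bound; it is sized for
  desk-scale experiments, not for hundreds of nights at full width.
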