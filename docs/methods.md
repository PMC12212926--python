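# Methods

`stimscape` implements an end-to-end analysis of how the *temporal shape* of
an optogenetic stimulation waveform determines hippocampal spectral
responses: five waveform classes are generated and characterized, synthetic
stimulation-evoked LFP trials are simulated, per-trial spectral features are
extracted, parameter→bandpower response surfaces are fit with Gaussian
processes, and the multi-band activity induced by each waveform class is
compared to behavioral activity in a 2-D neural latent space.

## Stimulation waveforms

All waveforms are irradiance time series (mW·mm⁻², nonnegative), default
5 s at 2000 Hz (the rate at which all downstream analyses operate).

| class | parameters (bounds) |
|---|---|
| standard | amplitude (10–50 mW·mm⁻²), frequency (5–42 Hz), pulse width (2–10 ms) |
| nested | amplitude, pulse frequency (20–100 Hz), pulse width (2–5 ms), train frequency (2–12 Hz), train width (20–80 ms) |
| poisson | amplitude, center frequency (5–42 Hz), pulse width (2–10 ms) |
| sine | amplitude, frequency (2–50 Hz) |
| double sine | amplitude, two frequencies (2–50 Hz), magnitude ratio (0–1) |

Implementation choices:

- Pulse edges are snapped to the sample grid; a pulse occupies
  `max(1, round(pulse_width·fs))` samples. A standard train over duration
  `T` therefore has `⌊T·f⌋` or `⌈T·f⌉` onsets.
- The nested train is a continuous pulse train at the pulse frequency
  masked by the train-window indicator. A nested parameter set is rejected
  when `⌊train_width·pulse_freq⌋ < 2` (fewer than two pulse periods fit in
  one window, so the waveform degenerates to a standard train) or when
  `train_width ≥ 1/train_freq` (adjacent trains overlap). Rejected draws
  are resampled, as in the experimental protocol.
- Poisson inter-pulse intervals are exponential waiting times with mean
  `1/f` (homogeneous Poisson process), redrawn while below a 1 ms
  refractory floor. The refractory period is a config knob (some published
  descriptions use 2 ms). Redraw-truncation biases the mean interval
  upward by roughly the refractory period; at the default frequencies this
  is below 1 % of the mean.
- Both sinusoids are offset to span `[0, amplitude]`, since irradiance
  cannot be negative; the double sine is the ratio-weighted sum of two
  zero-phase sinusoids rescaled to that range, so ratio = 1 degenerates
  exactly to the single sine.
- `waveform_spectrum` removes the DC offset and averages periodograms over
  independent realizations for the stochastic (poisson) class; 100+
  realizations give a stable broadband average and deterministic classes
  are independent of the realization count.

## Synthetic LFP generator

The generator defines the study conditions for every downstream test; it
emulates the *statistical structure* the analysis assumes, not biophysics.

**Background.** Frequency-domain synthesis: each rFFT bin receives an
independent complex Gaussian amplitude whose expected periodogram equals a
target spectrum `S(f) = noise_sd²·f^(−α) + theta_bump(f)` with α = 1 and a
Gaussian theta bump (center 7 Hz, bandwidth 1.5 Hz, peak density 5 a.u.²/Hz)
whose power is multiplied by 4 during exploration. Units are arbitrary
because every reported metric is a percent change normalized by session
baselines. Because the target spectrum is analytic, expected band powers
are available in closed form and serve as oracles in the tests.

**Stimulation response.** The normalized waveform shape is filtered by a
one-pole low-pass with time constant 10 ms (effective opsin kinetics),
passed through a static nonlinearity `y + 0.5·(y² − E[y²])` whose quadratic
term seeds harmonics (35 Hz drive → 70 Hz peak), and scaled by

- a monotone logistic frequency gain `σ((f_eff − 11)/0.8)` — a roll-off
  knee at 11 Hz below which entrainment is negligible, matching the
  empirical finding that low-frequency stimulation fails to raise theta
  power above baseline;
- an amplitude saturation `A/(A + 20)`;
- a per-subject log-normal gain (σ = 0.2 across 4 subjects).

The effective frequency is the stimulation frequency for standard, poisson
and sine; the pulse frequency for nested; the magnitude-weighted mean of
the two frequencies for the double sine. The overall response gain (12) is
set so that 35 Hz standard stimulation at 50 mW·mm⁻² yields a mean
low-gamma increase of roughly +160 % over baseline — a deliberately strong,
clearly detectable effect; no claim is made that it matches in-vivo effect
magnitudes. The response is deterministic given the waveform, so a
same-seed trial decomposes exactly into background + response.

**Schedule.** Per subject: 600 trials for 2-parameter spaces, 750 for
3-parameter, 1750 for 4/5-parameter (5600 over all five spaces), plus 150
stimulation-free behavior trials per condition, shuffled into sessions
(default 350 trials) that alternate between exploration and quiescence.
Trials are 10 s: 5 s pre-stimulation baseline, 5 s stimulation. A
`trials_scale` factor shrinks the whole schedule uniformly for desk-scale
runs.

**What the generator does not emulate:** spiking activity, phase dynamics
and cross-frequency coupling, state-dependent response nonlinearity,
electrode/channel structure, artifacts, and non-stationarity within a
session. Passing tests therefore demonstrate that the *analysis chain*
behaves correctly under the assumed statistical structure, not that the
chain would produce identical numbers on animal recordings.

## Spectral features

- Multitaper PSD: DPSS tapers on the full 5 s segment, time-bandwidth 3,
  5 tapers (common defaults for this segment length), one-sided density,
  deterministic. Tapers are cached per segment length.
- Bandpower integrates the PSD over half-open intervals `[lo, hi)` by
  bin-sum, which makes adjacent bands exactly additive. Theta is 4–10 Hz,
  low gamma 32–50 Hz; canonical bands delta/theta/beta/low-gamma cover the
  axis for the entrainment analysis ("band nearest the stimulation
  frequency").
- Percent change is `100·(P_stim − B)/B` with `B` the mean pre-stimulation
  bandpower over all trials of the recording session, making the metric
  invariant to rescaling a session's signals.
- The latent-space feature vector is the stimulation-epoch PSD linearly
  interpolated onto a fixed 164-point grid spanning 0–50 Hz, then natural-
  log-transformed with a 1e-12 floor (synthetic silence would otherwise
  produce −∞). No standard FFT length yields exactly 164 bins over
  0–50 Hz at 2000 Hz, so the fixed interpolation grid is imposed as the
  definition.
- The lag autocorrelation at frequency `f` is evaluated at the lag nearest
  `fs/f` samples and normalized as `mean(x_t·x_{t+lag})/mean(x_t²)`, which
  avoids the `(n−lag)/n` shrinkage of the sum-based biased estimator (a
  pure tone then scores ≈ 1 at its own period) and is invariant to
  rescaling.

## Response surfaces

Gaussian-process regression (scikit-learn) with inputs standardized
per-dimension and the kernel signal/noise variances initialized to the
target variance. Two mean functions (constant; affine, implemented as an
ordinary least-squares trend with the GP fit to residuals) cross seven
covariance functions: Matérn (ν = 2.5), periodic (exp-sine-squared),
rational quadratic, squared exponential, Gabor (squared-exponential ×
cosine, implemented as a custom kernel with analytic gradients), linear
(dot product) and polynomial (dot product squared). Kernel configuration
is chosen by 5-fold cross-validated normalized MSE (MSE / target variance)
averaged across subjects' datasets.

Outlier handling is a single removal pass: points whose **leave-one-out**
residual exceeds three residual standard deviations are excluded and the
model refit. LOO residuals (closed form from the Cholesky factor) are used
because the marginal-likelihood optimum can shrink its length scale enough
to interpolate gross outliers, making in-sample residuals blind to them;
the LOO residual is the point's deviation from the GP fit to the remaining
points, which is the operative notion of "distance from the mean GP".
Coincident outliers can still mask each other — inherent to any
single-pass 3-SD rule.

The entrainment analysis groups trials by discrete grid frequency
(5, 7, 11, 17, 23, 29, 35, 42 Hz), computes each trial's percent change in
the canonical band containing (or nearest to) that frequency, and applies
a one-sided Wilcoxon signed-rank test of median > 0. Cells with fewer than
5 trials are skipped with a warning.

## Neural latent space

Order of operations: embed per subject → drop latent-space outliers
(points whose mean pairwise Euclidean distance in the raw embedding
exceeds the mean + 3 SD over all points) → drop stimulation trials with
amplitude < 30 mW·mm⁻² (strict inequality; behavior trials always kept) →
min-max normalize each axis to [−1, 1] (idempotent; degenerate axes map
to 0).

Embedding adapters: UMAP (umap-learn, the featured method), t-SNE and PCA
(scikit-learn); all seeded and deterministic under a fixed seed. The
algorithms themselves are used as-is, never reimplemented.

Boundary masks: density on a fixed 200 × 200 node-centered grid spanning
[−1.1, 1.1] per axis, as the **average of unit-mass symmetric 2-D Gaussian
kernels** with σ = 0.05 — i.e. a true probability density, the natural
reading of "probability proportional to point density". A node belongs to
a region when its density strictly exceeds 0.01 (a point exactly on the
level set is excluded). Both σ and the threshold are configurable; the
ranking results are robust to kernel width, the absolute areas are not.
`scipy.stats.gaussian_kde` is deliberately not used: its data-driven
bandwidth contradicts the fixed-σ kernel that defines the metric.

Normalized area divides a group's node count by the total-boundary count
(all retained points pooled, same σ/threshold); the grid fraction
(count / 40 000) is also reported, as representative occupancies are
usually quoted that way. Because a subset's KDE tails can poke past the
pooled boundary, a group's normalized area may slightly exceed 1 (bounded
in practice by ~1.1). DICE(X,Y) = 2|X∩Y|/(|X|+|Y|) counted in grid nodes;
two empty masks give 0 by convention.

Neighbor inspection returns the k = 50 Euclidean-nearest trials to a query
coordinate with their waveform-class histogram and mean log-PSD.

## Inference

- Kruskal–Wallis H with tie correction (scipy); fully tied data returns
  H = 0, p = 1.
- Sign test: exact binomial, zeros dropped, `p = min(1, 2·min(tails))`.
- Bootstrapped hierarchical Friedman: for each of 5 replicates, every
  subject × group trial set is resampled with replacement at its original
  size and the group metric recomputed (for latent metrics this means
  re-deriving the KDE boundary from the resampled embedded points — the
  embedding itself is *not* recomputed, and the subject's total-boundary
  count is held fixed as the reference); each subject × replicate is one
  block of a Friedman rank test across groups, so 4 subjects × 5
  replicates = 20 blocks and df = groups − 1 = 5 for six groups. This
  block construction is the only reading consistent with the reported
  degrees of freedom. The subject-level-only Friedman (no resampling, one
  block per subject) is reported alongside as the underpowered secondary
  test.
- Caveat, verified by the test suite: because the replicate blocks are
  resamples of the *same* subjects, they are not independent, and the
  procedure rejects well above the nominal rate under exchangeable data.
  It should be read as an effect-consistency score across subjects and
  resamples, not as a calibrated p-value; the subject-level Friedman is
  the conservative companion.
- Degenerate fully-tied Friedman inputs return statistic 0, p = 1. Fewer
  than three groups is an error (the two-group case collapses to a sign
  test).

## Problem sizes

The default test and acceptance runs use desk-scale sizes chosen as
adequate for each statistical check: 40 trials per grid frequency ×
20 seeded experiments for the entrainment calibration, 200 trials for GP
argmax recovery, 200–300 realizations for the averaged Poisson spectrum,
10 seeded runs for the latent-space ranking check, and a uniformly scaled
trial schedule (`trials_scale` = 0.03–0.1) for pipeline runs. The full
5600-trials-per-subject schedule is available by leaving the scale at 1.

## Known limitations

- The 164-point grid is a definition, not a derivation; other
  interpolation grids change feature values but not downstream rankings.
- GP fits use exact inference; parameter tables much beyond ~2000 points
  per subject would need sparse approximations (out of scope).
- The bootstrapped Friedman anticonservatism described above.
- The latent-space outlier rule is O(n²) in embedded points.
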