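# Methods

## The model

`tensortrf` fits linear finite-impulse-response (FIR) encoding models that
predict a multichannel neural time series from a sparse stream of word
events, each carrying a numeric embedding.  For a story sampled at rate
`f` (default 50 Hz) with `T` samples and `C` channels, the stimulus is the
series `X ∈ R^{T×N}` that is zero except at word-onset samples, where it
holds the word's embedding (dimension `N`).  The prediction is

    M̂[t, c] = Σ_{d=0}^{D-1} Σ_n  F[d, n, c] · X[t-d, n]

with a filter tensor `F ∈ R^{D×N×C}` over `D` post-onset delays.  Forty
delays at 50 Hz cover 800 ms after word onset, where most language-driven
signal is expected.

Two parameterizations of `F` are provided:

* **Full rank** (`FullRankRidge`): every entry free, fit per channel by
  ridge regression on the lagged dense design, with the penalty chosen per
  channel by sequential 6-fold cross-validation over a logarithmic grid
  spanning [1e-3, 1e4].  Folds are contiguous equal-length time blocks
  within each story, so temporally correlated samples do not straddle the
  train/validation boundary.  The solver reuses a single SVD across the
  penalty grid; the fit is closed form and exactly reproducible.
* **Low rank** (`CPTensorRegression`): `F` is a rank-R canonical polyadic
  (CP) sum, `F[d,n,c] = Σ_r α_r U_D[r,d] U_E[r,n] U_C[r,c]`, with unit-norm
  factor rows and all scale in `α_r ≥ 0`.  The CP form is identifiable only
  up to component permutation and paired sign flips; every recovery
  comparison therefore goes through the greedy channel-correlation matcher
  (`match_components`).

## Fitting the CP model

The loss is mean squared error plus a ridge penalty on the **expanded**
tensor entries,

    L = (1/(I·T·C)) Σ (M̂ - M)² + (λ/(C·D·N)) Σ_{d,n,c} F[d,n,c]²,

computed in factorized form via the Gram matrices of the factor rows (cost
`O(R²(D+N+C))`, never materializing `F`).  A configuration switch
(`penalize_factors`) penalizes factor entries instead; the expanded form is
the default.  Optimization uses Adam (implemented in numpy) on full- or
mini-batch gradients with analytically derived factor gradients.  Defaults:
learning rate 5e-3, batch size 300,000 contiguous time samples (full batch
for the problem sizes used here), uniform λ = 0.1, i.i.d. Gaussian
initialization with sd 0.1.  Factors are unconstrained during fitting;
normalization is pulled out afterwards, exactly preserving the expansion.

Stopping: relative epoch-loss change below 1e-5 for 5 consecutive epochs,
capped at 1000 epochs.  A minimum of 150 epochs is enforced because the
multiplicative parameterization sits on a near-flat plateau around the
small random initialization; the relative-change rule would otherwise fire
before the loss starts to move.  Mini-batches are contiguous time blocks
(shuffled across stories each epoch) because the convolution couples
adjacent samples.  Divergence (non-finite loss) raises an error naming the
epoch.

## Evaluation

Performance is measured on a held-out story recorded multiple times.  The
noise ceiling per channel uses the signal-power estimator

    SP    = (Var_t(Σ_i y_i) − Σ_i Var_t(y_i)) / (n(n−1)),
    CCmax = sqrt(SP / Var_t(ȳ)),

and model skill is `CCnorm = Corr(ȳ, M̂) / CCmax`.  Ceilings that are
non-finite or below 0.2 clamp to 0.2 (flagged per channel), so near-zero
signal channels cannot inflate CCnorm.  With an unbiased ceiling estimate,
CCnorm of the generating filter can slightly exceed 1; tests allow
[0.9, 1.1] at high SNR.

Post-onset predictability uses 100 ms windows spanning 0–800 ms after word
onset (5-sample windows at 50 Hz): samples whose lag to some word onset
falls in window k are concatenated, the ceiling of that subsampled series
is computed, and the whole-series ceiling subtracted ("excess" ceiling).
When words are closer than 800 ms a sample may belong to several windows;
the alternative of attributing it only to the nearest preceding word is a
config option (`assignment="nearest"`).  PCA of the windows × channels
excess matrix (channels as observations) summarizes latency structure.

Significance: model-vs-model comparison resamples channels with
replacement (bootstrap; ties counted half, so identical inputs give
p = 0.5); model-vs-chance builds a null by circularly shifting the
prediction in time by offsets of at least one block length (default 50
samples = 1 s), preserving autocorrelation, with
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`.

## Interpretation

For a normalized filter, component weight timecourses
`W[r,t] = α_r Σ_{n,d} U_D[r,d] U_E[r,n] X[t−d,n]` satisfy
`M̂ = Wᵀ U_C` exactly.  Leave-one-out influence is the drop in mean CCnorm
when a component's scale is zeroed; components are reported sorted by
influence.  Most-activating contexts rank corpus snippets by the raw dot
product between their embeddings and `U_E[r]` (cosine available as an
option); ties break by corpus order.  Mode power is
`Q_D[d] = Σ_r α_r² U_D[r,d]²` (analogously over channels), reported
normalized by its Euclidean norm (sum-to-one as an option).

## Controls and residualization

Low-level covariates — an 80-band log-mel spectrogram (16 kHz analysis
rate, 25 ms hop, HTK-scale triangular filterbank, log floor at 1e-10 of
peak power, frames linearly interpolated onto the recording grid, 15 lags)
and binary word-onset / sentence-start / sentence-end series (unlagged by
default; a config lags them too) — are regressed out by a ridge-less OLS
fit over train and test jointly, which is the default protocol here for
fidelity to common practice with these controls even though joint fitting
leaks test data by conventional standards; a strict train-only mode is
provided (`fit_rows`).  An intercept column is appended so the projection
commutes with the per-channel re-z-scoring applied to the residuals,
making residualization idempotent.  With multiple stories the per-story
re-scaling makes idempotence hold only to high approximation (second-pass
corrections scale with between-story differences in residual scale, well
below 1% here); with a single story, or without re-normalization, it is
exact.

## Synthetic data

The generator emulates the study conditions: geometric (memoryless)
inter-word gaps with mean 20 samples (a word every 400 ms at 50 Hz),
sentence lengths uniform on [4, 15] words with start/end flags, zero-mean
Gaussian embeddings with a diagonal covariance whose eigenvalues decay
geometrically (ratio 0.85, unit mean variance) to mimic the effectively
low-dimensional embeddings of language models, ground-truth CP filters
with smooth Gaussian-bump delay profiles and random unit embedding/channel
directions with well-separated scales (default `R..1`), white Gaussian
channel noise, and repeat presentations sharing one deterministic signal.
Everything is bit-reproducible from the config seed; each (purpose, story,
repeat) gets an independent substream.

It does **not** emulate: temporally correlated or spatially structured
sensor noise, realistic sensor geometry/lead fields, prosodic timing, or
audio waveforms.  Tests passing on this generator show the estimation and
evaluation machinery is correct under the model's own assumptions; they do
not show the model is well specified for real recordings.

## Numerical and design choices

* Sample indices are 0-based; delay 0 means "at word onset"; story starts
  are zero-padded (no cross-story leakage, asserted by construction).
* Words sharing a sample merge into one event with summed embeddings
  (forced by linearity).
* Embedding PCA is rotation-only (no whitening), mean computed on training
  stories; the reduced dimension is the smallest K whose cumulative
  explained variance reaches the threshold (default 0.95).
* Ridge penalties enter the normal equations as `(XᵀX + λI)`; no intercept
  is fit for the encoding models since recordings are z-scored and the
  event design is effectively centered.
* Mean CCnorm averages over all channels by default; a report method
  restricts to unclamped channels.
* Zero-variance predictions define correlation 0 rather than NaN; removing
  the only component of a rank-1 model therefore has influence equal to
  the full model's mean CCnorm.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen to make
every statistical check tight while keeping a single-CPU run fast: up to
3 stories × 30,000 samples × 20 channels for recovery, 10,000-sample
training stories for the rank sweep, 20,000 samples for ceiling
calibration, 50-replicate detection and 200-dataset calibration loops for
the frequentist checks.

## Known limitations

* The CP fit is non-convex; recovery is demonstrated at well-separated
  component scales and moderate noise, not guaranteed globally.
* The noise ceiling estimator assumes exchangeable repeats with
  independent noise; slow drift across repeats would bias it.
* Full-rank ridge stores the dense lagged design in memory
  (`T × D·N` doubles), which bounds practical problem sizes.
* The log-mel front end is a standard analysis chain, not a reimplementation
  of any specific audio toolkit; band edges may differ slightly from other
  implementations (Slaney-style filterbanks) in the lowest bands.
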