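# Methods

`smoothpls` decodes continuous 3-D trajectories from multichannel neural
recordings with multi-way partial least squares (N-way PLS) and two
smoothness-penalised variants, against a Kalman-filter baseline. This note
records the models, the numerical choices, and what the synthetic studies do
and do not demonstrate.

## Feature extraction

A recording sampled at `fs` (default 1000 Hz) is cut into epochs of length
Δτ = 1 s ending at times `t_i = Δτ + i·Δt`, Δt = 0.1 s. Each epoch is mapped
by a continuous wavelet transform with a complex Morlet mother wavelet

    psi(t) = (pi B)^(-1/2) exp(-t^2/B) exp(2 pi i C t),

analysed at 15 frequencies 10–150 Hz (step 10 Hz) with scale `a = C fs / f`.
The log-modulus `log(max(|coef|, eps))` is taken (`eps = 1e-12` makes the
all-zero epoch well defined), and the temporal axis is block-averaged into 10
bins of 100 ms, yielding one frequency × lag × channel cube per epoch. The
trajectory row paired with an epoch is the sample nearest in time to the
epoch's *end* — features are causal.

Defaults `B = 2, C = 1` make adjacent 10 Hz bins resolvable over a 1 s epoch
(frequency std ≈ f/(πC√(2B)) ≈ 0.16·f) while keeping the kernel support well
inside the epoch at 10 Hz. Epoch edges are zero-padded; the decimation step
averages the edge effects into the first and last lag bins. An
artifact-filtration hook (`recording -> recording`) can be plugged into the
config; the default is the identity.

## N-way PLS

For a centered tensor of observations `X` (N × d1 × d2 × d3) and centered
responses `Y` (N × m), each factor f carries unit-norm mode projectors
`w1_f, w2_f, w3_f`, a score `t_f = <X_res, w1 o w2 o w3>`, a unit response
loading `q_f` and inner coefficients `b_f` with `u_f = T_f b_f`:

    X = sum_f t_f o w1_f o w2_f o w3_f + E,
    Y = sum_f (T_f b_f) q_f' + F_resid.

Numerical conventions (all needed for reproducibility):

* `u` is initialised from the dominant left singular vector of the current
  Y residual, removing any dependence on response column order.
* The per-factor weight tensor is the dominant rank-one approximation of the
  contraction `Z = <X_res, u>`, computed by higher-order power iteration
  (tolerance 1e-10, ≤ 500 iterations) initialised from the dominant singular
  vectors of the mode unfoldings.
* The inner loop iterates to relative score change ≤ 1e-8 (≤ 500 iterations).
* X is deflated by the rank-one component `t o w1 o w2 o w3`, Y by its
  running prediction. This keeps the decomposition form above exact, at the
  price that scores are *not* mutually orthogonal (orthogonality would
  require loading-based deflation); the inner regression `u_f = T_f b_f`
  handles the resulting obliqueness.
* Every projector's (and loading's) first non-negligible entry is made
  positive; scores absorb the flips.
* No variance scaling anywhere — required for the exact λ = 0 reduction of
  the penalised fits.

The coefficient tensor `B` (d1 × d2 × d3 × m) is materialised through the
effective-weight recursion `r_f = w_f − Σ_{g<f} (w_g·w_f) r_g`, which
reproduces the sequential score pipeline exactly as a single linear map;
prediction is `<B, x - x̄> + ȳ`.

Generic matrix PLS is the same algorithm with the three feature modes
unfolded into one (singleton modes 2 and 3); an independent matrix-PLS
implementation in the test suite guards the equivalence at 1e-8.

Degenerate factors (exhausted residual) truncate the model with a warning
rather than failing. F = 0 yields the mean predictor.

## Smoothness penalties (SNPLS, PNPLS)

Both penalties act on the *prediction stream*, not on the coefficients, and
both are implemented by data augmentation: stack a scaled penalty block under
the centered data with zero responses and fit plain N-way PLS to the pair —
centering first, so the zero response block stays exactly zero and λ = 0
reduces to the unpenalised fit to machine precision.

* **Sobolev (SNPLS)**: the block is the s-th backward finite difference of
  the feature stream along epochs (default s = 3, no Δt scaling — λ absorbs
  it), with N − s rows; the first s undefined rows are dropped. This
  penalises the s-th derivative of the predicted trajectory, i.e. a
  Sobolev-norm objective.
* **Polynomial (PNPLS)**: the block is the residual of a sliding
  Savitzky–Golay smoother (degree p = 2, window L = 2l+1 = 9), on the N − 2l
  valid window centres. Feature streams that are exactly degree-p
  polynomials of the epoch index incur zero penalty.

In the augmented least-squares limit the fits equal a generalised ridge
`B = (X'X + λ² D'D)^(-1) X'Y` with `D` the difference (or smoother-residual)
operator; the test suite verifies the high-factor SNPLS fit converges to
that closed form. Penalty rows are appended after the data rows in epoch
order. λ is selected by cross-validation (grid {0, 10⁻², 10⁻¹, 1, 10, 10²}
by default, configurable).

## Kalman-filter baseline

State `y_k` = positions + causal first-difference velocities and
accelerations (m = 9); observation `x_k` = the unfolded feature vector.
System identification is least squares on the centered streams:

    A = Y2 Y1'(Y1 Y1')^-1,  H = X Y'(Y Y')^-1,
    W = (Y2 - A Y1)(Y2 - A Y1)'/(N-1),  Q = (X - H Y)(X - H Y)'/N.

Only the m × m state moments are inverted during identification, so the fit
is defined for n ≫ N; the rank-deficient `Q` that then arises surfaces at
filter time, where an optional innovation jitter `δI` (default δ = 0)
restores invertibility — the filter is known to be ill-suited to
high-dimensional features, and the jitter makes that regime runnable rather
than hiding it. Initialisation: ŷ0 = 0 (centered), P0 = W. Filtering is the
standard predict/update recursion; covariances are symmetrised each step. A
steady-state mode first converges the gain (for wide observation matrices
via the information-form identity `K = (P⁻¹+H'Q⁻¹H)^(-1) H'Q⁻¹`, one n × n
factorisation total) and then applies the fixed gain, making the per-step
cost O(nm).

## Evaluation

Per coordinate, then averaged with equal weights:

    r    = Pearson correlation
    RMSE = ||y − ŷ||₂ / ||y − ȳ||₂          (mean predictor scores 1)
    MAE  = ||y − ŷ||₁ / ||y − ȳ||₁
    MADE = ||y′ − ŷ′||₁ / ||y′ − ȳ′||₁      (y′ = first differences)

MADE measures accuracy *and* smoothness; the derivative is the unscaled
first difference (Δt cancels). The prediction delay is the minimal shift
k·Δt in [0, 2] s maximising the correlation between the observed signal and
the advanced prediction (ties go to the smaller shift). Modality influence
normalises the sums of |B| over all-but-one axis to weight vectors per
modality (frequency, temporal lag, channel). A thin one-way-ANOVA helper
compares per-recording criterion samples at α = 0.05.

## Synthetic data

`gen_trajectory` draws Gaussian noise low-pass filtered below a cutoff
(Chebyshev-II, stopband at the cutoff, so < 1% of spectral power leaks
above it), standardized per coordinate — slow reach-like movements relative
to the 10 Hz epoch rate. `gen_feature_tensor` plants R rank-one factors
whose scores are fixed linear combinations of the coordinates, plus AR(1)
epoch-level noise scaled to a target SNR; the per-mode projectors are
orthonormal across factors, the condition under which sequential
dominant-component extraction identifies the planted factors exactly.
`gen_raw_recording` produces carrier sinusoids amplitude-modulated by the
coordinates over 1/f background noise for end-to-end tests of the feature
stage.

Not emulated: non-stationarity, cross-channel correlation, movement
artifacts, realistic spectra beyond 1/f. Passing tests therefore show the
algorithms behave as specified on data satisfying their assumptions, not
that any particular accuracy will transfer to real recordings.

### The noisy-smooth family

The penalty-vs-baseline comparisons run on a fixed family: N = 2000 epochs
at Δt = 0.1 s, 15 × 10 × 24 tensors (3600 features against 1400 training
epochs — deliberately over-parameterised, the regime where penalisation has
work to do), R = 3 factors, trajectory cutoff 0.5 Hz, SNR 0.02, noise AR
coefficient 0.3. With features ≪ training epochs the PLS estimate averages
the noise nearly optimally and *any* smoothing strictly hurts (its
augmented-OLS limit over-shrinks); the chosen scale reproduces the
qualitative regime of 64-channel decoding, where coefficient estimation
noise makes predictions rough.

Study protocol, per replicate: chronological 70/30 split; F fixed at the
true 3; penalty strength chosen by 2-fold blocked CV over {0, 0.3, 1, 3},
minimising CV MADE among strengths whose CV correlation is ≥ 95% of the
unpenalised fit — smoothing with minimal accuracy loss, which is exactly
what the penalties are for (RMSE-based selection is used in the generic
pipeline; it is indifferent to smoothness and would defeat the comparison).
The Kalman baseline runs in steady-state mode with relative innovation
jitter 1e-3·tr(Q)/n. Twenty replicates, all seeds derived from one study
seed. The problem sizes (fold count, replicate count, λ grid) were chosen
to keep a full study in the minutes range on one core.

## Pipeline

Chronological 70/30 split (time series — no shuffling); hyper-parameter
selection by k-fold CV with *contiguous* time blocks (default 10 folds;
seeded shuffled folds behind a flag), minimising mean held-out RMSE, ties
toward smaller F then smaller λ; final fit on the full training part;
evaluation (criteria, delay, influence) on the held-out part. Reports are
deterministic given config + seed. Models serialize to single HDF5 files
with a versioned schema.

## Known limitations

* The response is a matrix (3 or 9 columns); tensor-valued responses and
  predictor orders ≠ 4 are out of scope.
* Scores are non-orthogonal by construction (see deflation above).
* The Kalman baseline is the plain filter: no square-root form, smoothing,
  or time-varying system matrices.
* CV is sequential; no parallel execution.
* The polynomial smoother uses only interior (full-window) rows for the
  penalty; the s first rows are dropped from the derivative penalty.
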