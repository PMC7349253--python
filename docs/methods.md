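# Methods

This note documents the models and procedures implemented in `mveeg`, the
parameters that matter, the numerical choices behind them, and what the
synthetic data does and does not establish.

## Synthetic ERD/ERS trial sets

`generate_trialset` emulates the statistical signature that motor imagery
leaves in EEG, not the biophysics. Background activity is 1/f-shaped
Gaussian noise band-limited to 0.5–100 Hz (the usual acquisition band) and
normalised to unit variance per channel. Class k (k = 1..4) adds a coherent
sinusoid with random frequency inside its own analysis sub-band (8–12,
12–16, 16–20, 20–24 Hz respectively) and random phase per trial, on four
contiguous channels assigned to that class. The amplitude is set per trial
so that the burst's power equals `snr` times the measured background power
in that sub-band on those channels; `snr = 0` removes all class structure.
Trials are 3 s at 250 Hz with 22 channels by default, matching a typical
cue-paced imagery window; one synthetic "subject" has 72 trials per class
unless configured otherwise.

What this emulates: class-dependent band-power modulation with a stable
spatial pattern, recoverable by a filter bank and by CSP. What it does not:
volume conduction from dipolar sources, EOG/EMG artifacts, non-stationarity
across a session, inter-subject variability, or ERD proper (power
*decrease*); the signatures here are synchronisation-style power increases.
Passing tests on this data therefore demonstrate the pipeline's mechanics
and its sensitivity/robustness at controlled SNR — not expected accuracy on
real recordings.

## Preprocessing and views

Published EEG cleaning pipelines for this task are toolbox-specific and
under-documented; here preprocessing is deliberately minimal and stated:
per-channel mean removal per trial, plus an optional zero-phase 0.5–100 Hz
Butterworth band-pass (4th order, forward–backward). The filter-bank view
uses the same filter design on the five sub-bands tiling 8–30 Hz. All
band edges are configurable.

The time–frequency view uses a full wavelet-packet tree of depth 4
(Daubechies family; `db4` by default — the family is standard for EEG, the
order is a free choice). Analysis uses zero-extension boundaries, which
keeps the transform energy-preserving and perfectly reconstructible at any
trial length (periodized boundaries would require dyadic lengths). Leaves
are ordered by natural frequency; leaf k nominally spans
[k, k+1]·fs/2^(levels+1), and the leaves whose span intersects 8–30 Hz are
reconstructed back to time-domain signal sets (3 leaves at fs = 250,
levels = 4). Feeding CSP with reconstructed leaf *signals*, rather than raw
coefficients, lets the identical spatial-filtering step serve all three
views.

## CSP

For a dichotomy (A, B), per-trial spatial covariances are normalised by
their trace, averaged within class, and ridged by 1e-10 · trace for
conditioning. The filters solve the generalized eigenproblem
Σ_A w = λ (Σ_A + Σ_B) w; eigenvectors are scaled so W (Σ_A + Σ_B) Wᵀ = I,
which makes each component's eigenvalue pair sum to 1 and both projected
covariances exactly diagonal. The returned W keeps the N most
A-discriminative and N most B-discriminative rows (N = 2 by default; N is
a free parameter of the method). Multi-class banks combine one-versus-rest
(4 filters) and the three balanced two-versus-two splits, 7 filters for
four classes.

Features are f_j = log Σ_t Z_j(t)² exactly — no normalisation by total
variance (a normalised variant is available via `apply_csp`'s caller if
needed; the scaling law f(cX) = f(X) + 2 log c is part of the test
contract). A component with exactly zero power is floored at machine
epsilon with a warning by default (`zero_power="error"` raises instead).

With defaults the views contribute 28 (F1′), 140 (F2′) and 84 (F3′)
features; per-trial, per-view-block 2-norm normalisation precedes
concatenation (252 features total). Normalising per trial rather than per
matrix keeps trials comparable to one another, which the classifier
requires. CSP banks are always fitted on training trials only.

## RBM pretraining

The stack is X–500–500–2500–d; the first three hidden layers are Bernoulli
with sigmoid means, the top layer is linear-Gaussian so the latent code is
real-valued. Inputs are min-max scaled to [0, 1] per feature using
training-set ranges and treated as real-valued visible probabilities.
Training is CD-1: hidden units are sampled in the data phase (Gaussian
noise of unit variance for the linear layer), reconstructions use sigmoid
means, and the negative statistics use the reconstruction's hidden means.
Updates carry momentum on a persistent velocity and an L2 weight-cost on W.

Per-layer schedules: sigmoid layers — learning rate 0.007, weight-cost
0.005, 70 epochs, momentum 0.5 for the first ten epochs then 0.7; linear
layer — 0.0002, 0.003, 80 epochs, momentum 0.6 then 0.8. Mini-batches of
100; weights initialised N(0, 0.01²), biases zero. The "weight" constant is
interpreted as the L2 weight-cost; an alternative reading as the initial
weight scale is available through `weight_meaning="init_scale"` since the
phrasing is ambiguous in the source material for this family of schedules.

## Parametric t-SNE fine-tuning

Per fixed batch of 100 trials (one seeded shuffle, trailing partial batch
dropped), Gaussian conditionals are calibrated per point by bisection on
log σ over [1e-20, 1e20] (50 steps, tolerance 1e-5 on 2^H) to perplexity
25, then symmetrised: p_ij = (p_{j|i} + p_{i|j}) / 2B. Latent similarities
use the Student-t kernel (1 + ‖y_i − y_j‖²/α)^{−(α+1)/2} with α = 32 and
latent dimension d = 60 by default (both exposed; the traversal sweep
covers d ∈ {5..70 step 5} × α ∈ {4..48 step 4}, a 14 × 12 lattice).

The cost is C = KL(P‖Q). Its exact latent gradient is

    dC/dy_i = ((2α+2)/α) Σ_j (p_ij − q_ij)(y_i − y_j)(1 + ‖y_i − y_j‖²/α)^{−1};

note the last factor's exponent is −1, the derivative of the kernel — not
the kernel itself. At α = 1 this reduces to the familiar t-SNE gradient
4 Σ (p−q)(y_i−y_j)/(1+d²). The implementation uses the exact form; it is
verified against central finite differences to < 1e-5 relative error.
Gradients are backpropagated through the sigmoid/linear stack and
minimised by conjugate gradients (Polak–Ribière with strong-Wolfe line
search via `scipy.optimize.minimize(method="CG")`), 3 CG steps per batch
per epoch, 50 epochs by default ("iterations" is read as epochs over all
batches). Batches are fixed after the initial shuffle so the per-batch KL
trace is monotone-comparable; P is calibrated once per batch since it
depends only on the inputs. p_ii = q_ii = 0, and probabilities are floored
at 1e-12 inside logs and ratios.

## Classification and evaluation

An RBF-kernel SVM (C = 1, gamma = 1/(n_features · var), one-vs-one) on the
latent codes; kernel and hyperparameters are configurable since nothing
deeper is specified by the method. Accuracy is 100 · Σ n_ii / N. Kappa is
(p_o − p_e)/(1 − p_e) with two p_e variants: the standard Cohen form
Σ row_i · col_i / n² (default, and the form comparison tables in this
literature use), and a diagonal variant Σ row_i · diag_i / n² in which the
per-class predicted count is the number predicted *correctly*; the two
differ (e.g. 0 vs 0.2 on an all-one-class degenerate balanced matrix), so
both are reported.

Cross-validation is stratified k-fold (k = 10 by default) after a seeded
shuffle. The default mode is leakage-safe: CSP banks, feature scaling, RBM
pretraining, fine-tuning and the SVM are all refitted per training fold;
band-pass and wavelet transforms are per-trial and label-free, so they are
computed once. A `pooled` mode fits the feature learning once on all
trials before cross-validating only the classifier, mirroring evaluation
protocols that pool and re-split train/test data; reports are labelled
with the mode.

## Problem sizes used in tests and the acceptance script

The bundled end-to-end runs use the pipeline at reduced width so the whole
study executes on a single CPU in minutes: an X–64–64–256–10 network, 10 CD
epochs per layer and 10 fine-tuning epochs, on 60 trials per class with
5-fold cross-validation; the fine-tuning-progress check uses 50 epochs.
These sizes are the package's chosen desk-scale study conditions; the
full-size defaults (500/500/2500, d = 60, 70/80/50 epochs, 10-fold) remain
the configuration defaults.

## Known limitations

* The synthetic generator's simplifications (above) mean synthetic accuracy
  says nothing quantitative about accuracy on real recordings.
* GDF/EDF epoch extraction is a thin wrapper over `mne` annotations with a
  configurable cue-relative window (default 0.5–3.5 s); event-code mapping
  across vendors is not normalised beyond sorting.
* CD-1 is a biased estimator of the RBM gradient; no persistent CD is
  provided.
* Fine-tuning drops a trailing partial batch; with fewer trials than one
  batch, fine-tuning refuses to run (reduce `batch_size`/`perplexity`).
* The two-versus-two CSP strategy is defined only for exactly four classes.
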