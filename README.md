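# mveeg — deep multi-view feature learning for motor-imagery EEG

`mveeg` implements a complete recognition pipeline for four-class
motor-imagery EEG (left hand / right hand / feet / tongue): it is aimed at
brain-computer-interface researchers who want a transparent, fully scripted
reference implementation of multi-view CSP feature learning with a deep
embedding, runnable end to end on synthetic data or on their own recordings.

## The method

Motor imagery modulates the sensorimotor mu and beta rhythms (8–30 Hz)
through event-related desynchronization/synchronization (ERD/ERS). The
pipeline captures this with three complementary views of each trial
X ∈ ℝ^{channels × samples}:

* **F1 (time domain)** — the preprocessed signal itself;
* **F2 (frequency domain)** — a five-band filter bank tiling 8–30 Hz
  (8–12, 12–16, 16–20, 20–24, 24–30 Hz);
* **F3 (time–frequency domain)** — depth-4 Daubechies wavelet-packet
  sub-band signals whose nominal spans intersect 8–30 Hz.

Each view is spatially filtered by multi-class **common spatial patterns**
(one-versus-rest plus two-versus-two dichotomies). For a filter W the
per-trial features are

    Z = W X,   f_j = log Σ_t Z_j(t)²,

and the three view blocks are 2-norm normalised per trial and concatenated
into the multi-view feature F = [F1′/‖F1′‖, F2′/‖F2′‖, F3′/‖F3′‖].

F then enters a stacked-RBM feedforward network (X–500–500–2500–d; sigmoid
hidden layers, linear top layer) pretrained layer-wise by CD-1 contrastive
divergence, and fine-tuned by **parametric t-SNE**: per batch, Gaussian
joint probabilities p_ij (bandwidths calibrated to perplexity 25) are
matched to latent Student-t joint probabilities

    q_ij = (1 + ‖y_i − y_j‖²/α)^{−(α+1)/2} / Z,   α = 32, d = 60,

by conjugate-gradient minimisation of KL(P‖Q) backpropagated through the
network. An RBF-kernel SVM classifies the latent codes; results are
reported as accuracy and kappa = (p_o − p_e)/(1 − p_e) under stratified
10-fold cross-validation, with a traversal sweep over d (5–70, step 5) and
α (4–48, step 4) available for parameter selection.

A bundled generator produces labelled synthetic trial sets with
class-specific ERD/ERS-style band-power structure (22 channels, 250 Hz),
so the whole pipeline is testable without external recordings; GDF/EDF
recordings can be read through `mne` (optional extra `raw`).

## Worked example

```python
import mveeg

trials = mveeg.generate_trialset(mveeg.SimConfig(n_trials_per_class=60, snr=5.0, seed=1))
cfg = mveeg.PipelineConfig().scaled_down()   # X-64-64-256-10, 10 CD + 10 fine-tune epochs
report = mveeg.cross_validate(trials, cfg, k=5, seed=2)
print(f"accuracy = {report.accuracy:.2f}%  kappa = {report.kappa_standard:.3f}")
print(report.confusion.counts)
```

prints

```
accuracy = 96.67%  kappa = 0.956
[[57  0  0  3]
 [ 0 59  1  0]
 [ 0  0 59  1]
 [ 0  0  3 57]]
```

i.e. on a 240-trial synthetic set whose four classes modulate distinct
mu/beta sub-bands at 5× background power, the scaled-down pipeline
recovers the class structure almost perfectly (chance is 25%, kappa 0);
the pooled confusion matrix shows the few residual mix-ups between
spectrally adjacent classes. At `snr=0` the same pipeline scores ~25%
accuracy and kappa ~0, as it should.

The same stages are available from the shell:

```bash
mveeg run-all --config demo.yaml      # simulate → features → pretrain → finetune → evaluate
mveeg sweep --config demo.yaml        # d × alpha traversal search
```

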