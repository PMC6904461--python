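# Methods

## The estimation problem

`collidernet` studies prognosis prediction from medical images when one
of the image's factors of variation is a *collider*. The simulated
world has two latent patient variables — tumour aggressiveness `u1` and
patient fitness `u2` — that jointly cause nodule size `x` (the
collider), while fitness alone drives treatment allocation `t` and a
third independent factor, radiodensity heterogeneity `z`, carries
prognostic information. Survival is

    y = t − z − 2·u1 − 0.5 + ε,   ε ~ N(0, 0.05),

so the true average treatment effect (ATE) is exactly 1. Marginally,
`t` and the outcome share no open backdoor path: a regression of `y` on
`t` alone is unbiased. Conditioning on `x` (or on an image that shows
it) opens the path `t ← u2 → x ← u1 → y` and biases the estimated
treatment effect downward. A network free to use the whole image
("BiasedNet") will condition on size because size predicts survival in
the observed data; the constrained model ("CausalNet") must use the
image's prognostic content while staying linearly independent of the
measured collider.

## Structural equations and their defaults

All second parameters of Normal distributions are standard deviations.

| variable | model | default parameters |
|---|---|---|
| u1, u2 | N(0, sd_u) | sd_u = 0.7071 ≈ √2/2, so sd(x) ≈ 1 |
| z | N(0, sd_z) | sd_z = 1 |
| x | N(u1 − u2, sd_x_noise) | sd_x_noise = 0.05 |
| t | Bern(invlogit(N(u2 − 0.5, 0.25))) | noise added to the log-odds |
| y | N(t − z − 2u1 − 0.5, sd_y_noise) | sd_y_noise = 0.05 |

The treatment logit is centred at −0.5, which yields an empirical
treated fraction near 39%, not 50%; the simulator reports the fraction
but does not force it.

## Synthetic image pool

Each 100×100 patch (0.7 mm isotropic spacing) holds one elliptical
nodule on a noisy background:

- **Size.** The target area is drawn log-uniformly over 20–700 mm²
  (the area of a 30 mm nodule, the conventional upper bound for calling
  a lesion a "nodule"). The mask is the `n` pixels closest to the
  centre in the ellipse metric, so the measured size (pixel count ×
  spacing²) matches the target to sub-pixel accuracy.
- **Annotation ambiguity.** Around the solid core the nodule fades
  linearly to background over a halo whose extent is
  `exp(|N(0, 1.3)|)` times the core area. The mask annotates the core
  only, as human readers outline the solid component; the visible
  extent therefore over-states the annotated size by a random factor,
  giving an irreducible error when predicting the measured size from
  pixels. This emulates the inter-reader segmentation variability of
  real nodule data, which is the dominant part of the "inherent
  measurement error" of the pipeline; the default magnitude puts that
  error in the range the published baseline results imply (error
  variance of order one half on the standardized collider scale),
  where the collider is hard to read precisely while heterogeneity
  stays easy.
- **Heterogeneity.** Intra-core texture is a smoothed Gaussian field
  rescaled so the intensity variance inside the mask equals the target
  exactly (population variance; the pixel set is a complete
  enumeration, not a sample). Targets are log-uniform over
  0.3–5.0 by default, spanning faint to strongly heterogeneous
  nodules on the standardized intensity scale.
- **Background clutter.** Small bright ellipses (vessel cross-sections,
  streaks) are scattered over the background so aggregate patch
  brightness is not a trivial proxy of nodule area — in real chest CT a
  7 cm patch contains far more anatomy than the nodule, and size
  information requires localizing the lesion.
- Pixel intensities of the whole pool are standardized by the training
  split's global mean and standard deviation. Splits are disjoint at
  the patch level; all feature-standardization constants come from the
  training split only.

What the generator does **not** emulate: 3-D structure, spiculation and
lobulation, attachment to pleura or vessels, scanner/vendor texture
differences, and annotation disagreement about nodule *presence*.
Passing tests on this pool show that the estimator behaves correctly
when its assumptions hold — a measurable collider and a prognostic
factor recoverable from the image — not that those assumptions hold for
any particular clinical dataset.

## Matching images to subjects

Pool features are z-scored **log** size and **log** heterogeneity
(training-split constants): target areas are log-uniform, so the log
scale is the one on which the standardized pool features cover the
N(0,1) range of the simulated `(x, z)`. Each subject draws, with
replacement, the patch minimizing the Euclidean distance between the
standardized pairs; ties break to the lowest pool index. Validation
subjects only ever draw from the validation pool.

## Network and losses

A VGG-style CNN: five 3×3 convolutions with 16 channels, each followed
by ReLU, with 2×2 max-pooling after the first four stages (51 → 25 →
12 → 6 → 3, flattening to 144 = 16·3·3); then fully connected layers
of sizes 144, 144, 12 (ReLU + dropout 0.25) and a final linear layer of
N_k = 6 activations. The outcome head is linear regression on the
activations plus the treatment indicator. Optimizer: Adam, learning
rate 1e-3, batch size 40, no weight decay.

Three loss terms:

- `L_y`: minibatch MSE of the outcome;
- `L_x`: MSE tying the reserved activation a₁ to the measured collider;
- `L_reg = max(0, MSE(x̄, x′) − MSE(x̂_reg, x′))`: the improvement an
  in-minibatch OLS of x′ on the remaining activations achieves over the
  batch-mean predictor. The OLS includes an intercept and a ridge
  jitter of 1e-6 on the normal equations; gradients flow through the
  closed-form solution by default (a stop-gradient variant is a config
  switch — by the envelope theorem at the in-batch optimum the two
  gradients coincide, and both are exposed for transparency).

The total loss is the plain sum. Training runs until the validation
total loss stops improving (patience 10 epochs, cap 200), and the best
validation epoch's parameters are restored. Minibatches too small for
the in-batch OLS (m ≤ N_k + 1) are dropped rather than fitted.

### How the independence constraint is actually optimized

Making the hinge the *gradient carrier* of the constraint fails in two
distinct ways, both reproducible on this simulation:

1. *Under-pricing.* The in-sample OLS always beats the raw batch mean,
   by the overfit factor p/m even for independent activations. With a
   unit-variance collider the maximum outcome-loss gain from leaking
   collider signal into the constrained activations slightly exceeds
   the discounted penalty, so gradient descent drifts into collider use
   regardless of seed. The `df_correct` option replaces the two MSEs
   with degrees-of-freedom-corrected variance estimates, which centres
   the hinge at zero under independence ("no better than the mean"
   meaning no better than chance) and prices above-chance dependence at
   full value.
2. *Degenerate gradient geometry.* Differentiating the hinge (with or
   without gradients through the closed-form solution — by the envelope
   theorem the two coincide) yields a rank-one push along the in-batch
   OLS residual. That push vanishes as the fit becomes good, and in
   practice training settles into a limit cycle in which the hinge
   stays large while its gradient keeps failing to remove a distributed
   leak.

The package therefore separates *measurement* from *optimization*: the
hinge is always the quantity logged, reported and used for early
stopping, while the constraint's gradient is carried by a
decorrelation penalty — the sum of squared sample correlations between
each constrained activation and x′ (`decorrelation_weight`, default
27, ramped in linearly over `constraint_ramp_epochs` = 15 after a
warm-up of `constraint_warmup_epochs` = 10 during which only L_y and
L_x train). The warm-up lets the reserved slot a₁ become a good collider
carrier first, which makes any leak in the other activations redundant
for the outcome loss and therefore cheap to remove; the ramp avoids the
representation collapse a suddenly-enabled large penalty causes.  The
collider losses are evaluated on a dropout-free forward of the same
minibatch (`clean_collider_pass`), so the penalty prices the dependence
of the deterministic activations the post-hoc estimator will use.
Matching, diagnostics (R² is scale-invariant) and all estimators see
the standardized x′; `collider_loss_scale` is exposed for feeding the
collider target to `L_x`/`L_reg` on an amplified scale but defaults to
the natural one.

## Post-hoc estimation

After training, all CNN parameters are frozen and activations are
computed per subject on the deterministic path (center crop, no flips,
dropout off). The reported estimates come from ordinary least squares
refits on the training split, evaluated on the validation split:

- **CausalNet**: y ~ t + a₂..a₆ (the collider slot is excluded);
- **BiasedNet**: y ~ t + a₁..a₆ (conditions on the full image);
- **Regression baselines**: y ~ t, y ~ t + x′ + z′, and y ~ t + z′ on
  the simulated cohort, with x′, z′ = x, z plus Gaussian measurement
  noise whose standard deviations are calibrated from the pipeline's
  inherent error — by default the matching discrepancy
  (mean squared difference between the subject's (x, z) and the matched
  patch's standardized features); a ground-truth CNN run (same
  architecture trained to predict x or z) is available as the
  calibration the published procedure describes, and explicit values
  can be set in the config.

Rank-deficient designs drop collinear columns with a warning (constant
activations are common when ReLU units die). The independence
diagnostic is the validation R² of x′ regressed on the constrained
activations; values near zero mean the post-hoc regression mimics
omitting the collider.

## Scale-mismatch sensitivity

The measured collider can be fed to the network on the wrong scale:
treating the standardized log-size as a z-score of log-area, it is
mapped to the positive area scale, raised to a power (3: a
diameter-scale collider measured as volume; 1/3: the inverse), and
re-standardized with training-cohort constants. Rank order is preserved
for every mode, so this probes robustness to monotone measurement
distortions.

## Numerical and testing choices

- The CNN trains in single precision (standard for CNNs); the loss
  functions preserve double precision when given float64 inputs, and
  the unit tests verify `L_reg` against an independent normal-equations
  oracle to 1e-8 in float64.
- The reverse-mode autodiff engine is checked against central finite
  differences op-by-op and end-to-end through the full loss.
- The test suite exercises the full pipeline at a reduced scale —
  750/250 matched subjects, a pool of 1200 patches, 40 epochs, Adam
  learning rate 3e-3 — chosen so several replicate trainings complete
  in minutes on one CPU. The learning rate is raised relative to the
  full-scale default because Adam moves each parameter by roughly the
  learning rate per step and the reduced runs take about a fifth as
  many steps. Full-scale defaults (3000/1000 subjects, pool 2000+,
  lr 1e-3, up to 200 epochs) reproduce the published protocol.

## Known limitations

- The identity of the collider must be known and a measurement of it
  available; the method removes linear dependence only.
- The in-batch hinge is a noisy estimate of the population dependence
  (overfit floor ≈ p/m per batch); enforcement quality therefore
  depends on batch size and the collider-loss scale.
- Whether training converges to a leak-free representation depends on
  the race between the collider slot learning x′ and the outcome head
  discovering size as a shortcut; the training log (per-epoch L_x,
  L_reg on both splits) is the tool for auditing this, and the
  independence R² should always be checked before trusting the ATE.
- Holding the constraint and extracting prognostic signal compete for
  the shared representation. At the reduced replication scale (~950
  optimizer steps) the default configuration resolves the competition
  in favour of the constraint: the treatment effect is recovered
  without bias and the independence diagnostic is clean, but the
  surviving activations carry little net outcome signal, so the
  constrained model's validation MSE sits near the image-free
  baseline rather than below it. Larger step budgets relax this
  trade-off; the audit quantities to watch are the ones above.
- A single collider; extensions with several reserved slots are out of
  scope.
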