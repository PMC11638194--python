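# Methods

## Problem and model

Early sepsis prediction from ICU data is a binary classification task —
will this patient meet the Sepsis-3 criteria within the next `h` hours
(`h ∈ {0..6}`) — whose inputs mix three streams per stay: a multivariate
vitals/labs window `O` of shape `(t, o)`, a static-indicator vector `B`
(age, sex, admission category, comorbidity), and a bag of clinical-note
tokens `Z`.  A model trained to maximise observational accuracy will use
any feature that co-varies with the outcome, including features that are
associated with sepsis only through common causes.  Those shortcuts do not
survive distribution shift, which is the practical failure mode this
package targets.

The causal structure assumed is: a latent severity process drives both the
observations and the outcome (the causal path), an unobserved confounder
`e` affects both the extracted features and the outcome, and two observed
confounders — the note content `Z` and the static indicators `B` — affect
both the feature-extraction path and the outcome, opening back-door paths.
The predictor combines two classical remedies, each realised with learned
representations:

1. **Instrumental-variable representation.**  Two convolutional encoders
   with identical architecture and disjoint weights map `O` to a candidate
   instrument `A = φ_A(O)` and a confounder representation `C = φ_C(O)`
   (each 128-dim).  The causal feature `X` is an MLP over `[A; C]`.
   Instrument validity is pushed for by five diagonal-Gaussian variational
   heads `q(X|A)`, `q(Y|A)`, `q(X|C)`, `q(Y|C)`, `q(C|A)` and a
   contrastive objective: raise the matched-versus-mismatched
   log-likelihood contrast (a variational surrogate for mutual
   information) for the pairs that should be dependent (A–X, C–X, C–Y) and
   lower it for the pairs that should not (A–Y, A–C).  Optimisation is
   two-stage per batch: `k = 5` head-fitting steps on detached encoder
   outputs (only head parameters move), then one main step through
   encoders, fuse, adjustment and classifier with head parameters frozen.
2. **Back-door adjustment with the NWGM approximation.**  Because the
   classifier ends in a softmax, the expectation over confounder strata is
   moved inside the network (normalized weighted geometric mean):
   `f_y(X) = α1·X + α2·Σ_b P(b)·M(b)` for static levels and
   `f_z(X) = β1·X + β2·Σ_w P(w)·s_w·H(w)` for tokens, with
   `s_w = H(w)·X / n` the token's importance for `X`.  `P(B)` and `P(Z)`
   are empirical priors from the training split; `M(b)` is a learned
   per-level embedding projected to `X`'s dimension; `H(w)` is a
   pretrained-style word vector with a learned linear projection.  The
   classifier sees `[f_y(X) + f_z(X); C]`.  For point-mass priors the
   approximation is exact, which is how the implementation is tested.

## Architecture details

Branch 1 of each encoder treats time steps as channels: conv1d `t→64`
(kernel 3, padding 1) over the feature axis, transpose, conv1d `o→32`,
batch-norm, max-pool, giving a `(32, 32)` map.  Branch 2 applies the same
pattern with the axes swapped.  The second convolution always sees length
64 (the first convolution's channel count transposed into the length
axis), so the `(32, 32)` map holds for any valid `(t, o)`.  Each map runs
through a LeNet-style head — two 5×5 conv + 2×2 max-pool blocks and a
linear layer — to a 64-vector; concatenation gives the 128-dim output.
The fuse MLP is `256→256→128` with tanh; the classifier is
`256→64→2` with ReLU and softmax.

Everything runs on the package's own reverse-mode autodiff core
(`causalsepsis.nn`): float64 tensors by default (the arithmetic contracts
in the tests are asserted to 1e-10), float32 inside training loops for
throughput.  Checkpoints restore bit-identical predictions because state
dtypes are preserved on load.

## Numerical choices

* **Gaussian head form.**  `log q(x|·) = −(x−μ)²·e^{−σ} − σ` with `σ` the
  log-variance (no ½ factors, no constants) — the heteroscedastic Gaussian
  log-likelihood up to constants.  `σ` is soft-bounded to ±8 via a scaled
  tanh.  A Bernoulli variant for the binary outcome heads is available via
  `bernoulli_y`.
* **Contrastive components.**  Each component averages
  `log q(matched) − log q(mismatched)` over the full d×d ordered-pair grid
  of a batch; the combination is
  `L_1 = L_AX + L_AY + δ1(L_CX+L_CY) + δ2·L_AC` with trainable positive
  δ's (softplus, initialised to 1).  Because the log-likelihoods sum over
  target dimensions, the 128-dim components are numerically much larger
  than the scalar-outcome components; this imbalance is a property of the
  printed combination and is kept as is (re-weighting by dimension was
  tried and destabilised training).
* **Stability safeguards.**  The combined objective is unbounded below
  through the contrastive terms, and unconstrained training lets a single
  component (typically the C–X contrast) run away and starve
  classification.  Three safeguards keep the per-component formulas exact
  while bounding their influence: each component enters the combination
  through a soft magnitude cap `10·tanh(term/10)` (identity in the normal
  operating range); one supervised warm-up epoch precedes the causal
  losses; gradients are clipped to global norm 5.  Raw component values
  are logged and tested exactly.
* **Class imbalance.**  Training splits are balanced 1:1 by down-sampling
  the majority class; validation and test splits are brought to ≈4:1
  negatives per positive.  Stays are allocated 70/15/15 per class before
  ratio enforcement, and no stay appears in more than one split.
* **Missing observations** (tabular inputs): hourly binning with
  last-observation-carried-forward, then within-window median fill, plus a
  binary observed-mask channel appended per feature (configurable).
* **Defaults.**  Window `t = 24` hourly steps; `o = 20` channels for the
  synthetic cohorts; encoder output 128; Adam with learning rate 1e-3 for
  both stages; batch 64; `λ = 1` on the causal losses; one model per
  horizon.

## The synthetic generator

The generator emulates the structure of a credentialed ICU EHR cohort
without its data: irregular multivariate windows, demographic priors, note
tokens, and — crucially — a known causal graph.  Per stay it draws latent
severity `s`, unobserved confounder `e`, a note-confounder trait `z` and a
demographic trait `b` (elderly, comorbid and emergency admissions
up-weighted), then sets

    logit P(Y=1) = −1.1 + β·s + γ_e·e + γ_Z·z + γ_B·b

with defaults `β = 2.0, γ_e = 0.8, γ_Z = 1.5, γ_B = 1.0` — a strongly
confounded regime.  Observation channels are partitioned by a seed-fixed
permutation into severity channels (lagged within-window ramps so the
temporal encoder has structure to exploit), nuisance channels driven by
`e`, `z` and `b`, and pure-noise channels.  Latent draws are shared across
horizons: a window ending `h` hours before onset differs only in its
severity signal amplitude, which ramps linearly from 0.6 at `h = 6` to 2.0
at `h = 0`, so shorter horizons are genuinely easier and horizon
comparisons are paired.  Note tokens follow a Zipf prior with designated
severity-tilted and confounder-tilted token subsets; word vectors are
random unit vectors fixed by seed, written in GloVe text format (a
synthetic stand-in for pretrained embeddings).

The interventional split regenerates the same stays from the same draws
with the `Z→Y` and `B→Y` edges severed; `O`, `B`, `Z` coincide
episode-for-episode, only outcomes differ.  The generalization gap —
interventional minus observational AUC — therefore isolates reliance on
observed-confounder shortcuts.  What the generator does **not** emulate:
clinically realistic vitals dynamics, treatment feedback, informative
missingness, or note semantics; a pass here shows the causal machinery
works where its assumptions hold, not that it transfers to real EHR data.

## The mutual-information probe

`mi_probe` audits trained representations.  It fits a fresh linear-Gaussian
variational head by exact maximum likelihood on half of the pairs
(cross-fitted both ways) and returns the InfoNCE contrast — matched
conditioning versus the log-mean-exp over mismatched conditionings — on
the held-out halves.  A constant critic yields exactly zero, so
independence maps to ≈0; on bivariate Gaussians the estimate tracks the
analytic `−log(1−ρ²)/2` closely (e.g. 0.82 vs 0.83 at ρ = 0.9,
n = 2000).  Wide targets are reduced to variance-carrying principal
components and wide conditionings to their most target-predictive ridge
directions (fit-half statistics only), making wide-input estimates lower
bounds — the conservative direction for the audits.  The `train_steps`
argument is retained for interface compatibility; the exact fit needs no
iteration.

## Problem sizes used by the test suite

Stochastic end-to-end checks train on synthetic cohorts of 1200 stays for
10 epochs over 5 seeds (the variant grid: full model, plain supervised
baseline, instrument-only, adjustment-only, and a no-exclusion-term
ablation), probe representations on fresh 2000-stay draws, and use
n = 2000–5000 for the probe-calibration and linear-benchmark checks.
`scripts/acceptance.py` re-runs the grid at the same sizes over 3 cohorts.

## Known limitations

* The instrument-exclusion pressure acts on *marginal* dependence between
  `A` and `Y`; the theoretical condition is conditional on `X` and `e`.
  In a linear-Gaussian benchmark this distinction is decisive: the learned
  `A` tracks the fitted outcome direction, and probing it as a 2SLS
  instrument does not de-bias the effect estimate relative to naive OLS
  (measured and reported honestly by the test suite).  The benefit the
  machinery does deliver — and which the interventional-split evaluation
  confirms — is a representation less reliant on observed-confounder
  shortcuts.
* Training the combined objective is sensitive: without the soft component
  cap and warm-up, a large fraction of seeds collapse.  The safeguards
  make all tested seeds healthy, but the variance across seeds of the
  interventional advantage remains substantial (per-seed gaps 0.01–0.08).
* The back-door adjustment absorbs the expectation over strata into fixed
  prior-weighted vectors, so at inference no per-patient `B` or `Z` is
  consulted; the adjustment acts as a learned, prior-informed linear
  correction of `X` rather than a per-patient covariate path.
* AUC confidence intervals use a percentile bootstrap over episodes
  (1000 resamples), which ignores patient-level clustering beyond stays.
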