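# Methods

## The model

The classifier is a recurrent log-linearised Gaussian mixture network
(R-LLGMN): a continuous-density hidden Markov model whose parameters are
absorbed into the weights of a recurrent network and learned by gradient
descent.  Each class `c ∈ {1..C}` (here `C = 2`: class 1 "normal", class 2
"deterioration") carries `K_c` hidden states with strictly positive
transition probabilities `γ^c_{k',k}`, state priors `π^c_k`, and per-state
Gaussian mixture emissions with `M_{c,k}` components (mixing `r_{c,k,m}`,
mean `μ`, covariance `Σ`).  The class posterior of a sequence
`x(1..T) ∈ R^d` follows the scaled forward recursion

    a^c_k(1) = π^c_k b^c_k(x(1)),
    a^c_k(t) = Σ_{k'} a^c_{k'}(t−1) γ^c_{k',k} b^c_k(x(t)),
    P(c,k|x(1..t)) = a^c_k(t) / Σ_{c',k'} a^{c'}_{k'}(t),
    P(c|x(1..t)) = Σ_k P(c,k|x(1..t)).

Because `log[γ r N(x; μ, Σ)]` is linear in the expanded input
`X = [1, x, x_i x_j (i ≤ j)]`, each product `γ_{k',k} r_m N(x; μ, Σ)` can be
written as `exp(w_{c,k',k,m} · X)` for a single coefficient vector.  The
network evaluates the recursion through five layers: quadratic expansion,
exponentiated linear units (one per `(c, k', k, m)`), a sum over source
states and components weighted by the previous step's state posterior, joint
normalization over all `(c, k)`, and a sum over states.  The normalized
state posterior is fed back instead of the raw forward variable; the scale
difference cancels in the joint normalization (verified to 1e-9 in the
tests).

### Expansion term order

`X = [1, x_1..x_d, x_i x_j for i ≤ j row-major]`, so `H = 1 + d + d(d+1)/2`.
Weight files are meaningless under any other ordering; the order is recorded
in the file header (`term_order`).

### Boundary condition and priors

The recurrent boundary is `O⁴_{c,k}(0) = 1` for every unit.  A single
time-homogeneous weight tensor therefore implies a first-step state prior
proportional to the column sums of `Γ^c` — not uniform, and not freely
choosable.  `encode_hmm_gmm` consequently emits, by default, a second tensor
used only at `t = 1` whose constant term is `log(π_k r_{c,k,m} / K_c)`;
summing the all-ones boundary over `k'` then yields exactly
`π_k b_k(x(1))`, making the encoding exact for arbitrary valid parameters
(the oracle-equivalence suite exercises 200 random instances at ≤ 1e-6).
With `first_step_priors=False` the single tensor is returned as trained
networks store it; it coincides with the oracle only when the transition
columns sum to 1, the prior is uniform, and the classes share one state
count.  Trained networks are always time-homogeneous: a single trained
tensor cannot represent `π` and `Γ` separately, and does not need to —
whatever first-step behaviour fits the data is absorbed into the weights.

### Numerical stability

Layer-2 pre-activations are shifted by their per-time-step maximum before
exponentiation.  The shift cancels exactly in the joint normalization (an
invariance the tests assert at 1e-12), so it needs no gradient.  If the
layer-3 normalizer still underflows to zero or overflows, the forward pass
raises a numerical-degeneracy error rather than propagating NaN.

## Training

The objective is the final-step cross-entropy
`J = −Σ_n Σ_c Y^(n)_c log O⁵_c(T)` (teachers supervise only `t = T`; the
per-step variant is out of scope).  Gradients are exact backpropagation
through time, accumulated through the recurrent dependence on the previous
state posterior; exactness is enforced permanently by a central
finite-difference test (max relative error ≤ 1e-4, observed ~1e-7).
A saturated output (teacher-class posterior exactly 0) contributes a clamped
`−log` at the double-precision floor instead of infinity.

Optimisation is full-batch gradient descent with a deterministic monotone
step rule: starting from `learning_rate` (default 0.05), the step is halved
until the loss does not increase and grown by 1.1× after every accepted
step (capped at 100× the configured rate).  A fixed step is unreliable
here: the quadratic input expansion makes the loss surface curvature scale
with the fourth power of the input amplitude, so unit-scale inputs diverge
at 0.05 while σ_d-scaled inputs (0.01) crawl.  The monotone rule handles
both without per-dataset tuning, guarantees a non-increasing loss
trajectory, and keeps training bit-reproducible.  Training runs `restarts`
independent initialisations (default 5, the customary repeat count for this
network family), each drawing initial weights uniformly from
`[−init_range, init_range]` (default 0.1) from its own seeded substream,
and returns the restart with the lowest final J.  Stopping: `|ΔJ| < tol`
(default 1e-6) or `max_epochs` (default 1000).

The weights are overparameterised (a softmax-style gauge freedom); nothing
is pinned by default since training is unaffected, but `pin_unit=True`
fixes the last unit of the last class at zero for reproducible comparisons.

## Preprocessing

* HRV indices on a trailing window: CVRR = sample std (N−1 divisor) of the
  RR intervals over their mean; RMSSD = root mean square of the N−1
  successive differences (divisor N−1); pNN50 = fraction of successive
  differences with |diff| ≥ 50 ms (the ≥ convention is deliberate and
  tested).  Default geometry: 30-s windows stepped by 10 s; an analysis
  segment of 30 s yields T = 3 three-dimensional vectors.
* Standardization to mean 0, sample std `σ_d` per record per channel —
  no leakage across patients.  Defaults follow the established settings for
  this model family: `σ_d = 0.01` for multichannel inputs, `0.1` for
  one-dimensional RRI input.  Constant series map to zeros with a log entry.
* Optional noise-robust differentiation
  `Δs(t) = (1/(18Δh))[Σ_{n=2..4} s(t+nΔh) − Σ_{n=2..4} s(t−nΔh)]`, emitted
  only where all six taps exist (output 8 samples shorter); exact on affine
  signals.  Off by default — standardization alone is the better-performing
  preprocessing for this model.
* Labels: a window ending at `t` is class 2 iff an event occurs in
  `(t, t + P]` minutes.  Vitals windows default to 12 min of 1-min samples
  (T = 12, d = 4: HR, SBP, DBP, MAP).

## Evaluation

Decision score: class-2 posterior at the final step (the causal choice; the
per-step trajectory is available for plotting).  Threshold: the ROC
candidate (unique observed scores, `score ≥ θ` ⇒ positive) maximizing
Youden's J, ties resolved toward the smaller threshold, selected on
learning data only.  AUC: trapezoid over the unique-score operating points,
identical to the Mann-Whitney statistic with ties credited ½ (cross-checked
against scikit-learn at 1e-12 on 100 random sets).  Percentages are stored
at full precision and rounded to 1 decimal for display; ratios with empty
denominators are reported as absent, never NaN.  Cross-validation holds out
one patient or one event per fold, thresholds on the training folds, pools
held-out decisions into one report per repeat, and reports the mean
accuracy across repeats plus the pooled confusion table of the last repeat.

## Synthetic data

Generators are fully deterministic given (spec, seed).  The default cohort
matches the geometry the classifier targets: 20 positive and 20 negative
sequences, T = 12, d = 4, ground truth C = 2, K = 3 states per class,
single-Gaussian emissions with identity covariance, sticky transitions
(0.8 self-probability), uniform priors, and a class-centroid separation of
3 pooled standard deviations (class 2 shifts every state mean by a vector
of norm 3).  Because the generating model is explicit, the Bayes-optimal
posterior is computable exactly (oracle recursion with class priors
`n_neg : n_pos`), which anchors the end-to-end checks: leave-one-event-out
CV accuracy ≥ 90% and trained AUC within 0.05 of the Bayes AUC on the
default cohort, and CV accuracy inside [35%, 65%] at separation 0 (a
leakage guard — with identical class distributions any systematic departure
from chance indicates information bleeding across folds).

The vitals generator emits stationary baselines (HR 80 bpm, SBP 120 mmHg,
DBP 70 mmHg, Gaussian measurement noise) for negatives and a deterministic
pre-event drift (SBP −30, DBP −15, HR +15 over the 5-min lead) for
positives, with MAP = (SBP + 2·DBP)/3 + noise.  The RRI generator uses
AR(1) intervals with the AR coefficient set from
`RMSSD² = 2·SDNN²·(1 − φ)`, so the realized RMSSD approaches its target
(within 15% over ≥ 300 s).  What these generators do **not** emulate:
artefacts and ectopic beats, missing-data patterns, non-Gaussian and
non-stationary physiology, inter-patient heterogeneity beyond the class
shift.  Passing the suite therefore demonstrates correctness of the
machinery under its own assumptions, not clinical performance; accuracies
on real cohorts must be established on real data through the CSV ingestion
path.

## Problem sizes and harness choices

The cross-validation checks run 40 folds on the 40-sequence default cohort
with 2 restarts and at most 300 epochs per fold and a single repeat —
settings at which every fold converges well past the stopping tolerance on
this cohort while the whole suite stays quick.  The published-table checks
are pure integer/percentage identities and run in milliseconds.

## Known limitations

* Training is batch gradient descent; no adaptive optimisers are wired in
  (the config leaves room for them).
* Baum-Welch estimation of the explicit HMM-GMM parameters is out of scope;
  the explicit parameterisation exists to generate data and to verify the
  network, not to be fitted.
* Classes share the input dimension; emissions other than Gaussian mixtures
  are not supported.
* The ROC threshold rule (Youden, low tie-break) is one defensible choice
  among several; it favours sensitivity-leaning operating points.
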