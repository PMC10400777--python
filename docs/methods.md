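# Methods

## The model

Structural covariance treats the correlation of a regional morphometric
measure across subjects as a connectivity metric. Given a cohort matrix
`X` (n subjects × N regions of mean regional gray-matter volume, GMV), the
group-level structural covariance network (SCN) is the N × N matrix of
pairwise Pearson correlations of the region columns.

A group correlation carries no subject index, so the SCN is individualized
through jackknife pseudovalues. For edge e with full-sample correlation
`r(e)` and leave-one-out correlation `r_{-i}(e)`,

    Theta_i(e) = n * r(e) - (n - 1) * r_{-i}(e),

the classical jackknife pseudovalue, quantifies subject i's contribution
to the group correlation. Pseudovalues are not confined to [-1, 1]; their
subject mean reproduces the identity
`mean_i Theta_i(e) = n*r(e) - (n-1)*mean_i r_{-i}(e)` exactly, which the
test suite asserts to 1e-12. An optional flag computes pseudovalues on
Fisher z-transformed correlations instead of raw r; raw r is the default
because nothing in the protocol requires the variance-stabilized scale,
and the default keeps pseudovalues interpretable as correlation
contributions.

Connectome-based predictive modeling (CPM) then predicts a behavioral
severity score (FTND, 0–10) from the subjects × edges pseudovalue matrix:

1. in the training set, correlate every edge with the score (Pearson r,
   two-tailed p from `t = r*sqrt((n-2)/(1-r^2))` with n-2 df);
2. keep edges with `p < threshold_p` (default 0.01, strict inequality) and
   split them by the sign of r into a positive and a negative network;
3. per subject, sum the pseudovalues over each network mask ("network
   strength");
4. fit ordinary least squares: `score ~ intercept + strength` for a
   single-sign model, or `score ~ intercept + pos_strength + neg_strength`
   in combined mode (a single-predictor difference score `pos - neg` is
   available via `combined_form="difference"`);
5. apply the fitted coefficients to the held-out subject.

Evaluation uses leave-one-out cross-validation: selection, strengths and
coefficients are recomputed inside every fold from the n-1 training
subjects, so the held-out subject never influences the model that predicts
it (asserted by mutation tests). Performance is the Pearson correlation
between out-of-fold predictions and true scores. Significance comes from
permutation: each run shuffles the score vector, reruns the entire LOOCV,
and records that run's performance r; the p-value is
`(1 + #{null r >= true r}) / (1 + n_perm)`. The add-one correction keeps
valid p-values bounded away from zero; the raw proportion is available via
a flag. Shuffling scores alone is equivalent to shuffling both scores and
connectomes, so only the scores are permuted. Runs whose predictions are
constant have undefined r and enter the null as negative infinity; an
undefined true r yields p = 1.

Two selection summaries are reported: the consensus network (edges
selected in every fold — the primary, conservative summary) and the
full-sample selection (edges selected once on all subjects — secondary).
Anatomy summaries — node degree, top-k degree tables (ties broken by atlas
order), and within/between canonical-network edge counts — operate on
either. Edges touching regions without a canonical-network assignment are
tallied under an explicit `UNASSIGNED` bucket so that edge counts are
conserved (handshake identity checked property-based).

A sensitivity analysis correlates the predicted scores with nuisance
covariates (total intracranial volume, image quality rating, age); absent
correlations indicate the prediction is not a confound artifact.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `threshold_p` | 0.01 | per-edge selection threshold (strict `<`) |
| `mode` | combined | positive / negative / combined network model |
| `combined_form` | two_predictor | OLS with both strengths, or their difference |
| `n_perm` | 5000 | permutation runs for the null distribution |
| `add_one` | true | (1+k)/(1+n_perm) p-value vs raw proportion |
| `fisher_z` | false | pseudovalues on arctanh(r) instead of raw r |

Degenerate situations are handled explicitly: an empty mask contributes a
zero strength and is dropped from the design (so combined mode with an
empty negative mask equals positive mode exactly); a fold with no selected
edges, or a rank-deficient design (e.g. constant strengths), predicts the
training-score mean with a logged warning; zero-variance edges get r = 0,
p = 1. NIfTI-based regional extraction requires grids to match (affines
within 1e-4 absolute); resampling is out of scope.

## The synthetic-cohort generator

No cohort data are distributed, so a generator produces cohorts whose
ground truth is known. It plants, on designated region pairs, a per-edge
shared latent factor whose loading follows the subject's standardized
score z_i: `lam_i = max(0, lambda0 + beta*z_i)` for positively coupled
edges and `max(0, lambda0 - beta*z_i)` for negatively coupled ones, added
to both endpoint regions on top of independent Gaussian region noise.
This is the minimal structure under which a subject's contribution to an
edge's group correlation — the jackknife pseudovalue — is monotone in the
score, i.e. exactly what CPM on individualized SCNs assumes. Scores are
Normal(6, 2.5) clipped to [0, 10], emulating a moderately dependent
smoker cohort; region means are Normal(500, 50); TIV, IQR and age are
drawn independently of the score so that the sensitivity analysis has a
true null. One seeded RNG stream with a documented draw order makes
cohorts byte-reproducible.

Defaults: `coupling beta = 0.8`, `base_load lambda0 = 1.0`,
`noise_sd = 0.25`. The noise level sets the share of edge covariance
carried by the planted factor (~0.85 at the defaults), a strong-signal
regime chosen once so that recovery benchmarks probe the estimator rather
than raw detection power.

What the generator does not emulate: spatial structure and smoothness,
global covariance among all regions (baseline regions are independent),
integer-valued FTND scores, site/scanner effects, and any non-smoker
control group. Passing benchmarks therefore demonstrate the estimator's
correctness and calibration under the assumed structure, not performance
on real MRI cohorts.

## Benchmark conditions and known limitations

The packaged benchmarks use n = 100 subjects, N = 30 regions and 20 + 20
planted edges (LOOCV r, permutation p, consensus precision/recall,
monotonicity in beta), and 200 signal-free cohorts of n = 60, N = 15 with
200 permutations each for null calibration; `scripts/acceptance.py`
reports medians over 10 replicate cohorts at the recovery conditions.
These sizes keep a full run in minutes on one CPU while leaving the
Monte-Carlo bands tight enough to detect miscalibration.

Two structural limitations are worth knowing:

- **Consensus recall is bounded.** An edge's planted factor enters each
  subject's contribution through `lam_i^2 * u_i^2` with `u_i ~ N(0, 1)`,
  so the pseudovalue carries multiplicative chi-square noise that caps the
  per-edge pseudovalue–score correlation near 0.4 even at vanishing region
  noise. Requiring selection in all ~100 folds at the p < 0.01 cutoff
  (|r| ≈ 0.26 at n = 99) therefore recovers only the stronger part of the
  planted set: median consensus recall is ~0.25–0.3 at the defaults, with
  precision ~0.85. Consensus is a high-precision, moderate-recall summary.
- **Many-edge regimes can anti-predict.** Pseudovalues of one edge nearly
  sum to a constant across subjects, and the individualized SCN is built
  on the full cohort before cross-validation (as in the protocol this
  package implements). A fold is then slightly more likely to select a
  chance edge precisely when the held-out subject's value opposes the
  training trend. With few planted edges at full atlas scale
  (E = 6,670, ~67 chance selections per fold at p < 0.01), these
  anti-aligned chance edges can dominate the strengths and drive the LOOCV
  r negative. At the benchmark scale (E = 435, ~4 chance edges per fold)
  the planted signal dominates. Users applying the pipeline to full-atlas
  data should expect meaningful prediction only when the true
  severity-related network is large or strong relative to the chance
  selection rate — consistent with protocols of this family reporting
  modest r on real cohorts.

Numerical choices: correlations are computed on centered data; per-fold
training correlations use exact downdates of full-sample sums (O(nE) per
LOOCV rather than O(n^2 E)) and agree with direct recomputation to well
below test tolerances; selection inside folds uses the critical-|r|
equivalent of the t threshold, which is algebraically identical to
comparing p < threshold; the OLS fall-back threshold is a relative rank
cutoff of 1e-10 in `lstsq`. The jackknife itself recomputes each
leave-one-out correlation matrix directly, which is O(n^2 N^2) but exact
and fast at cohort scale (~0.5 s at n = 100, N = 116).
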