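# Methods

## Model

Promoter strength of σ70-dependent *E. coli* promoters is modelled as a
log-linear function of the PWM scores of the two conserved hexamer
elements:

    ln(strength) = β0 + β35·s35 + β10·s10 + ε,   ε ~ N(0, σ²)

Strength is normalized to a reference promoter, so it lies in (0, 1] for
the training data; because ln diverges as strength → 0, strengths are
floored at 1e-4 before the transform (`STRENGTH_FLOOR`). Normalizing by a
different reference multiplies all strengths by a constant and therefore
shifts only the intercept, never the slopes — a property the test suite
checks explicitly.

The additive PWM score is the standard independent-positions
approximation to the protein–DNA binding energy; the log-linear link
encodes the assumption that binding-energy differences act
multiplicatively on transcription initiation rates. No interaction
between the two elements is modelled: on the training data the
interaction coefficient is indistinguishable from zero (p ≈ 0.98) and
the interaction model has a lower adjusted R².

## PWM construction

Given aligned hexamers, per-position base counts `c[i,b]` are converted
to log-odds weights

    w[i,b] = log_2( (c[i,b] + pc·q_b) / (n + pc) / q_b )

where `q` is the background distribution and `pc` the total pseudocount
mass per position, apportioned proportionally to the background. The
defaults are:

* **background** — GC-content derived: q_G = q_C = 0.508/2, q_A = q_T =
  0.492/2 (*E. coli* GC content 50.8%);
* **pseudocount_total = 1.0** per position, i.e. A/T receive 0.246 and
  C/G 0.254. One unit of prior mass is the usual Laplace-style choice; it
  guarantees finite weights without visibly distorting frequencies at the
  hexamer-set sizes involved (hundreds to ~1000 sequences);
* **log base 2**, recorded on the PWM and configurable. Score magnitudes
  are therefore in bits; any base gives the same regression R² since the
  change of base is a linear rescaling of the features.

With these conventions a base whose observed frequency equals its
background frequency has weight exactly 0, and the probability matrix is
exactly recoverable from the weights (round-trip tested at 1e-12).

### Exact score p-values

The p-value attached to a hexamer score t is P[score(X) ≥ t] for X drawn
i.i.d. from the background at each position. Positions are independent,
so the null score distribution is the convolution of six 4-point
distributions; it is computed exactly, merging equal sums at a 1e-9
resolution (at most 4⁶ = 4096 support points, so this costs microseconds
and agrees with exhaustive enumeration to better than 1e-6). A score
within 1e-6 of a support point counts as reaching it, absorbing the
accumulated float rounding of the merge. An approximate fixed-width
score grid was considered and rejected: it is no cheaper at width 6 and
its boundary effects break exact agreement with enumeration.

### Region scanning

Promoter element positions are uncertain by a few bases, so extraction
takes 13-nt windows centred on the nominal −35/−10 positions, scores all
eight 6-nt sub-windows, keeps the best (ties broken toward the smallest
offset) and retains the region iff the best hit's p-value is below α
(default 0.05). A single pass is used: match, filter, then build the
final PWMs from the retained hexamers — no iterative re-derivation.
For the very first pass, before any PWM exists, a consensus matcher
scores hexamers by −(mismatches) against `TTGACA`/`TATAAT`, with its own
exact mismatch-count null distribution. Reverse-strand scanning is out
of scope: promoter regions are strand-resolved by construction.

## Fitting and inference

`fit_ols` solves the least-squares problem by a rank-revealing
decomposition (`numpy.linalg.lstsq`) after an explicit rank check that
rejects collinear designs. `fit_gradient_descent` minimizes the
mean-squared-error cost J(β) = ‖Xβ − y‖²/(2n) by full-batch descent from
zero initial coefficients. Defaults: learning rate 0.015 and 1e5
iterations, which converge on the unscaled training features (largest
curvature of the cost ≈ 80, so rates below ≈ 0.025 are stable there);
optional internal standardization (`feature_scaling=True`) permits much
larger rates, with coefficients mapped back to the raw scale. Divergence
— a non-finite cost, or cost increasing over 100 consecutive steps —
raises an error suggesting a smaller rate or scaling. The two routes are
interchangeable: on the training data their fitted values correlate at
≥ 0.998 (in practice 1.0 to machine precision).

Inference is classical OLS: coefficient standard errors from
σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n−m−1), two-sided t p-values, the overall F
test on (m, n−m−1) degrees of freedom, and level-0.95 confidence
intervals estimate ± t₀.₉₇₅,ₙ₋ₘ₋₁·SE. Adjusted R² follows
1 − (1−R²)(n−1)/(n−m−1). No robust/sandwich errors are provided. An
exactly interpolating fit (residual variance numerically zero, below
1e-20 relative) reports infinite t statistics with a warning rather than
failing.

## Validation machinery

* **LOOCV** refits OLS n times, once per held-out promoter. For OLS this
  equals the closed-form shortcut cvresᵢ = residᵢ/(1−hᵢᵢ); both routes
  are implemented and cross-checked at 1e-8, and the explicit refit is
  the one reported.
* **Random baseline** draws (−35, −10) hexamer pairs with bases i.i.d.
  uniform on {A,C,G,T} — the model consumes only hexamers, so random
  "promoters" are random pairs — scores them, and summarizes the
  predicted strengths over 100 sets of 100 pairs: grand mean of the
  set means, standard error sd(set means)/√(n_sets). The grand mean is
  invariant to the partitioning into sets; the set structure only
  furnishes the standard error.
* **Diagnostics** emit the four standard linear-model plot datasets as
  tables (no rendering): residual vs fitted, √|standardized residual| vs
  fitted, normal Q-Q of internally studentized residuals with
  (i−0.5)/n plotting positions, and standardized residual vs leverage.
* **Correlation analysis** reports the Pearson matrix over s35, s10,
  the combined score s35+s10, raw strength, and log strength. Pearson is
  used throughout.

## Training data

The 18-promoter training library (hexamers, normalized strengths, and
their published PWM feature scores) is embedded in
`promstrength.fixtures`. The published feature scores are shipped
verbatim and used directly for all regression-facing results, because
the exact PWM parameterization that produced them (log base, pseudocount
magnitude, source hexamer sets) is not recoverable; PWM construction is
instead exercised against synthetic hexamer sets (below). This cleanly
separates regression results, which are exact and reproducible from the
embedded table, from PWM behaviour, which is checked by properties and
brute-force oracles.

One training-table inconsistency is documented in the fixture: the
published prediction for BBa_J23110 is not reproducible from its own
published feature scores (its −35 score entry duplicates TTTACG's score
although its hexamer is TTTAGG). The scores are kept verbatim; the
row-wise reproduction test covers the other 17 promoters.

## Synthetic data generator

`SyntheticMotifProfile` emulates a curated hexamer collection by
per-position base probabilities. The default profiles place
literature-typical σ70 conservation on the consensus base (−35
`TTGACA`: 0.69, 0.79, 0.61, 0.56, 0.54, 0.54; −10 `TATAAT`: 0.77, 0.76,
0.60, 0.61, 0.56, 0.82) with the remainder split equally among the other
three bases, and default sample sizes of 1004 (−35) and 1046 (−10)
hexamers, matching the sizes of the curated collections the original
model was trained against. `synthetic_feature_table` generates
regression tables with known ground truth: by default n = 18, true
coefficients (−5.1046, 0.4271, 0.2726), residual sd 0.853 (the training
fit's residual scale), and features uniform over the observed score
ranges.

What the generator does **not** emulate: positional dependence between
bases (real promoter sets show correlated positions), the joint
distribution of −35/−10 scores in real promoters (they are weakly
anti-correlated in the training data, ≈ −0.37), spacer-length effects,
and any non-linearity in the sequence–strength map. Passing tests on
synthetic data therefore demonstrate correctness of the algorithms and
calibration of the inference under the stated model, not biological
validity on new promoter collections.

## Numerical choices and edge cases

* Sequences are uppercased on input; RNA (U) and IUPAC ambiguity codes
  are rejected rather than distributed over bases.
* Window-scan ties break to the smallest offset, making extraction
  deterministic.
* Predicted strengths above 1 (stronger than the reference promoter) are
  reported as-is, with an advisory note in the CLI.
* All random operations (hexamer generation, baseline draws, synthetic
  tables) take explicit integer seeds and are reproducible bit-for-bit.
* Problem sizes in the test suite (synthetic hexamer sets of 200–5000,
  200 parameter-recovery replicates, 100×100 baseline draws) were chosen
  to keep the full suite under a few seconds while leaving binomial/SE
  tolerances comfortably tight.

## Known limitations

* The model is trained on 18 promoters from one mutagenesis family;
  extrapolation beyond the observed score ranges is unreliable (the
  effect-confidence of each score degrades toward the edges of its
  training range).
* Only σ70 core promoters are addressed; other σ factors would need
  their own PWMs and training sets, though the machinery is generic.
* Spacer length between the elements, UP elements, and extended −10
  motifs are not modelled.
* The exact p-value machinery assumes a zeroth-order background; a
  Markov background would require a different convolution.
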