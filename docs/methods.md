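# Methods

This document records the statistical methodology implemented by
`activitycanyon` and the reasoning behind each modelling choice.  The
package treats the structure–activity landscape of a drug collection as a
weighted pair network and asks where the observed joint distribution of
chemical and biological pair weights departs from what independence of
structure and activity would predict.

## 1. Pair weights

Given a bipartite drug–target activity network and a symmetric chemical
similarity matrix, every unordered drug pair (i, j) receives three
weights:

* **c** — Tanimoto similarity of the two chemical structures,
  `|a ∩ b| / |a ∪ b|` for fingerprints a, b, with the empty/empty case
  defined as 0.  Values lie in [0, 1].
* **s** — number of common targets, `|A_i ∩ A_j|`.
* **d** — symmetric-difference count, `|A_i Δ A_j|`.

These satisfy the exact identity

```
d + 2 s = deg(i) + deg(j)
```

where `deg` is a drug's target count.  `build_pair_weights` carries the
degrees along in the pair table so the identity can be re-verified at any
point; the test suite checks it on hundreds of random networks.

Distinctive interactions — the pairs of interest — are those with *high*
chemical similarity but *divergent* activity: large d, or small s,
relative to the pairs in the same chemical-similarity region.

## 2. Marginal models and fitting

The marginal distributions are modelled as:

| axis | form | default parameter | support |
|------|------|-------------------|---------|
| c | power law, `P(c) ∝ c^(−γ)` | γ = 3.6 | c ≥ c_min = 0.004 |
| s | power law, `P(s) ∝ s^(−α)` | α = 2.37 | s ≥ s_min = 1 |
| d | exponential, `P(d) ∝ e^(−λd)` | λ = 0.17 | d ≥ d_min = 0 |

The defaults in `ModelConstants` describe large public drug–target
collections; for any concrete data set the parameters should be re-fitted.

Fitting is ordinary least squares on log-transformed empirical
frequencies (`fit_power_law`, `fit_exponential`), i.e. a straight line in
log–log (power law) or lin–log (exponential) coordinates, via
`scipy.stats.linregress`.  Two practical safeguards matter:

* **Sparse-tail exclusion.**  Log-frequency noise explodes where bins
  hold only a handful of observations.  `reliable_range(dist, min_count)`
  restricts the fit to the largest contiguous support prefix whose bins
  all hold at least `min_count` (default 10) observations.
* **Bin resolution for steep power laws.**  For continuous c the
  empirical pmf uses fixed-width bins and assigns each bin its midpoint.
  Near a small cutoff (c_min = 0.004) a steep power law varies strongly
  *within* a bin, so midpoints overestimate the typical abscissa and bias
  the slope: with 0.01-wide bins a γ = 3.6 sample fits to ≈ 4.0, while
  0.002-wide bins recover ≈ 3.62 at 10⁵ draws.  The package default
  (`DEFAULT_C_BIN_WIDTH = 0.01`) matches common practice for plotting;
  parameter-recovery work should use 0.002 or finer, as the acceptance
  script does.

A Hill-type maximum-likelihood estimator (`fit_power_law_mle`) is
provided as an independent cross-check of the OLS exponents.

## 3. Predicted joint probabilities

Under the null hypothesis that structure and activity are independent,
the probability of a pair falling in the rectangle
`[c1, c2] × [m1, m2]` (m being s or d) is a product of two closed-form
marginal integrals.  `predicted_prob_cs` / `predicted_prob_cd` evaluate
these analytically; the test suite validates them against numerical
quadrature of the density product to 1e-8 and against 10⁶-draw Monte
Carlo frequencies to three binomial standard errors.

Two modes are supported:

* **`normalized`** — every marginal integrates to one over its support.
  This is the statistically meaningful mode: full-range probabilities
  equal 1, and the joint factorizes exactly into marginal probabilities.
* **`paper_constants`** — reproduces a historical parameterization in
  which the d-axis antiderivative carries an empirical prefactor
  k_d = 0.042 in place of the normalizing constant λe^(λ·d_min); the
  full-range (c, d) mass then evaluates to k_d / λ ≈ 0.247 rather
  than 1.  On the (c, s) axis the historical formula is algebraically
  identical to the normalized integral, so the two modes agree there and
  the recorded prefactor k_s = 0.045 never enters the computation.

Because the `paper_constants` d-axis mass is not normalized, comparisons
with observed frequencies use a least-squares scale factor (below); this
also absorbs the mismatch between a *joint* prediction and a
*conditional* observation.

## 4. Threshold scans and goodness of fit

`scan_thresholds` compares observation and prediction over a grid of
exceedance thresholds `t(n) = μ + n·σ`, n = 0, 0.2, …, 9, where μ and σ
are the mean and (population) standard deviation of the measure within
the chemical region under study.  Thresholds are clamped to the support
minimum (e.g. `μ − nσ` cannot drop below s_min on the s axis).

* **Observed** probability is, by default, *conditional on the chemical
  region*: the fraction of region pairs exceeding the threshold.  This
  matches the convention of treating the chemical window as given
  (P(c-region) = 1) when studying the activity axis.
* **Predicted** probability is the joint model integral over
  `[c1, c2] × [t, ∞)`.

The two differ by the model's c-region mass (and, in `paper_constants`
mode, the non-unit d normalization), so predictions are rescaled by the
least-squares factor `f = Σ(pred·obs) / Σ(pred²)` before computing

```
RMSE = sqrt( Σ_j (f·pred_j − obs_j)² / (J − 1) )
```

with J grid points.  On ensembles drawn from the model's own marginals
the scaled RMSE is below 0.01 for both s and d, which is the
self-consistency bar used by the tests.  Note that for such
model-generated ensembles the study region must be (essentially) the full
support: the pure c marginal places only ~1.3e-5 of its mass above
c = 0.3, so a "transitional-region" scan on 10⁵ model pairs holds almost
no data.  Empirical networks, whose similarity distributions are flatter,
can be scanned on [0.3, 1.0] directly.

## 5. Hypothesis tests

`run_battery` executes six pre-registered tests of the proposition that
activity *divergence* (d) dominates activity *overlap* (s) as the source
of pair-weight variation:

1–3. **McNemar tests** (global, transitional and high-similarity
   regions): each pair is classified by whether s exceeds μ_s and whether
   d exceeds μ_d within the region; the discordant counts n2 (s-only) and
   n3 (d-only) feed the statistic `χ² = (n2 − n3)² / (n2 + n3)` and an
   **exact one-sided binomial tail** `P(X ≥ n3 | n2+n3, ½)`, computed by
   direct `math.comb` summation (no normal approximation), with the
   alternative "d-exceedance is more common".  Significance level 0.01.

4–5. **Paired t tests**: the exceedance-fraction vectors over the integer
   threshold grid n = 0…8 are compared between the transitional and
   high-similarity regions, separately for s and d, with
   `t = Δ̄ / (σ_Δ / √n)` on n − 1 degrees of freedom (the standard paired
   statistic; σ_Δ uses ddof = 1).  One-sided, level 0.05.

6. **McNemar in the high-similarity region** comparing the below-μ_s and
   above-μ_d distinctiveness criteria directly.

Degenerate situations (no discordant pairs, zero-variance differences,
empty regions) are reported as `degenerate` / `not_computable` entries
rather than raised, so one sparse region does not abort the battery.  No
multiple-comparison correction is applied: the six tests are reported
individually, as a battery of separately interpreted pre-registered
hypotheses, not as a family-wise decision.

## 6. Distinctiveness filtering

`filter_distinctive` extracts the sub-network of pairs in a chemical
region satisfying `d ≥ μ_d + n·σ_d` (divergent activity) or
`s ≤ μ_s − n·σ_s` (low overlap), with inclusive inequalities and the
below-threshold floored at 0.  Each retained edge is annotated with the
maximal integer level n it satisfies, so one pass yields the whole nested
family of networks.  `compare_filters` tabulates the two criteria and
their overlap across levels; `cross_magnitude_diagnostic` reports how
often above-average d values exceed the upper quartile of below-average s
values, a scale check on "d variation dominates s variation".

## 7. Synthetic ensembles

Two seeded generators support testing and calibration:

* **`pair_sampler`** draws c, s, d *independently* from the model
  marginals (truncated-Pareto inverse CDF for c; zero-inflated zipf for
  s, with P(s = 0) = 0.9; geometric for d).  This is the null-hypothesis
  world.  **The degree identity d + 2s = deg_i + deg_j is *not* enforced**
  — there are no degrees, and the columns are NaN — so these tables
  exercise the distribution machinery, not the network invariants.
* **`bipartite_graph`** builds an actual drug–target network with
  zipf-distributed drug degrees (resampled, then capped at the target
  count with a logged warning) and uniform or preferential target
  attachment, then derives s and d from the network.  All set identities
  hold by construction here.

`random_similarity_matrix` draws pairwise similarities from a truncated
power law; its default exponent is 1.8 (flatter than the c marginal's
3.6) so that small simulated networks still populate the high-similarity
regions that the filtering and testing machinery operates on.

## 8. Limitations

* OLS on log-frequencies is a pragmatic, transparent estimator but not
  efficient; the MLE cross-check mitigates, not removes, binning
  sensitivity for continuous power laws.
* The least-squares scaling step means the scan assesses the *shape* of
  the predicted exceedance curve, not its absolute level.
* The default constants describe one historical snapshot of public
  drug–target data; conclusions about any other data set require
  re-fitting.
* p-values from 10⁵-pair synthetic ensembles are effectively 0 and should
  be read as "direction confirmed", not as calibrated evidence strength.
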