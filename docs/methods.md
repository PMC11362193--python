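# Methods

This note documents the statistical model behind `mfindices`, the
parameter choices that matter, the design of the synthetic-data generator
and simulation study, and the package's numerical conventions and known
limitations.

## Model and standardization

The toolkit assumes two groups (males, females) whose trait vectors are
approximately multivariate normal with **equal covariance matrices**. All
index equations operate on standardized scores

    z_j = (x_j − midpoint_j) / s_j,

where `s_j` is the pooled within-sex SD of trait `j` (two-group pooling,
denominator `n_M + n_F − 2`) and `midpoint_j = (μ_M,j + μ_F,j)/2` is the
**unweighted** average of the sex means. Using the unweighted midpoint
rather than the grand mean keeps the zero point of every index at the
point equidistant between the centroids even when group sizes differ.
Constant traits are rejected; rows with missing values are dropped
complete-case (no imputation). Sex is coded male = 1 / female = 0
internally so that positive index values are masculine.

The multivariate effect summary consists of the Cohen's-d vector
`d_j = (μ_M,j − μ_F,j)/s_j` and the pooled within-sex correlation matrix
`R`, computed by centering each sex at its own mean, concatenating the
residuals, and correlating — equivalent to a degrees-of-freedom-weighted
pooling of the two within-sex covariance matrices.

When scoring new individuals, the standardization (pooled SDs, means,
midpoint) is **frozen** at fit time; the model object carries it, so
refitting on the new sample is possible but never implicit.

## The four indices

* **Sex-directionality** `M-F_D = zᵀd / ‖d‖`. Each trait contributes
  independently of its correlations with the others; ‖d‖ is the
  standardized Euclidean distance between centroids, and the 1/‖d‖
  normalizer puts M-F_D on a scale comparable to M-F_T.
* **Sex-typicality** `M-F_T = zᵀa / D_M`, with discriminant coefficients
  `a = R⁻¹d` and `D_M = √(dᵀR⁻¹d)`. The normalizer is chosen to satisfy
  the unit-variance contract: the pooled within-sex variance of the raw
  discriminant score `zᵀa` is `aᵀRa = dᵀR⁻¹d = D_M²`, so dividing by
  `D_M` makes the within-sex variance of M-F_T exactly 1. (The
  alternative normalizer `1/√(aᵀR⁻¹a)` sometimes seen in print does not
  have this property; the unit-variance contract is what the
  implementation honors, and the training-sample variance is unit-tested
  to 1 ± 1e−6.)
* **Sex-probability** `M-F_P = expit(zᵀa)`, the estimated probability of
  being male under **equal priors** (no prior option is exposed; with
  unequal priors the classification boundary would leave the centroid
  midpoint and the boundary-consistency properties below would no longer
  hold). Probabilities are saturated into the open interval (0, 1) at
  machine precision to guard downstream logits.
* **Sex-centrality** `M-F_C = [D_Mah(z, f) − D_Mah(z, m)] / D_M` with
  `m = d/2`, `f = −d/2` and the Mahalanobis metric `R⁻¹`. Scores of ±1
  mean "as male-/female-central as the corresponding centroid". In high
  dimensions most of the probability mass lies far from both centroids,
  so centrality scores compress and should be interpreted cautiously for
  large p.

Because M-F_P and M-F_C are monotone companions of M-F_T (exactly for the
LDA fit), all three always agree in sign; discordance is possible only
against M-F_D. A profile is flagged **discordant** on strict sign
disagreement between M-F_D and M-F_T; exact zeros lie on a boundary and
are counted as concordant (a measure-zero convention that only matters on
constructed data). With equal priors both boundaries pass through z = 0,
where all indices are 0 (and M-F_P = 0.5).

The **bias-corrected centroid distance** uses the standard unbiased
estimator of the squared Mahalanobis distance,

    D_Mu² = max(0, ((n − p − 3)/(n − 2)) · D_M² − p(1/n_M + 1/n_F)),

floored at zero; it converges to D_M as n grows.

### Logistic alternative

`method="logistic"` fits an unpenalized maximum-likelihood logistic
regression of sex on the standardized traits (statsmodels `Logit`). The
un-normalized linear predictor replaces `zᵀa`: M-F_P is its inverse
logit, and the M-F_T analogue is the predictor centered on the midpoint
of its two sex means and scaled to unit pooled within-sex variance (both
frozen at fit time). On multivariate-normal data the two methods agree
almost perfectly; logistic regression merely relaxes the normality
assumption. The exact sign identities above are guaranteed only for LDA.

### Numerical conventions

* The discriminant solve uses `np.linalg.solve`, with a hard error when
  the condition number of R exceeds 1e10 (the advice to the user is to
  aggregate or drop collinear traits, not silent ridge regularization).
* Distances are computed as quadratic forms via linear solves, never by
  explicit inversion.
* The summary figure is rendered deterministically (fixed SVG hash salt,
  no embedded timestamp), so repeated renders of identical scores are
  byte-identical.

## Measurement-error correction

Reliability `rel_j ∈ (0, 1]` is the true-score share of observed variance
(classical test theory). Error attenuates observed correlations by
`√(rel_i · rel_j)` and inflates within-sex spread by `1/√rel_j`; the
correction inverts both:

1. **Correlation disattenuation**: `r*_ij = r_ij / √(rel_i rel_j)`,
   clipped to [−1, 1]; if the result leaves the positive-semi-definite
   cone it is projected back (eigenvalues floored at 1e−8, diagonal
   renormalized).
2. **DMD-style data transform**: within-sex residuals, standardized by
   the observed pooled SD, are multiplied by `R_obs^(−1/2) R*^(1/2)`
   (symmetric square roots) and rescaled by `√rel_j`; sex means are left
   untouched in trait units. The corrected table then has pooled
   correlation exactly `R*`, within-sex variance equal to the true-score
   share, and standardized sex differences enlarged by `1/√rel_j` — the
   classical disattenuation of Cohen's d. Refitting the indices on the
   corrected table therefore raises D_M and sharpens the distinction
   between typicality and directionality.

The transform is deterministic, reduces to the identity under perfect
reliability, and achieves the correlation target to machine precision.
Richer per-observation disattenuation schemes exist; this whiten/recolor
construction was chosen for those exactness properties and is isolated
behind `dmd_transform` so it can be swapped.

**Caveats.** Correction trades bias for variance: disattenuated estimates
have larger sampling error, so it is best used at large n. Applying it to
data that were *not* noisy at the stated reliabilities overcorrects —
correlations get pushed past ±1, the PSD projection leaves a nearly
singular matrix, and D_M can explode. The reliabilities must describe
genuine measurement error in the data at hand. Reliabilities are inputs
(CSV column or JSON name→value map); the package does not estimate them
from item-level data.

## Synthetic data generator

`simulate_population` draws males from MVN(+d/2, R) and females from
MVN(−d/2, R) in standardized units with a deterministic sex split;
`add_measurement_error` adds independent homoscedastic Gaussian noise
with variance `(1 − rel)/rel` per trait, which makes the empirical
variance ratio equal the nominal reliability under the generator's
unit-variance contract.

Correlation matrices come from the **C-vine construction**: partial
correlations drawn as `2·Beta(β, β) − 1` and propagated to marginal
correlations layer by layer. At the study's β = 4 the mean absolute
off-diagonal correlation is in the .20–.25 range for p between 5 and 30
(checked over 100 draws); large β concentrates the matrix near identity.

What the generator deliberately does **not** emulate: non-normal or
skewed traits, unequal male/female covariance matrices, correlated or
sex-dependent measurement error, missing data, and sampling designs with
unequal group variances. Tests that pass on this generator therefore
certify the algebra and the error model, not robustness to those
real-data complications.

## Validity simulation design

`run_validity_experiment` runs, per replicate: draw R (vine) and a
Cohen's-d vector `d ~ N(0, d_sd²)`; simulate an error-free sample; fit
and score it (the "true" indices come from a model fitted on the
noiseless data of the same replicate, mirroring what an analyst would
have obtained with perfect measurement — not from population
parameters); then for each reliability level add noise, refit on the
observed data, and record per index the validity
`corr(true score, observed score)`, plus the observed r(M-F_D, M-F_T),
its within-sex partial version, the phi coefficient between true and
observed concordance classifications, and the realized D_M. The d vector
is redrawn every replicate so the boxplot spread propagates design
uncertainty, not just sampling noise.

Study conditions follow the reference design: 50 % females, vine β = 4,
reliabilities .50–.99, and `d_sd` tied to trait count (0.70 for p = 5,
0.50 for p = 10, 0.05 for p = 30), which makes the average true centroid
separation grow from about 2 to about 4 with dimensionality. The default
profile is scaled down to 20 replicates of N = 1000 — enough for stable
medians of every reported quantity in a few seconds — with the full-scale
profile (100 replicates of N = 2000) available via `--full-scale`.
Replicates whose refit fails (singular observed correlation) are skipped
and counted; all seeds derive from a single `SeedSequence`, so identical
configurations reproduce results exactly.

The qualitative findings this package's tests pin down: every index's
validity is non-increasing in error; directionality (which does not touch
R) is the most robust, and the gap to typicality/centrality widens with
p; noisy indices become mutually redundant (observed r(M-F_D, M-F_T)
rises toward 1 as reliability falls); concordance classification decays
steeply and is imperfect even at reliability .90; and DMD-style
correction with the true reliabilities raises D_M and all validities
while moving the within-sex r(M-F_D, M-F_T) back toward its true-score
value.

## Limitations

* Exactly two sex categories; no ordinal or categorical traits.
* Linear discriminants only (no nonlinear or ensemble classifiers for
  the probability index).
* Reliability-based correction requires externally supplied reliability
  estimates and assumes classical (independent, homoscedastic) error.
* Sex-centrality loses interpretability in high-dimensional trait spaces
  (distance concentration); it is computed but should be read with care
  for large p.
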