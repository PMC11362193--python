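# mfindices

Statistical masculinity–femininity (M-F) indices from multivariate trait
profiles with binary sex labels.

Researchers studying sex differences — in body morphology, brain structure,
personality, vocational interests — often summarize a person's multivariate
trait profile as a single position on a masculine–feminine continuum. There
is more than one defensible way to do that, and the alternatives can
disagree: the same profile can be *female*-shifted on average traits yet
statistically *male*-typical as a combination. `mfindices` computes four
complementary indices, flags such discordant profiles, corrects the input
data for measurement error, and quantifies (by Monte-Carlo simulation) how
unreliable measurement degrades each index.

## The indices

All scores live in a common z-space: traits standardized by the pooled
within-sex SD and centered on the unweighted mean of the male and female
centroids. With **z** the standardized profile, **d** the vector of
per-trait Cohen's *d* values (positive = higher male mean), and **R** the
pooled within-sex correlation matrix:

| index | formula | meaning |
|---|---|---|
| sex-directionality M-F_D | **z**ᵀ**d** / ‖**d**‖ | projection on the centroid axis; each trait weighted by its univariate sex difference |
| sex-typicality M-F_T | **z**ᵀ**a** / D_M, **a** = **R**⁻¹**d** | projection on the linear discriminant axis, scaled to unit within-sex variance |
| sex-probability M-F_P | exp(**z**ᵀ**a**) / (1 + exp(**z**ᵀ**a**)) | probability of being male under equal priors |
| sex-centrality M-F_C | [D_Mah(**z**, **f**) − D_Mah(**z**, **m**)] / D_M | relative closeness to the male vs. female centroid in the Mahalanobis metric |

Here D_M = √(**d**ᵀ**R**⁻¹**d**) is the Mahalanobis distance between the
sex centroids (a bias-corrected D_Mu is also reported), and **m** = **d**/2,
**f** = −**d**/2 are the centroids in z-space. Positive scores are
masculine by convention. A profile is **discordant** when M-F_D and M-F_T
disagree in sign.

Given per-trait reliabilities, the toolkit also applies a DMD-style
(data-matrix disattenuation) correction: trait correlations are
disattenuated (r / √(rel_i·rel_j)) and the data are transformed so their
pooled correlation matches that target exactly, restoring the true-score
structure before indices are fitted.

## Worked example

Score a CSV of trait profiles (one sex column, remaining columns numeric):

```sh
mfindices compute profiles.csv --sex-column sex \
    --scores-out scores.csv --summary-out summary.json --plot-out summary.png
```

On a simulated five-trait sample of 400 people this prints

```
n = 200 M / 200 F, p = 5; D_M = 2.027 (D_Mu = 1.999); 21.5% discordant; r_p(M-F_D, M-F_T) = 0.631
```

meaning: the male and female centroids are separated by about two pooled
SDs along the discriminant (the small-sample-corrected value is nearly
identical at this n); 21.5 % of profiles are male-directional but
female-typical or vice versa; and within sex, directionality and
typicality correlate .63 — related but clearly distinct constructs. The
figure written to `summary.png` shows per-sex densities of each index,
pairwise scatterplots with the discordant regions shaded, and the r / r_p
correlations among the indices.

The same pipeline is available in Python:

```python
from mfindices import read_profile_table, fit_mf_model, score_profiles, summarize_indices

profiles = read_profile_table("profiles.csv", sex_column="sex")
model = fit_mf_model(profiles)            # or method="logistic"
scores = score_profiles(model, profiles)  # mfd, mft, mfp, mfc, discordant
summary = summarize_indices(scores, model)
```

The Monte-Carlo harness measures index *validity* — the correlation
between indices computed on noisy traits and on the same traits measured
without error:

```sh
mfindices simulate --p 5 --n 400 --reps 3 --d-sd 0.7 --seed 2 --out-dir sim/
```

```
median validity by reliability:
             validity_mfd  validity_mft  validity_mfp  validity_mfc
reliability
0.50                0.801         0.739         0.741         0.707
0.70                0.901         0.859         0.859         0.834
0.90                0.973         0.949         0.950         0.934
0.99                0.997         0.995         0.995         0.992
```

Noise hurts every index, but sex-directionality — which ignores trait
correlations — degrades least; the gap widens sharply with more traits.

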