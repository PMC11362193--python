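"""The four masculinity-femininity indices and their fitted scoring model.

Given a standardized profile z, a Cohen's-d vector d, and the pooled
within-sex correlation matrix R, the indices are

* sex-directionality  M-F_D = z' d / ||d||          (projection on the
  centroid axis, each trait weighted by its univariate sex difference);
* sex-typicality      M-F_T = z' a / D_M with a = R^-1 d (projection on the
  linear discriminant axis, normalized to unit pooled within-sex variance);
* sex-probability     M-F_P = expit(z' a)           (estimated probability
  of being male under equal priors);
* sex-centrality      M-F_C = [D_Mah(z, f) - D_Mah(z, m)] / D_Mah(m, f)
  (normalized difference of Mahalanobis distances to the two centroids,
  with m = d/2, f = -d/2 in z-space).

D_M = sqrt(d' R^-1 d) is the Mahalanobis distance between the sex
centroids; D_Mu is its small-sample bias-corrected counterpart. Positive
scores are masculine by convention. A profile is *discordant* when its
directionality and typicality scores disagree in sign (e.g.
female-directional but male-typical).

Note on the typicality normalizer: the pooled within-sex variance of the
raw discriminant score z'a equals a'Ra = d'R^-1 d = D_M^2, so dividing by
D_M — not by sqrt(a' R^-1 a) — is what makes the within-sex variance of
M-F_T exactly 1. This implementation divides by D_M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import (
    EffectSummary,
    ProfileTable,
    StandardizationModel,
    DataError,
    effect_summary,
    standardize,
)

#: Condition-number ceiling beyond which R is treated as singular.
MAX_CONDITION_NUMBER = 1e10


class SingularCorrelationError(DataError):
    """Pooled correlation matrix is singular or numerically near-singular."""


@dataclass
class MFModel:
    """Fitted scoring model: standardization, effect summary, discriminant.

    Attributes
    ----------
    a : (p,) ndarray
        Discriminant coefficients, ``a = R^-1 d`` for the LDA method.
    D_M, D_Mu : float
        Mahalanobis distance between sex centroids and its bias-corrected
        counterpart.
    method : {"lda", "logistic"}
    logistic_coefficients : (p + 1,) ndarray or None
        Intercept-first maximum-likelihood coefficients of sex on the
        standardized traits (present iff ``method == "logistic"``).
    """

    std: StandardizationModel
    eff: EffectSummary
    a: np.ndarray
    D_M: float
    D_Mu: float
    method: str
    logistic_coefficients: np.ndarray | None = None
    # frozen normalization of the logistic typicality analogue
    _logistic_center: float = 0.0
    _logistic_scale: float = 1.0

    @property
    def p(self) -> int:
        return self.eff.p


@dataclass
class MFScoreTable:
    """Per-individual scores on the four indices plus the concordance flag."""

    mfd: np.ndarray
    mft: np.ndarray
    mfp: np.ndarray
    mfc: np.ndarray
    discordant: np.ndarray
    sex: np.ndarray
    ids: np.ndarray | None = None

    INDEX_NAMES = ("mfd", "mft", "mfp", "mfc")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sex": self.sex,
                "mfd": self.mfd,
                "mft": self.mft,
                "mfp": self.mfp,
                "mfc": self.mfc,
                "discordant": self.discordant,
            }
        )
        if self.ids is not None:
            df.insert(0, "id", self.ids)
        return df


def _solve_discriminant(R: np.ndarray, d: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        raise SingularCorrelationError(
            f"pooled within-sex correlation matrix is near-singular "
            f"(condition number {cond:.3g} > {MAX_CONDITION_NUMBER:.0e}); "
            "reduce or aggregate collinear traits before fitting"
        )
    return np.linalg.solve(R, d)


def mahalanobis_centroid_distance(eff: EffectSummary) -> tuple[float, float]:
    """Mahalanobis distance between centroids, plain and bias-corrected.

    ``D_M = sqrt(d' R^-1 d)``. The bias-corrected version rescales the
    squared distance by its degrees of freedom and subtracts the expected
    sampling inflation, floored at zero:

    ``D_Mu^2 = max(0, ((n - p - 3) / (n - 2)) D_M^2 - p (1/n_M + 1/n_F))``.
    """
    a = _solve_discriminant(eff.R, eff.d)
    dm2 = float(eff.d @ a)
    D_M = float(np.sqrt(max(dm2, 0.0)))
    n = eff.n_male + eff.n_female
    p = eff.p
    corrected = ((n - p - 3) / (n - 2)) * dm2 - p * (
        1.0 / eff.n_male + 1.0 / eff.n_female
    )
    D_Mu = float(np.sqrt(max(corrected, 0.0)))
    return D_M, D_Mu


def fit_mf_model(profiles: ProfileTable, method: str = "lda") -> MFModel:
    """Fit the scoring model on a training sample.

    ``method="lda"`` solves ``R a = d`` for the discriminant coefficients;
    ``method="logistic"`` additionally fits an (unpenalized)
    maximum-likelihood logistic regression of sex on the standardized
    traits, whose linear predictor replaces the discriminant score.
    """
    if method not in ("lda", "logistic"):
        raise ValueError(f"unknown method {method!r}; use 'lda' or 'logistic'")
    std, z = standardize(profiles)
    eff = effect_summary(profiles, std)
    a = _solve_discriminant(eff.R, eff.d)
    D_M, D_Mu = mahalanobis_centroid_distance(eff)
    model = MFModel(std=std, eff=eff, a=a, D_M=D_M, D_Mu=D_Mu, method=method)
    if method == "logistic":
        import statsmodels.api as sm

        X = sm.add_constant(z)
        fit = sm.Logit(profiles.sex, X).fit(disp=False)
        model.logistic_coefficients = np.asarray(fit.params, dtype=float)
        eta = X @ model.logistic_coefficients
        center, scale = _midpoint_and_pooled_sd(eta, profiles.sex)
        model._logistic_center = center
        model._logistic_scale = scale
    return model


def _midpoint_and_pooled_sd(
    scores: np.ndarray, sex: np.ndarray
) -> tuple[float, float]:
    m = scores[sex == 1]
    f = scores[sex == 0]
    center = (m.mean() + f.mean()) / 2.0
    ss = np.sum((m - m.mean()) ** 2) + np.sum((f - f.mean()) ** 2)
    return float(center), float(np.sqrt(ss / (len(scores) - 2)))


def mfd_scores(z_table: np.ndarray, eff: EffectSummary) -> np.ndarray:
    """Sex-directionality: projection on the centroid axis, z'd / ||d||."""
    if eff.d_norm <= 0:
        raise DataError(
            "Cohen's d vector is zero: there is no dimorphism axis to "
            "project on"
        )
    return np.atleast_2d(z_table) @ eff.d / eff.d_norm


def _raw_discriminant(z_table: np.ndarray, model: MFModel) -> np.ndarray:
    """Un-normalized score whose logistic transform is the sex-probability."""
    z = np.atleast_2d(z_table)
    if model.method == "logistic":
        beta = model.logistic_coefficients
        return beta[0] + z @ beta[1:]
    return z @ model.a


def mft_scores(z_table: np.ndarray, model: MFModel) -> np.ndarray:
    """Sex-typicality: discriminant projection with unit within-sex variance.

    For LDA the normalizer is ``D_M`` (the pooled within-sex SD of ``z'a``);
    for the logistic method the linear predictor is centered on the
    midpoint of the two sex means and rescaled to unit pooled within-sex
    variance, both frozen at fit time.
    """
    if model.method == "logistic":
        eta = _raw_discriminant(z_table, model)
        if model._logistic_scale <= 0:
            raise DataError("degenerate logistic predictor (zero variance)")
        return (eta - model._logistic_center) / model._logistic_scale
    if model.D_M <= 0:
        raise DataError(
            "Mahalanobis distance between centroids is zero; typicality "
            "scores are undefined"
        )
    return np.atleast_2d(z_table) @ model.a / model.D_M


def mfp_scores(z_table: np.ndarray, model: MFModel) -> np.ndarray:
    """Sex-probability: inverse-logit of the un-normalized discriminant score.

    Assumes equal prior probabilities of being male versus female. Output
    is saturated to the open interval (0, 1) at machine precision.
    """
    p = expit(_raw_discriminant(z_table, model))
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)


def _mahalanobis_to_point(
    z: np.ndarray, center: np.ndarray, R: np.ndarray
) -> np.ndarray:
    diff = np.atleast_2d(z) - center
    sol = np.linalg.solve(R, diff.T)
    return np.sqrt(np.einsum("ij,ji->i", diff, sol))


def mfc_scores(z_table: np.ndarray, model: MFModel) -> np.ndarray:
    """Sex-centrality: normalized Mahalanobis-distance difference.

    ``(D_Mah(z, f) - D_Mah(z, m)) / D_Mah(m, f)`` with the male/female
    centroids at ``+d/2`` / ``-d/2``. +1 means as male-central as the male
    centroid; -1 as female-central as the female centroid; 0 lies on the
    classification boundary.
    """
    if model.D_M <= 0:
        raise DataError(
            "Mahalanobis distance between centroids is zero; centrality "
            "scores are undefined"
        )
    m, f = model.eff.centroids()
    dist_f = _mahalanobis_to_point(z_table, f, model.eff.R)
    dist_m = _mahalanobis_to_point(z_table, m, model.eff.R)
    return (dist_f - dist_m) / model.D_M


def classify_concordance(
    mfd: np.ndarray, mft: np.ndarray
) -> tuple[np.ndarray, float]:
    """Flag profiles whose directionality and typicality disagree in sign.

    Exact zeros sit on a boundary (neither masculine nor feminine) and are
    treated as concordant. Returns the per-profile flags and the overall
    discordant fraction.
    """
    mfd = np.asarray(mfd, dtype=float)
    mft = np.asarray(mft, dtype=float)
    if mfd.shape != mft.shape:
        raise ValueError("score vectors must have equal length")
    flags = np.sign(mfd) * np.sign(mft) < 0
    return flags, float(np.mean(flags))


def axis_angle(eff: EffectSummary, model: MFModel) -> float:
    """Angle in degrees between the centroid axis d and discriminant axis a.

    Zero when R is the identity (a = d); widens as trait correlations pull
    the discriminant away from the centroid axis, enlarging the discordant
    regions.
    """
    if model.method != "lda":
        raise ValueError("axis_angle is defined for the LDA discriminant")
    nd, na = np.linalg.norm(eff.d), np.linalg.norm(model.a)
    if nd <= 0 or na <= 0:
        raise DataError("zero-length axis; angle undefined")
    cos = float(np.clip(eff.d @ model.a / (nd * na), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def score_profiles(
    model: MFModel,
    profiles: ProfileTable | None = None,
    z_table: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    ids: np.ndarray | None = None,
) -> MFScoreTable:
    """Compute all four indices (plus concordance flags) with a fitted model.

    Pass either a ProfileTable (standardized through the model's frozen
    StandardizationModel) or an already-standardized z-table.
    """
    if (profiles is None) == (z_table is None):
        raise ValueError("pass exactly one of profiles or z_table")
    if profiles is not None:
        z_table = model.std.transform(profiles.values)
        sex = profiles.sex
        ids = profiles.ids
    mfd = mfd_scores(z_table, model.eff)
    mft = mft_scores(z_table, model)
    mfp = mfp_scores(z_table, model)
    mfc = mfc_scores(z_table, model)
    discordant, _ = classify_concordance(mfd, mft)
    if sex is None:
        sex = np.full(len(mfd), -1)
    return MFScoreTable(
        mfd=mfd, mft=mft, mfp=mfp, mfc=mfc,
        discordant=discordant, sex=np.asarray(sex), ids=ids,
    )


def _partial_corr_given_binary(
    x: np.ndarray, y: np.ndarray, s: np.ndarray
) -> float:
    """First-order partial correlation of x and y controlling for s."""
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xs = np.corrcoef(x, s)[0, 1]
    r_ys = np.corrcoef(y, s)[0, 1]
    denom2 = (1 - r_xs**2) * (1 - r_ys**2)
    if denom2 <= 0:
        # a score is perfectly collinear with sex: within-sex association
        # is undefined
        return float("nan")
    return float((r_xy - r_xs * r_ys) / np.sqrt(denom2))


def summarize_indices(
    scores: MFScoreTable, model: MFModel | None = None
) -> dict:
    """Summary record: correlations among indices, r_p controlling for sex,
    percent discordant, per-sex moments, and (if a model is given) D_M, D_Mu.

    Full-sample Pearson correlations ``r`` are confounded with the overall
    size of the sex difference; the partial correlations ``r_p`` remove the
    binary sex indicator and describe the within-sex association.
    """
    names = list(MFScoreTable.INDEX_NAMES)
    mat = np.column_stack([getattr(scores, k) for k in names])
    variances = mat.var(axis=0)
    if np.any(variances <= 0):
        flat = [names[j] for j in np.flatnonzero(variances <= 0)]
        raise DataError(
            f"index score(s) {flat} have zero variance; correlations are "
            "undefined"
        )
    s = scores.sex.astype(float)
    k = len(names)
    r = np.eye(k)
    r_p = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = np.corrcoef(mat[:, i], mat[:, j])[0, 1]
            r_p[i, j] = r_p[j, i] = _partial_corr_given_binary(
                mat[:, i], mat[:, j], s
            )
    per_sex = {}
    for label, code in (("male", 1), ("female", 0)):
        sub = mat[scores.sex == code]
        per_sex[label] = {
            "mean": dict(zip(names, sub.mean(axis=0))),
            "sd": dict(zip(names, sub.std(axis=0, ddof=1))),
        }
    out = {
        "n_male": int(np.sum(scores.sex == 1)),
        "n_female": int(np.sum(scores.sex == 0)),
        "percent_discordant": float(100.0 * np.mean(scores.discordant)),
        "r": pd.DataFrame(r, index=names, columns=names),
        "r_p": pd.DataFrame(r_p, index=names, columns=names),
        "per_sex": per_sex,
    }
    if model is not None:
        out.update(
            p=model.p, D_M=model.D_M, D_Mu=model.D_Mu, method=model.method
        )
    return out
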