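"""Reliability-based correction of trait data before index computation.

Measurement error attenuates trait correlations toward zero and inflates
within-sex spread, which shrinks standardized sex differences. Given
per-trait reliabilities (the true-score fraction of observed variance,
classical test theory), this module

1. disattenuates the pooled within-sex correlation matrix
   (``r*_ij = r_ij / sqrt(rel_i rel_j)``), with clipping and a
   positive-semi-definite repair when the raw correction overshoots; and
2. applies a DMD-style (data matrix disattenuation) transform to the data
   themselves: within-sex residuals are whitened with the observed pooled
   correlation and recolored with the disattenuated target, so the
   corrected sample correlation matches the target to machine precision,
   while the within-sex spread of each trait is rescaled by sqrt(rel) and
   sex-mean differences are left untouched in trait units. Standardized
   Cohen's d values therefore grow by 1/sqrt(rel), the classical
   disattenuation of d.

The transform is a deterministic whiten/recolor construction built from
symmetric matrix square roots; the correction literature contains richer
per-observation schemes, but this one exactly achieves the disattenuated
correlation target and reduces to the identity under perfect reliability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    ProfileTable,
    DataError,
    _within_sex_residuals,
)

logger = logging.getLogger(__name__)

#: Eigenvalue floor used in the positive-semi-definite repair.
PSD_EIGENVALUE_FLOOR = 1e-8


@dataclass
class ReliabilityVector:
    """Per-trait reliabilities, each in (0, 1]."""

    rel: np.ndarray

    def __post_init__(self) -> None:
        self.rel = np.asarray(self.rel, dtype=float).ravel()
        if self.rel.size == 0:
            raise DataError("reliability vector is empty")
        if np.any(self.rel <= 0) or np.any(self.rel > 1):
            raise DataError(
                "reliabilities must lie in (0, 1]; got "
                f"{self.rel.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.rel)


def read_reliabilities(path, trait_names: list[str] | None = None) -> ReliabilityVector:
    """Load reliabilities from a single-column CSV or a JSON name->value map.

    With a JSON map and ``trait_names`` given, values are reordered to match
    the trait order; missing traits are rejected.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            mapping = json.load(fh)
        if not isinstance(mapping, dict):
            raise DataError("JSON reliability file must be a name->value map")
        if trait_names is not None:
            missing = [t for t in trait_names if t not in mapping]
            if missing:
                raise DataError(
                    f"reliability file lacks entries for trait(s) {missing}"
                )
            values = [mapping[t] for t in trait_names]
        else:
            values = list(mapping.values())
        return ReliabilityVector(np.asarray(values, dtype=float))
    col = pd.read_csv(path).iloc[:, -1].to_numpy(dtype=float)
    return ReliabilityVector(col)


def nearest_psd_correlation(
    R: np.ndarray, floor: float = PSD_EIGENVALUE_FLOOR
) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``floor``, the matrix is reconstructed, and
    the diagonal renormalized to 1.
    """
    sym = (R + R.T) / 2.0
    w, V = np.linalg.eigh(sym)
    fixed = (V * np.maximum(w, floor)) @ V.T
    scale = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(scale, scale)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def disattenuate_correlation(
    R_obs: np.ndarray, rel: ReliabilityVector
) -> np.ndarray:
    """Correct an observed correlation matrix for measurement attenuation.

    Off-diagonal entries become ``r_ij / sqrt(rel_i rel_j)`` (clipped to
    [-1, 1]); the diagonal stays at 1; the result is projected to the
    nearest positive-semi-definite correlation matrix when the raw
    correction leaves that cone.
    """
    R_obs = np.asarray(R_obs, dtype=float)
    if R_obs.shape[0] != len(rel):
        raise DataError(
            f"reliability vector length {len(rel)} does not match the "
            f"{R_obs.shape[0]} traits of the correlation matrix"
        )
    scale = np.sqrt(np.outer(rel.rel, rel.rel))
    R_star = np.clip(R_obs / scale, -1.0, 1.0)
    np.fill_diagonal(R_star, 1.0)
    if np.linalg.eigvalsh((R_star + R_star.T) / 2.0).min() < PSD_EIGENVALUE_FLOOR:
        logger.info(
            "disattenuated correlation matrix left the PSD cone; projecting"
        )
        R_star = nearest_psd_correlation(R_star)
    return R_star


def _sqrt_psd(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    w = np.maximum(w, 0.0)
    return (V * np.sqrt(w)) @ V.T


def _inv_sqrt_pd(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    if w.min() <= PSD_EIGENVALUE_FLOOR:
        raise DataError(
            "observed pooled correlation matrix is numerically singular; "
            "cannot whiten the data for disattenuation"
        )
    return (V / np.sqrt(w)) @ V.T


def dmd_transform(
    z_obs: np.ndarray,
    sex: np.ndarray,
    rel: ReliabilityVector,
) -> np.ndarray:
    """DMD-style correction of a standardized data table.

    ``z_obs`` is an N x p table in the pooled-within-sex z-space (unit
    pooled variance per trait); ``sex`` gives the binary group labels that
    define the pooled structure. The within-sex residuals are transformed
    by ``R_obs^(-1/2) R*^(1/2)`` and then rescaled by ``sqrt(rel)`` per
    trait, so the corrected table has pooled correlation exactly equal to
    the disattenuated target ``R*`` and pooled within-sex variance equal
    to ``rel`` (the true-score share), while within-sex means — hence raw
    mean sex differences — are preserved.
    """
    z_obs = np.asarray(z_obs, dtype=float)
    n, p = z_obs.shape
    if p != len(rel):
        raise DataError(
            f"reliability vector length {len(rel)} does not match trait "
            f"count {p}"
        )
    if n <= p:
        logger.warning(
            "N (%d) <= p (%d): the observed correlation is poorly "
            "estimated; correction may be unstable", n, p,
        )
    sex = np.asarray(sex)
    means = np.zeros((n, p))
    resid = z_obs.copy()
    for code in np.unique(sex):
        mask = sex == code
        mu = z_obs[mask].mean(axis=0)
        means[mask] = mu
        resid[mask] -= mu
    S_obs = resid.T @ resid / (n - 2)
    sd = np.sqrt(np.diag(S_obs))
    R_obs = S_obs / np.outer(sd, sd)
    np.fill_diagonal(R_obs, 1.0)
    R_star = disattenuate_correlation(R_obs, rel)
    transform = _inv_sqrt_pd(R_obs) @ _sqrt_psd(R_star)
    corrected = (resid / sd) @ transform * np.sqrt(rel.rel)
    return corrected + means


def correct_profile_table(
    profiles: ProfileTable, rel: ReliabilityVector
) -> ProfileTable:
    """Apply the DMD-style correction in original trait units.

    Within-sex residuals (standardized by the observed pooled SD) are
    whitened/recolored to the disattenuated correlation and shrunk by
    ``sqrt(rel)``; sex means stay where they are. Re-fitting the indices on
    the returned table therefore uses the corrected correlation matrix and
    the disattenuated (larger) standardized sex differences.
    """
    if profiles.p != len(rel):
        raise DataError(
            f"reliability vector length {len(rel)} does not match the "
            f"{profiles.p} traits of the profile table"
        )
    resid = _within_sex_residuals(profiles)
    sd = np.sqrt(np.sum(resid**2, axis=0) / (profiles.n - 2))
    if np.any(sd <= 0):
        raise DataError("constant trait(s): cannot correct")
    z = profiles.values / sd  # shift-free scaling; means handled inside
    corrected = dmd_transform(z, profiles.sex, rel) * sd
    return ProfileTable(
        values=corrected,
        sex=profiles.sex.copy(),
        trait_names=list(profiles.trait_names),
        ids=None if profiles.ids is None else np.asarray(profiles.ids),
    )
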