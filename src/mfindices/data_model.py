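"""Input structures, standardization, and sex-difference summaries.

All masculinity-femininity indices operate in a common z-space: each trait
is standardized by its pooled within-sex standard deviation and centered on
the unweighted mean of the male and female centroids (the midpoint of the
two group means, NOT the grand mean, which differs when group sizes are
unequal). This module builds that z-space and the multivariate effect-size
summary (Cohen's d vector and pooled within-sex correlation matrix) that
every index consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal sex coding: positive index scores are masculine by convention.
MALE = 1
FEMALE = 0


class DataError(ValueError):
    """Raised when input data violate the contracts of the toolkit."""


@dataclass
class ProfileTable:
    """A rectangular table of N individuals by p numeric traits plus sex labels.

    Parameters
    ----------
    values : (N, p) ndarray
        Trait scores in arbitrary (possibly heterogeneous) units.
    sex : (N,) ndarray of int
        Binary sex labels, ``1`` = male, ``0`` = female.
    trait_names : list of str
        Names of the p trait columns.
    ids : (N,) array-like, optional
        Per-individual identifiers, carried through to score output.
    """

    values: np.ndarray
    sex: np.ndarray
    trait_names: list[str] = field(default_factory=list)
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("trait values must form a 2-D (N x p) matrix")
        self.sex = np.asarray(self.sex)
        if not self.trait_names:
            self.trait_names = [f"trait_{j + 1}" for j in range(self.values.shape[1])]
        self._validate()

    def _validate(self) -> None:
        n, p = self.values.shape
        if p < 1:
            raise DataError("at least one trait column is required")
        if len(self.trait_names) != p:
            raise DataError("trait_names length does not match trait count")
        if self.sex.shape != (n,):
            raise DataError("sex labels must match the number of rows")
        labels = np.unique(self.sex)
        if not np.array_equal(np.sort(labels), [FEMALE, MALE]):
            raise DataError(
                f"sex must contain exactly the two codes {FEMALE} (female) and "
                f"{MALE} (male); got {labels.tolist()}"
            )
        if n < 4:
            raise DataError("at least 4 individuals are required")
        if self.n_male < 2 or self.n_female < 2:
            raise DataError(
                "at least 2 individuals per sex are required to estimate "
                "pooled within-sex SDs"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("trait values contain missing or non-finite entries")
        if self.ids is not None and len(self.ids) != n:
            raise DataError("ids length does not match the number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def n_male(self) -> int:
        return int(np.sum(self.sex == MALE))

    @property
    def n_female(self) -> int:
        return int(np.sum(self.sex == FEMALE))

    def male_values(self) -> np.ndarray:
        return self.values[self.sex == MALE]

    def female_values(self) -> np.ndarray:
        return self.values[self.sex == FEMALE]


@dataclass
class StandardizationModel:
    """Frozen per-trait standardization: pooled SDs, sex means, and midpoint.

    ``midpoint`` is the unweighted average of the male and female mean
    vectors. The z-space transform is ``(x - midpoint) / pooled_sd``.
    """

    pooled_sd: np.ndarray
    mean_male: np.ndarray
    mean_female: np.ndarray
    midpoint: np.ndarray
    trait_names: list[str]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Map raw trait values into the frozen z-space."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return (values - self.midpoint) / self.pooled_sd


@dataclass
class EffectSummary:
    """Multivariate sex-difference summary in z-space.

    ``d`` holds per-trait Cohen's d values (positive = higher male mean);
    ``R`` is the pooled within-sex correlation matrix; ``d_norm`` is the
    Euclidean norm of ``d``, i.e. the standardized Euclidean distance
    between the male and female centroids.
    """

    d: np.ndarray
    d_norm: float
    R: np.ndarray
    n_male: int
    n_female: int

    @property
    def p(self) -> int:
        return len(self.d)

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Male and female centroids in z-space, ``(+d/2, -d/2)``."""
        return self.d / 2.0, -self.d / 2.0


def _within_sex_residuals(profiles: ProfileTable) -> np.ndarray:
    """Rows centered at their own sex mean, in original trait units."""
    resid = profiles.values.copy()
    for code in (MALE, FEMALE):
        mask = profiles.sex == code
        resid[mask] -= resid[mask].mean(axis=0)
    return resid


def pooled_within_sex_sd(profiles: ProfileTable) -> np.ndarray:
    """Two-group pooled SD per trait, denominator ``n_M + n_F - 2``."""
    resid = _within_sex_residuals(profiles)
    ss = np.sum(resid**2, axis=0)
    return np.sqrt(ss / (profiles.n - 2))


def standardize(profiles: ProfileTable) -> tuple[StandardizationModel, np.ndarray]:
    """Standardize traits by pooled within-sex SD, centered on the midpoint.

    Returns the frozen :class:`StandardizationModel` and the N x p z-table.
    Constant traits (pooled SD of zero) are rejected by name.
    """
    mean_m = profiles.male_values().mean(axis=0)
    mean_f = profiles.female_values().mean(axis=0)
    midpoint = (mean_m + mean_f) / 2.0
    sd = pooled_within_sex_sd(profiles)
    degenerate = np.flatnonzero(sd <= 0)
    if degenerate.size:
        names = [profiles.trait_names[j] for j in degenerate]
        raise DataError(
            f"trait(s) {names} are constant within both sexes (pooled SD = 0) "
            "and cannot be standardized; remove them"
        )
    model = StandardizationModel(
        pooled_sd=sd,
        mean_male=mean_m,
        mean_female=mean_f,
        midpoint=midpoint,
        trait_names=list(profiles.trait_names),
    )
    return model, model.transform(profiles.values)


def pooled_within_sex_correlation(profiles: ProfileTable) -> np.ndarray:
    """Correlation of within-sex-centered data pooled across the sexes.

    Centering each sex at its own mean and concatenating the residuals is
    equivalent to weighting the within-sex covariance matrices by their
    degrees of freedom.
    """
    if profiles.p == 1:
        return np.ones((1, 1))
    resid = _within_sex_residuals(profiles)
    cov = resid.T @ resid / (profiles.n - 2)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr


def effect_summary(
    profiles: ProfileTable, std: StandardizationModel
) -> EffectSummary:
    """Cohen's d vector and pooled within-sex correlation matrix.

    ``d[j] = (mean_male[j] - mean_female[j]) / pooled_sd[j]``.
    """
    d = (std.mean_male - std.mean_female) / std.pooled_sd
    R = pooled_within_sex_correlation(profiles)
    return EffectSummary(
        d=d,
        d_norm=float(np.linalg.norm(d)),
        R=R,
        n_male=profiles.n_male,
        n_female=profiles.n_female,
    )


def read_profile_table(
    path,
    sex_column: str,
    male_label: str = "M",
    female_label: str = "F",
    trait_columns: list[str] | None = None,
    id_column: str | None = None,
    delimiter: str | None = None,
) -> ProfileTable:
    """Read a delimited text file (CSV/TSV with header) into a ProfileTable.

    Trait columns are coerced to numeric (a column that fails coercion is
    rejected by name); rows with any missing value are dropped complete-case
    with a logged count; sex labels are mapped per the configured
    ``male_label`` / ``female_label``.
    """
    if delimiter is None:
        import csv

        with open(path, newline="") as fh:
            sample = fh.read(64 * 1024)
        try:
            delimiter = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
        except csv.Error:
            delimiter = ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if sex_column not in df.columns:
        raise DataError(f"sex column {sex_column!r} not found in {path}")
    if trait_columns is None:
        trait_columns = [
            c for c in df.columns if c not in (sex_column, id_column)
        ]
    missing_cols = [c for c in trait_columns if c not in df.columns]
    if missing_cols:
        raise DataError(f"trait column(s) {missing_cols} not found in {path}")

    raw_sex = df[sex_column].astype(str).str.strip()
    known = {str(male_label), str(female_label)}
    unknown = sorted(set(raw_sex) - known)
    if unknown:
        raise DataError(
            f"unrecognized sex label(s) {unknown} in column {sex_column!r}; "
            f"expected {sorted(known)}"
        )

    numeric = pd.DataFrame(index=df.index)
    for col in trait_columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise DataError(
                f"trait column {col!r} is not numeric: {exc}"
            ) from exc

    complete = numeric.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning(
            "dropped %d row(s) with missing trait values (complete-case rule)",
            n_dropped,
        )
    numeric = numeric.loc[complete]
    sex = np.where(raw_sex.loc[complete] == str(male_label), MALE, FEMALE)
    ids = (
        df.loc[complete, id_column].to_numpy() if id_column is not None else None
    )
    return ProfileTable(
        values=numeric.to_numpy(dtype=float),
        sex=sex,
        trait_names=list(trait_columns),
        ids=ids,
    )


def write_profile_table(
    profiles: ProfileTable,
    path,
    sex_column: str = "sex",
    male_label: str = "M",
    female_label: str = "F",
) -> None:
    """Write a ProfileTable as CSV (full float precision, round-trip safe)."""
    df = pd.DataFrame(profiles.values, columns=profiles.trait_names)
    df.insert(
        0,
        sex_column,
        np.where(profiles.sex == MALE, male_label, female_label),
    )
    if profiles.ids is not None:
        df.insert(0, "id", profiles.ids)
    df.to_csv(path, index=False, float_format="%.17g")
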