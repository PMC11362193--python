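"""Summary plotting and replication drivers for empirical datasets.

The summary plot is a 4 x 4 matrix over the four indices: per-sex density
curves on the diagonal, two-color scatterplots below it (with the
discordant quadrants shaded in the panels that pair sex-directionality
with the typicality family), and the full-sample correlation r plus the
partial correlation r_p controlling for sex above it.

``replicate_example`` runs the full pipeline on a user-supplied dataset
for three canonical domains — body morphology (with circumference
variables residualized on BMI first), brain morphology components, and
personality scales (optionally with reliability-based correction) — and
emits the same summary record as :func:`mfindices.mf_indices.summarize_indices`.
No data are downloaded; the user supplies files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.stats import gaussian_kde

from .data_model import ProfileTable, DataError, read_profile_table
from .error_correction import ReliabilityVector, read_reliabilities, correct_profile_table
from .mf_indices import MFModel, MFScoreTable, fit_mf_model, score_profiles, summarize_indices

_LABELS = {"mfd": "M-F$_D$", "mft": "M-F$_T$", "mfp": "M-F$_P$", "mfc": "M-F$_C$"}
_COLORS = {1: "#2166ac", 0: "#b2182b"}  # male blue, female red
#: Index boundary between the masculine and feminine sides, per index.
_BOUNDARY = {"mfd": 0.0, "mft": 0.0, "mfp": 0.5, "mfc": 0.0}


def _density(ax, x, color):
    x = np.asarray(x, dtype=float)
    if np.ptp(x) <= 0:
        ax.axvline(x[0], color=color)
        return
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 200)
    ax.plot(grid, kde(grid), color=color)
    ax.fill_between(grid, kde(grid), alpha=0.25, color=color)


def _shade_discordant_quadrants(ax, x_bound, y_bound):
    """Shade the two quadrants where the x- and y-index signs disagree."""
    ax.autoscale(False)
    x0, x1 = ax.get_xlim()
    y0, y1 = ax.get_ylim()
    kw = dict(color="0.55", alpha=0.25, zorder=0, linewidth=0)
    ax.fill_between([x0, x_bound], y_bound, y1, **kw)
    ax.fill_between([x_bound, x1], y0, y_bound, **kw)


def summary_plot(
    scores: MFScoreTable,
    path,
    model: MFModel | None = None,
    shade_discordant: bool = True,
) -> None:
    """Render the 4 x 4 summary figure to ``path`` (PNG/PDF/SVG by extension)."""
    names = list(MFScoreTable.INDEX_NAMES)
    if len(scores.mfd) == 0:
        raise DataError("empty score table: nothing to plot")
    summary = summarize_indices(scores, model)
    mat = {k: np.asarray(getattr(scores, k), dtype=float) for k in names}
    sex = np.asarray(scores.sex)

    fig, axes = plt.subplots(4, 4, figsize=(10, 10))
    for i, yname in enumerate(names):
        for j, xname in enumerate(names):
            ax = axes[i, j]
            if i == j:
                for code in (1, 0):
                    _density(ax, mat[xname][sex == code], _COLORS[code])
                ax.set_yticks([])
            elif i > j:
                for code in (1, 0):
                    mask = sex == code
                    ax.scatter(
                        mat[xname][mask],
                        mat[yname][mask],
                        s=4,
                        alpha=0.5,
                        color=_COLORS[code],
                        linewidths=0,
                    )
                if shade_discordant and (xname == "mfd") != (yname == "mfd"):
                    _shade_discordant_quadrants(
                        ax, _BOUNDARY[xname], _BOUNDARY[yname]
                    )
            else:
                r = summary["r"].loc[xname, yname]
                r_p = summary["r_p"].loc[xname, yname]
                ax.text(
                    0.5,
                    0.6,
                    f"r = {r:.2f}",
                    ha="center",
                    va="center",
                    fontsize=11,
                    transform=ax.transAxes,
                )
                ax.text(
                    0.5,
                    0.35,
                    f"$r_p$ = {r_p:.2f}",
                    ha="center",
                    va="center",
                    fontsize=11,
                    transform=ax.transAxes,
                )
                ax.set_xticks([])
                ax.set_yticks([])
            if i == 3:
                ax.set_xlabel(_LABELS[xname])
            if j == 0:
                ax.set_ylabel(_LABELS[yname])
    fig.suptitle(
        f"M-F indices ({summary['n_male']} M / {summary['n_female']} F, "
        f"{summary['percent_discordant']:.1f}% discordant)"
    )
    fig.tight_layout(rect=(0, 0, 1, 0.97))
    # deterministic output: fixed SVG hash salt, no embedded timestamp
    with matplotlib.rc_context({"svg.hashsalt": "mfindices"}):
        if str(path).lower().endswith(".svg"):
            fig.savefig(path, metadata={"Date": None})
        else:
            fig.savefig(path)
    plt.close(fig)


def residualize_columns(
    profiles: ProfileTable,
    columns: list[str],
    on: np.ndarray,
    by_sex: bool = False,
) -> ProfileTable:
    """Replace selected traits by their residuals from a simple regression
    on a covariate (e.g. circumferences on BMI).

    The default is a single pooled intercept+slope fit per variable;
    ``by_sex`` fits each sex separately.
    """
    on = np.asarray(on, dtype=float).ravel()
    if len(on) != profiles.n:
        raise DataError("covariate length does not match the profile table")
    values = profiles.values.copy()
    idx = []
    for c in columns:
        if c not in profiles.trait_names:
            raise DataError(f"column {c!r} not among traits")
        idx.append(profiles.trait_names.index(c))
    groups = [np.ones(profiles.n, dtype=bool)]
    if by_sex:
        groups = [profiles.sex == 1, profiles.sex == 0]
    for mask in groups:
        X = np.column_stack([np.ones(mask.sum()), on[mask]])
        beta, *_ = np.linalg.lstsq(X, values[np.ix_(mask, idx)], rcond=None)
        values[np.ix_(mask, idx)] -= X @ beta
    return ProfileTable(
        values=values,
        sex=profiles.sex.copy(),
        trait_names=list(profiles.trait_names),
        ids=profiles.ids,
    )


@dataclass
class ReplicationConfig:
    """Column mapping and options for :func:`replicate_example`."""

    sex_column: str = "sex"
    male_label: str = "M"
    female_label: str = "F"
    trait_columns: list[str] | None = None
    id_column: str | None = None
    method: str = "lda"
    # body example: variables to residualize on the covariate column
    covariate_column: str | None = None
    residualize: list[str] = field(default_factory=list)
    residualize_by_sex: bool = False
    # personality example: reliabilities trigger DMD-style correction
    reliabilities: object | None = None  # path, array-like, or ReliabilityVector


def replicate_example(
    example: str,
    data_path,
    config: ReplicationConfig | None = None,
    plot_path=None,
):
    """End-to-end pipeline for one of the canonical example domains.

    ``example`` is one of ``body`` (residualizes the configured
    circumference columns on the covariate, typically BMI, before
    analysis), ``brain`` (consumes an already-reduced component table), or
    ``personality`` (applies the DMD-style correction when reliabilities
    are configured). Returns ``(summary, scores, model)``; the summary
    carries D_M, D_Mu, percent discordant, and the r / r_p matrices.
    """
    if example not in ("body", "brain", "personality"):
        raise ValueError(f"unknown example {example!r}")
    config = config or ReplicationConfig()

    read_cols = None
    if config.trait_columns is not None:
        read_cols = list(config.trait_columns)
        if config.covariate_column and config.covariate_column not in read_cols:
            read_cols.append(config.covariate_column)
    profiles = read_profile_table(
        data_path,
        sex_column=config.sex_column,
        male_label=config.male_label,
        female_label=config.female_label,
        trait_columns=read_cols,
        id_column=config.id_column,
    )
    if example == "body":
        if not config.covariate_column or not config.residualize:
            raise DataError(
                "the body example requires covariate_column (BMI) and the "
                "list of circumference columns to residualize"
            )
        cov_idx = profiles.trait_names.index(config.covariate_column)
        covariate = profiles.values[:, cov_idx]
        profiles = residualize_columns(
            profiles,
            config.residualize,
            covariate,
            by_sex=config.residualize_by_sex,
        )
        keep = [
            j
            for j, t in enumerate(profiles.trait_names)
            if t != config.covariate_column
        ]
        profiles = ProfileTable(
            values=profiles.values[:, keep],
            sex=profiles.sex,
            trait_names=[profiles.trait_names[j] for j in keep],
            ids=profiles.ids,
        )
    if config.reliabilities is not None:
        rel = config.reliabilities
        if isinstance(rel, (str, bytes)):
            rel = read_reliabilities(rel, profiles.trait_names)
        elif not isinstance(rel, ReliabilityVector):
            rel = ReliabilityVector(np.asarray(rel, dtype=float))
        profiles = correct_profile_table(profiles, rel)

    model = fit_mf_model(profiles, method=config.method)
    scores = score_profiles(model, profiles)
    summary = summarize_indices(scores, model)
    if plot_path is not None:
        summary_plot(scores, plot_path, model)
    return summary, scores, model
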