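"""Randomized-complete-block ANOVA with subsampling, and downstream tests.

The field design behind the phenotype tables is an RCBD with subsampling:
b blocks, t treatments randomized within each block (so b*t plots), and s
subsample plants measured per plot.  The linear model for a (possibly
log-transformed) trait is

    y_ijk = mu + beta_j + alpha_i + delta_ij + eps_ijk

with block effects beta_j, treatment effects alpha_i, plot-level
experimental errors delta_ij and subsample sampling errors eps_ijk.  The
crucial inferential rule of this design is that treatments are tested
against the *experimental-error* (plot) stratum, never against the
sampling error: subsample plants within a plot are not independent
replicates of the treatment.

The balanced classical analysis is computed from explicit sums of squares
so the stratum bookkeeping is transparent and directly checkable against
hand computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "DiagnosticsBundle",
    "fit_rcbd_subsampling",
    "tukey_pairwise",
    "treatment_correlations",
    "fit_plot_means_weighted",
    "diagnostics",
    "significance_stars",
]

SOURCES = ("blocks", "treatments", "experimental_error", "sampling_error")


@dataclass
class AnovaTable:
    """Classical nested ANOVA decomposition for the subsampling design."""

    df: dict[str, int]
    ss: dict[str, float]
    ms: dict[str, float]
    f_treatment: float
    p_treatment: float
    n_blocks: int
    n_treatments: int
    n_subsamples: int
    trait: str
    log_transform: bool
    grand_mean: float  # on the analysis scale
    treatment_means: pd.Series = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for src in SOURCES:
            rows.append(
                {
                    "source": src,
                    "df": self.df[src],
                    "sum_sq": self.ss[src],
                    "mean_sq": self.ms[src],
                    "F": self.f_treatment if src == "treatments" else np.nan,
                    "p": self.p_treatment if src == "treatments" else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _check_design(table: pd.DataFrame, trait: str) -> tuple[list, list, int]:
    for col in ("block", "treatment", trait):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    blocks = sorted(table["block"].unique())
    treatments = sorted(table["treatment"].unique())
    if len(blocks) < 2 or len(treatments) < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    counts = table.groupby(["block", "treatment"], observed=True)[trait].count()
    if counts.size != len(blocks) * len(treatments) or counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every block x treatment plot must have the "
            "same number of subsamples (classical balanced analysis only)"
        )
    s = int(counts.iloc[0])
    if s < 2:
        raise ValueError("need >= 2 subsamples per plot")
    return blocks, treatments, s


def _analysis_values(table: pd.DataFrame, trait: str, log_transform: bool) -> pd.Series:
    y = table[trait].astype(float)
    if log_transform:
        bad = y <= 0
        if bad.any():
            idx = list(table.index[bad][:10])
            raise ValueError(
                f"log transform requires positive values; offending rows: {idx}"
            )
        y = np.log(y)
    return y


def fit_rcbd_subsampling(
    table: pd.DataFrame,
    trait: str,
    log_transform: bool = False,
) -> AnovaTable:
    """Fit the balanced RCBD-with-subsampling ANOVA for one trait.

    Sums of squares (balanced case, b blocks, t treatments, s subsamples):

        SS_blocks     = t*s * sum_j (ybar_.j. - ybar)^2
        SS_treatments = b*s * sum_i (ybar_i.. - ybar)^2
        SS_exp_error  = s * sum_ij (ybar_ij. - ybar_i.. - ybar_.j. + ybar)^2
        SS_sampling   = sum_ijk (y_ijk - ybar_ij.)^2

    with df b-1, t-1, (b-1)(t-1) and b*t*(s-1).  The treatment F uses the
    experimental-error mean square as denominator.
    """
    blocks, treatments, s = _check_design(table, trait)
    b, t = len(blocks), len(treatments)
    work = table.copy()
    work["_y"] = _analysis_values(table, trait, log_transform)

    grand = work["_y"].mean()
    block_means = work.groupby("block", observed=True)["_y"].mean()
    trt_means = work.groupby("treatment", observed=True)["_y"].mean()
    plot_means = work.groupby(["block", "treatment"], observed=True)["_y"].mean()

    ss_blocks = t * s * float(((block_means - grand) ** 2).sum())
    ss_trt = b * s * float(((trt_means - grand) ** 2).sum())
    interaction = (
        plot_means
        - block_means.reindex(plot_means.index.get_level_values(0)).to_numpy()
        - trt_means.reindex(plot_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_exp = s * float((interaction**2).sum())
    fitted_plot = work.set_index(["block", "treatment"]).index.map(plot_means)
    ss_samp = float(((work["_y"].to_numpy() - fitted_plot.to_numpy()) ** 2).sum())

    df = {
        "blocks": b - 1,
        "treatments": t - 1,
        "experimental_error": (b - 1) * (t - 1),
        "sampling_error": b * t * (s - 1),
    }
    ss = {
        "blocks": ss_blocks,
        "treatments": ss_trt,
        "experimental_error": ss_exp,
        "sampling_error": ss_samp,
    }
    ms = {k: ss[k] / df[k] for k in ss}
    if ms["experimental_error"] > 0:
        f_trt = ms["treatments"] / ms["experimental_error"]
        p_trt = float(sps.f.sf(f_trt, df["treatments"], df["experimental_error"]))
    else:
        f_trt, p_trt = np.inf, 0.0
    return AnovaTable(
        df=df,
        ss=ss,
        ms=ms,
        f_treatment=float(f_trt),
        p_treatment=p_trt,
        n_blocks=b,
        n_treatments=t,
        n_subsamples=s,
        trait=trait,
        log_transform=log_transform,
        grand_mean=float(grand),
        treatment_means=trt_means,
    )


def tukey_pairwise(fit: AnovaTable, table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Tukey studentized-range comparisons of treatment means.

    The standard error uses the experimental-error stratum of ``fit``
    (its mean square and degrees of freedom), consistent with the design:
    q_ij = |ybar_i - ybar_j| / sqrt(MS_exp / (b*s)).  Returns a symmetric
    p-value matrix with a unit diagonal.
    """
    if fit.n_treatments < 2:
        raise ValueError("need >= 2 treatments")
    work_y = _analysis_values(table, trait, fit.log_transform)
    means = (
        pd.DataFrame({"treatment": table["treatment"], "_y": work_y})
        .groupby("treatment", observed=True)["_y"]
        .mean()
        .sort_index()
    )
    t = len(means)
    n_per = fit.n_blocks * fit.n_subsamples
    se = np.sqrt(fit.ms["experimental_error"] / n_per)
    dferr = fit.df["experimental_error"]
    labels = list(means.index)
    p = np.ones((t, t))
    for i in range(t):
        for j in range(i + 1, t):
            if se > 0:
                q = abs(means.iloc[i] - means.iloc[j]) / se
                pij = float(sps.studentized_range.sf(q, t, dferr))
            else:
                pij = 0.0 if means.iloc[i] != means.iloc[j] else 1.0
            p[i, j] = p[j, i] = pij
    return pd.DataFrame(p, index=labels, columns=labels)


def significance_stars(p: float) -> str:
    """Conventional significance codes: *** <0.001, ** <0.01, * <0.05."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def treatment_correlations(table: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Per-treatment Pearson correlations between trait pairs.

    Returns a tidy frame (treatment, trait_x, trait_y, r, p, stars, n),
    one correlation per treatment group per unordered trait pair.  A
    constant trait within a group yields an undefined correlation,
    reported as missing.
    """
    if len(traits) < 2:
        raise ValueError("need >= 2 traits")
    rows = []
    for trt, grp in table.groupby("treatment", observed=True):
        if len(grp) < 3:
            raise ValueError(f"treatment {trt!r} has < 3 observations")
        for a_i in range(len(traits)):
            for b_i in range(a_i + 1, len(traits)):
                ta, tb = traits[a_i], traits[b_i]
                x = grp[ta].astype(float).to_numpy()
                y = grp[tb].astype(float).to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = sps.pearsonr(x, y)
                rows.append(
                    {
                        "treatment": trt,
                        "trait_x": ta,
                        "trait_y": tb,
                        "r": float(r) if np.isfinite(r) else np.nan,
                        "p": float(p) if np.isfinite(p) else np.nan,
                        "stars": significance_stars(p),
                        "n": len(grp),
                    }
                )
    return pd.DataFrame(rows)


def fit_plot_means_weighted(
    table: pd.DataFrame,
    trait: str,
    *,
    log_transform: bool = False,
    variance_power: float = 0.0,
    n_iter: int = 10,
) -> dict[str, float]:
    """Treatment F-test on plot means with a power-of-fitted variance model.

    An optional robustness path for traits whose plot-level variance grows
    with the mean: Var(plot mean) proportional to \\|fitted\\|^(2*theta).
    Weighted least squares on the b*t plot means (blocks + treatments,
    additive) is iterated, re-deriving weights from the fitted values each
    pass.  With ``variance_power = 0`` this reduces to the ordinary
    plot-means analysis, whose treatment F equals the subsampling ANOVA's.

    Returns ``{"f_treatment", "p_treatment", "df1", "df2", "variance_power"}``.
    """
    blocks, treatments, _ = _check_design(table, trait)
    b, t = len(blocks), len(treatments)
    work = table.copy()
    work["_y"] = _analysis_values(table, trait, log_transform)
    pm = (
        work.groupby(["block", "treatment"], observed=True)["_y"].mean().reset_index()
    )
    yb = pm["_y"].to_numpy()
    xb = np.zeros((len(pm), 1 + (b - 1) + (t - 1)))
    xb[:, 0] = 1.0
    for j, blk in enumerate(blocks[1:]):
        xb[:, 1 + j] = (pm["block"] == blk).to_numpy(dtype=float)
    for i, trt in enumerate(treatments[1:]):
        xb[:, b + i] = (pm["treatment"] == trt).to_numpy(dtype=float)
    x0 = xb[:, : b]  # intercept + blocks only (null model)

    w = np.ones(len(pm))
    for _ in range(max(1, n_iter)):
        sw = np.sqrt(w)[:, None]
        beta, *_ = np.linalg.lstsq(xb * sw, yb * sw[:, 0], rcond=None)
        fitted = xb @ beta
        if variance_power == 0.0:
            break
        w = 1.0 / np.maximum(np.abs(fitted), 1e-8) ** (2.0 * variance_power)
        w /= w.mean()
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(xb * sw[:, None], yb * sw, rcond=None)
    rss_full = float((((yb - xb @ beta) * sw) ** 2).sum())
    beta0, *_ = np.linalg.lstsq(x0 * sw[:, None], yb * sw, rcond=None)
    rss_null = float((((yb - x0 @ beta0) * sw) ** 2).sum())
    df1 = t - 1
    df2 = (b - 1) * (t - 1)
    f = ((rss_null - rss_full) / df1) / (rss_full / df2)
    return {
        "f_treatment": float(f),
        "p_treatment": float(sps.f.sf(f, df1, df2)),
        "df1": df1,
        "df2": df2,
        "variance_power": variance_power,
    }


@dataclass
class DiagnosticsBundle:
    """Residual diagnostics: data behind the QQ and fitted-vs-residual plots."""

    qq_theoretical: np.ndarray  # normal quantiles for plot-level residuals
    qq_observed: np.ndarray  # sorted plot-level residuals
    fitted: np.ndarray  # per-observation fitted plot means
    residuals: np.ndarray  # per-observation sampling residuals
    shapiro_stat: float
    shapiro_p: float


def diagnostics(fit: AnovaTable, table: pd.DataFrame, trait: str) -> DiagnosticsBundle:
    """Residual diagnostics for a fitted trait.

    Plot-level residuals (the estimated experimental errors
    ybar_ij. - ybar_i.. - ybar_.j. + ybar) feed a Shapiro-Wilk normality
    test and the QQ data; per-observation sampling residuals against the
    fitted plot means feed the fitted-vs-residuals data.
    """
    work = table.copy()
    work["_y"] = _analysis_values(table, trait, fit.log_transform)
    grand = work["_y"].mean()
    block_means = work.groupby("block", observed=True)["_y"].mean()
    trt_means = work.groupby("treatment", observed=True)["_y"].mean()
    plot_means = work.groupby(["block", "treatment"], observed=True)["_y"].mean()
    plot_resid = (
        plot_means
        - block_means.reindex(plot_means.index.get_level_values(0)).to_numpy()
        - trt_means.reindex(plot_means.index.get_level_values(1)).to_numpy()
        + grand
    ).to_numpy()
    fitted = work.set_index(["block", "treatment"]).index.map(plot_means).to_numpy()
    resid = work["_y"].to_numpy() - fitted
    srt = np.sort(plot_resid)
    k = len(srt)
    theo = sps.norm.ppf((np.arange(1, k + 1) - 0.5) / k)
    stat, p = sps.shapiro(plot_resid)
    return DiagnosticsBundle(
        qq_theoretical=theo,
        qq_observed=srt,
        fitted=fitted,
        residuals=resid,
        shapiro_stat=float(stat),
        shapiro_p=float(p),
    )
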