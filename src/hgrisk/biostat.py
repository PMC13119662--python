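"""Descriptive and comparative statistics for fish THg surveys.

Covers the survey's analysis protocol: a Shapiro-Wilk normality gate with
log10 fallback, one-way ANOVA with Tukey HSD (plus a Levene
variance-homogeneity check reported as a warning), Pearson/Spearman
correlation matrices of morphometrics against tissue THg by species and
organ, OLS size models (muscle THg on TL and TW) with residual diagnostics,
coefficients of variation, and an exact Mann-Whitney contrast between size
classes.

Significance is read at p < 0.05 throughout.  Per-cell correlation p-values
are reported raw (no multiplicity correction across the species x organ
matrix), which mirrors the survey protocol and is deliberately liberal —
treat matrix-wide screening results accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.outliers_influence import OLSInfluence

from .survey import ORGANS, Survey

__all__ = [
    "StatResult",
    "InsufficientDataError",
    "normality_gate",
    "coefficient_of_variation",
    "oneway_anova_tukey",
    "correlation_matrix",
    "ols_size_model",
    "mann_whitney_size_contrast",
    "organ_summary",
]

ALPHA: float = 0.05


class InsufficientDataError(ValueError):
    """Too few observations for the requested test."""


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its p-value, sample size and context label."""

    statistic: float
    p_value: float
    n: int
    label: str = ""
    transformed: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def normality_gate(values) -> tuple[bool, np.ndarray]:
    """Return ``(transformed, working_sample)`` for downstream tests.

    Applies the Shapiro-Wilk test to the raw sample; when it rejects
    normality at p < 0.05 the sample is log10-transformed (requiring all
    values positive) and the flag is set.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(
            f"normality gate needs n >= 3, got {x.size}")
    _, p = stats.shapiro(x)
    if p >= ALPHA:
        return False, x
    if np.any(x <= 0):
        raise ValueError(
            "log10 transform requested for a sample with non-positive values")
    return True, np.log10(x)


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * SD / mean, with the n-1 SD denominator."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"CV needs n >= 2, got {x.size}")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def oneway_anova_tukey(values, groups, *, gate: bool = True
                       ) -> tuple[StatResult, pd.DataFrame]:
    """One-way ANOVA F with Tukey HSD pairwise comparisons.

    ``values``/``groups`` are parallel sequences.  The normality gate is
    applied to the pooled sample before testing (disable with
    ``gate=False``); Levene's test (median-centred) is run alongside and a
    failure raises a ``UserWarning`` rather than aborting.

    Returns the ANOVA :class:`StatResult` and a tidy Tukey table with
    columns ``group1, group2, meandiff, p_adj, lower, upper, reject``.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if x.shape != labels.shape:
        raise ValueError("values and groups must align")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise InsufficientDataError(
            f"every group needs >= 2 members; too small: {small}")

    transformed = False
    if gate:
        transformed, x = normality_gate(x)

    samples = [x[labels == u] for u in uniq]
    _, p_lev = stats.levene(*samples, center="median")
    if p_lev < ALPHA:
        warnings.warn(
            f"variance homogeneity questionable (Levene p = {p_lev:.3g}); "
            "ANOVA proceeds but interpret with care",
            UserWarning, stacklevel=2)

    f_stat, p_val = stats.f_oneway(*samples)
    result = StatResult(float(f_stat), float(p_val), int(x.size),
                        label="one-way ANOVA", transformed=transformed)

    tk = pairwise_tukeyhsd(x, labels, alpha=ALPHA)
    tukey = pd.DataFrame(
        tk.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower",
                 "upper", "reject"],
    )
    tukey["p_adj"] = np.asarray(tk.pvalues, dtype=float)
    return result, tukey


def correlation_matrix(survey: Survey, predictor: str = "tl",
                       method: str = "pearson", *, organ_subset=None,
                       log_conc: bool = False, min_n: int = 3
                       ) -> pd.DataFrame:
    """Species x organ matrix of size-THg correlations.

    ``predictor`` is ``"tl"`` (total length, cm) or ``"tw"`` (total weight,
    g); ``method`` is ``"pearson"`` or ``"spearman"``.  Cells with fewer
    than ``min_n`` paired observations are absent (NaN), not zero.
    Concentrations enter on the raw scale by default; ``log_conc=True``
    switches to log10.

    Returns a tidy frame with columns ``species, organ, r, p_value, n``.
    """
    if predictor not in ("tl", "tw"):
        raise ValueError("predictor must be 'tl' or 'tw'")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    df = survey.to_frame()
    pred_col = "tl_cm" if predictor == "tl" else "tw_g"
    organs = tuple(organ_subset) if organ_subset else ORGANS
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    rows = []
    for species in survey.species_list():
        for organ in organs:
            sub = df[(df.species == species) & (df.organ == organ)]
            n = len(sub)
            if n < min_n:
                rows.append({"species": species, "organ": organ,
                             "r": np.nan, "p_value": np.nan, "n": n})
                continue
            y = sub.thg_mg_kg_ww.to_numpy(dtype=float)
            if log_conc:
                y = np.log10(y)
            x = sub[pred_col].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"species": species, "organ": organ,
                             "r": np.nan, "p_value": np.nan, "n": n})
                continue
            r, p = corr(x, y)
            rows.append({"species": species, "organ": organ,
                         "r": float(r), "p_value": float(p), "n": n})
    return pd.DataFrame(rows)


def ols_size_model(survey: Survey, species: str, organ: str = "muscle", *,
                   log_conc: bool = False) -> dict:
    """OLS of organ THg on TL and TW for one species, with diagnostics.

    Returns a dict with ``params`` / ``bse`` / ``pvalues`` (pandas Series
    over ``const, tl_cm, tw_g``), ``n``, ``r_squared``, ``dropped``
    (predictors removed for collinearity), and ``diagnostics`` holding the
    residual Shapiro-Wilk p, Breusch-Pagan p, and maximum leverage.
    """
    df = survey.to_frame()
    sub = df[(df.species == species) & (df.organ == organ)]
    if sub.empty:
        raise KeyError(f"no {organ} records for {species!r}")
    if len(sub) < 4:
        raise InsufficientDataError(
            f"OLS with two predictors needs n >= 4, got {len(sub)}")
    y = sub.thg_mg_kg_ww.to_numpy(dtype=float)
    if log_conc:
        y = np.log10(y)
    X = sub[["tl_cm", "tw_g"]].astype(float)

    dropped: list[str] = []
    # collinear to machine precision -> drop TW, keep TL
    xs = (X - X.mean()) / X.std(ddof=1)
    if np.linalg.matrix_rank(xs.to_numpy(), tol=1e-10) < 2:
        dropped.append("tw_g")
        X = X[["tl_cm"]]

    Xc = sm.add_constant(X)
    fit = sm.OLS(y, Xc).fit()
    infl = OLSInfluence(fit)
    resid = fit.resid
    sw_p = float(stats.shapiro(resid)[1]) if len(resid) >= 3 else np.nan
    try:
        bp_p = float(sm.stats.het_breuschpagan(resid, Xc)[3])
    except (ValueError, np.linalg.LinAlgError):
        bp_p = np.nan
    return {
        "params": fit.params,
        "bse": fit.bse,
        "pvalues": fit.pvalues,
        "n": int(fit.nobs),
        "r_squared": float(fit.rsquared),
        "dropped": dropped,
        "diagnostics": {
            "resid_shapiro_p": sw_p,
            "breusch_pagan_p": bp_p,
            "max_leverage": float(np.max(infl.hat_matrix_diag)),
        },
    }


def mann_whitney_size_contrast(survey: Survey, species: str,
                               organ: str = "muscle") -> StatResult:
    """Mann-Whitney U between the small and large size classes.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties (normal approximation otherwise), with
    the smaller-of-the-two-U reporting convention and a two-sided p.
    """
    df = survey.to_frame()
    sub = df[(df.species == species) & (df.organ == organ)]
    if sub.empty:
        raise KeyError(f"no {organ} records for {species!r}")
    small = sub[sub.size_class == "small"].thg_mg_kg_ww.to_numpy(float)
    large = sub[sub.size_class == "large"].thg_mg_kg_ww.to_numpy(float)
    if small.size == 0 or large.size == 0:
        raise InsufficientDataError(
            "both size classes must be non-empty (run assign_size_classes)")
    return mann_whitney_exact(small, large,
                              label=f"{species} {organ} small vs large")


def mann_whitney_exact(x, y, *, label: str = "") -> StatResult:
    """Two-sided Mann-Whitney with the min(U1, U2) convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_comb = x.size + y.size
    ties = len(np.unique(np.concatenate([x, y]))) < n_comb
    method = "exact" if (n_comb <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return StatResult(u, float(res.pvalue), int(n_comb), label=label)


def organ_summary(survey: Survey, *, by: str | None = None) -> pd.DataFrame:
    """Organ-wise THg summary: mean, SD, median, min, max, CV%, n.

    With ``by`` set to ``"species"`` or ``"reservoir"`` the summary is
    additionally stratified by that column.
    """
    df = survey.to_frame()
    keys = ["organ"] if by is None else [by, "organ"]
    gb = df.groupby(keys)["thg_mg_kg_ww"]
    out = gb.agg(
        mean="mean",
        sd=lambda v: v.std(ddof=1),
        median="median",
        min="min",
        max="max",
        n="count",
    ).reset_index()
    out["cv_pct"] = 100.0 * out["sd"] / out["mean"]
    return out


def pairwise_unadjusted_pvalues(values, groups) -> pd.DataFrame:
    """Unadjusted two-sample t-test p per group pair (Tukey comparator)."""
    x = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    rows = []
    for a, b in combinations(np.unique(labels), 2):
        _, p = stats.ttest_ind(x[labels == a], x[labels == b])
        rows.append({"group1": a, "group2": b, "p_raw": float(p)})
    return pd.DataFrame(rows)
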