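"""Demographic comparisons and brain-behaviour correlation.

Covers the statistics used around the imaging pipeline: pooled two-sample
t tests on summary statistics (group demographics tables), the 2x2 Pearson
chi-square for sex ratios, Pearson and partial correlation between
cluster-mean imaging values and clinical scores, and Bonferroni control
over the (clusters x scores) family.

Partial correlation residualises both variables on [intercept |
covariates] and correlates the residuals; its degrees of freedom are
n - 2 - k for k covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult", "pearson_r_p", "pearson_p_from_r",
    "partial_corr_r_p", "bonferroni_adjust", "summary_two_sample_t",
    "chi_square_2x2", "correlate_clusters_with_scores", "demographic_table",
]


@dataclass
class CorrelationResult:
    """A correlation with its test: r, dof, t, two-sided p, adjusted p."""

    r: float
    n: int
    dof: int
    t_stat: float
    p_two_sided: float
    kind: str = "pearson"              # "pearson" or "partial"
    covariates: list = field(default_factory=list)
    p_adjusted: float = np.nan


def _r_to_t_p(r: float, dof: int) -> tuple[float, float]:
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return np.inf * np.sign(r), 0.0
    t = r * np.sqrt(dof) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), dof)
    return t, p


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r at dof = n - 2.

    Used to check printed (r, p) pairs for internal consistency.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    return _r_to_t_p(r, n - 2)[1]


def pearson_r_p(x, y) -> CorrelationResult:
    """Sample Pearson correlation with its t test (dof = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    t, p = _r_to_t_p(r, n - 2)
    return CorrelationResult(r=r, n=n, dof=n - 2, t_stat=t, p_two_sided=p,
                             kind="pearson")


def partial_corr_r_p(x, y, covariates, covariate_names=None) -> CorrelationResult:
    """Partial correlation of x and y given covariates (n x k).

    Both variables are residualised on [intercept | covariates] by least
    squares; the Pearson correlation of the residuals is tested at
    dof = n - 2 - k.  With k = 0 this reduces exactly to `pearson_r_p`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.size == 0:
        C = np.empty((len(x), 0))
    if C.ndim == 1:
        C = C[:, None]
    n, k = C.shape
    if len(x) != n or len(y) != n:
        raise ValueError("length mismatch")
    if n < k + 3:
        raise ValueError("need n >= k + 3")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariates are rank deficient")
    beta_x, *_ = np.linalg.lstsq(X, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    rx = x - X @ beta_x
    ry = y - X @ beta_y
    dof = n - 2 - k
    # a variable fully explained by the covariates leaves only roundoff:
    # its partial correlation is 0 by definition, not noise
    tol_x = 1e-10 * (x.std() + 1.0)
    tol_y = 1e-10 * (y.std() + 1.0)
    if rx.std() <= tol_x or ry.std() <= tol_y:
        return CorrelationResult(r=0.0, n=n, dof=dof, t_stat=0.0,
                                 p_two_sided=1.0, kind="partial",
                                 covariates=list(covariate_names or range(k)))
    r = float(np.corrcoef(rx, ry)[0, 1])
    t, p = _r_to_t_p(r, dof)
    return CorrelationResult(r=r, n=n, dof=dof, t_stat=t, p_two_sided=p,
                             kind="partial",
                             covariates=list(covariate_names or range(k)))


def bonferroni_adjust(p_values, m: int | None = None):
    """Bonferroni adjustment: p_adj = min(1, m * p).

    ``m`` defaults to the number of tests and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of tests")
    return np.minimum(1.0, m * p)


def summary_two_sample_t(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int,
                         welch: bool = False) -> dict:
    """Two-sample t test from summary statistics (pooled variance default).

    Suitable for comparing group demographics reported as mean +/- SD.
    """
    if sd1 <= 0 or sd2 <= 0 or n1 < 2 or n2 < 2:
        raise ValueError("need positive SDs and n >= 2 per group")
    if welch:
        se2 = sd1 ** 2 / n1 + sd2 ** 2 / n2
        t = (mean1 - mean2) / np.sqrt(se2)
        dof = se2 ** 2 / ((sd1 ** 2 / n1) ** 2 / (n1 - 1)
                          + (sd2 ** 2 / n2) ** 2 / (n2 - 1))
    else:
        dof = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / dof
        t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return {"t": float(t), "dof": float(dof), "p": float(p)}


def chi_square_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Pearson chi-square (1 dof, no continuity correction) on a 2x2 table.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or any(m == 0 for m in margins):
        raise ValueError("zero marginal total")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, 1))
    return {"chi2": float(chi2), "p": p}


def correlate_clusters_with_scores(cluster_values: pd.DataFrame,
                                   scores: pd.DataFrame,
                                   covariates: pd.DataFrame | None = None,
                                   ) -> pd.DataFrame:
    """Correlate per-subject cluster means against clinical scores.

    ``cluster_values``: subjects x clusters (mean ReHo or z per cluster);
    ``scores``: subjects x clinical scores (same index).  Both simple
    Pearson and covariate-adjusted partial correlations are reported, each
    Bonferroni-adjusted over its own n_clusters x n_scores family.
    """
    if cluster_values.empty or scores.empty:
        raise ValueError("need at least one cluster and one score")
    if not cluster_values.index.equals(scores.index):
        raise ValueError("cluster values and scores must share subjects")
    cov_df = None
    cov_names: list = []
    if covariates is not None and covariates.shape[1] > 0:
        if not covariates.index.equals(scores.index):
            raise ValueError("covariates must share subjects")
        cov_df = covariates.copy()
        if "sex" in cov_df.columns and cov_df["sex"].dtype == object:
            cov_df["sex"] = cov_df["sex"].map({"male": 0.0, "female": 1.0})
        cov_names = list(cov_df.columns)

    rows = []
    for cl in cluster_values.columns:
        for sc in scores.columns:
            pair = pd.concat([cluster_values[cl], scores[sc]], axis=1).dropna()
            x = pair.iloc[:, 0].to_numpy(float)
            y = pair.iloc[:, 1].to_numpy(float)
            if y.std() == 0:
                raise ValueError(f"score {sc} has zero variance")
            res = pearson_r_p(x, y)
            rows.append({"cluster": cl, "score": sc, "kind": "pearson",
                         "r": res.r, "n": res.n, "dof": res.dof,
                         "t": res.t_stat, "p": res.p_two_sided})
            if cov_df is not None:
                sub_mat = cov_df.loc[pair.index].to_numpy(float)
                pres = partial_corr_r_p(x, y, sub_mat, covariate_names=cov_names)
                rows.append({"cluster": cl, "score": sc, "kind": "partial",
                             "r": pres.r, "n": pres.n, "dof": pres.dof,
                             "t": pres.t_stat, "p": pres.p_two_sided})
    out = pd.DataFrame(rows)
    m = cluster_values.shape[1] * scores.shape[1]
    out["p_bonferroni"] = np.nan
    for kind in out["kind"].unique():
        sel = out["kind"] == kind
        out.loc[sel, "p_bonferroni"] = bonferroni_adjust(out.loc[sel, "p"], m)
    return out


def demographic_table(subjects: pd.DataFrame,
                      continuous: list[str] = ("age_years", "education_years",
                                               "gm_volume_ml"),
                      group_col: str = "group") -> pd.DataFrame:
    """Group mean +/- SD per covariate with pooled-t p values, plus the
    sex chi-square row — the usual participants table."""
    groups = sorted(subjects[group_col].unique())
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    g1 = subjects[subjects[group_col] == groups[0]]
    g2 = subjects[subjects[group_col] == groups[1]]
    rows = []
    for var in continuous:
        res = summary_two_sample_t(
            g1[var].mean(), g1[var].std(ddof=1), len(g1),
            g2[var].mean(), g2[var].std(ddof=1), len(g2))
        rows.append({"variable": var,
                     f"{groups[0]}_mean": g1[var].mean(),
                     f"{groups[0]}_sd": g1[var].std(ddof=1),
                     f"{groups[1]}_mean": g2[var].mean(),
                     f"{groups[1]}_sd": g2[var].std(ddof=1),
                     "stat": res["t"], "p": res["p"]})
    if "sex" in subjects.columns:
        a = int((g1["sex"] == "male").sum())
        b = int((g1["sex"] == "female").sum())
        c = int((g2["sex"] == "male").sum())
        d = int((g2["sex"] == "female").sum())
        chi = chi_square_2x2(a, b, c, d)
        rows.append({"variable": "sex_male_female",
                     f"{groups[0]}_mean": a, f"{groups[0]}_sd": b,
                     f"{groups[1]}_mean": c, f"{groups[1]}_sd": d,
                     "stat": chi["chi2"], "p": chi["p"]})
    return pd.DataFrame(rows)
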