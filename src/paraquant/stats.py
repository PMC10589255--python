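"""Bulk expression statistics for the quantified paralog matrix.

Implements the analysis layer run on reliable RPKM values: log10
transformation, one-way ANOVA with Levene/Shapiro–Wilk assumption checks
and Tukey–Kramer HSD post-hocs, ordinary least-squares regression of total
family expression on copy number, and pairwise Pearson profile
correlations with Benjamini–Hochberg correction.

Assumption tests are reported, not gating: ANOVA is run regardless, and
the Levene / Shapiro–Wilk p-values travel alongside so users can judge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


def significance_stars(p: float) -> str:
    """Conventional star coding: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AnovaResult:
    F: float
    p: float
    group_means: dict[str, float]
    levene_p: float
    shapiro_p: float
    tukey: Optional[pd.DataFrame]  # populated when p < alpha

    def __repr__(self):  # compact scientific display
        return (f"AnovaResult(F={self.F:.4g}, p={self.p:.3g}, "
                f"levene_p={self.levene_p:.3g}, shapiro_p={self.shapiro_p:.3g}, "
                f"tukey={'yes' if self.tukey is not None else 'no'})")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float


def log_transform(matrix: pd.DataFrame, value_col: str = "rpkm") -> pd.DataFrame:
    """log10-transform reliable expression values.

    Rows flagged unreliable are dropped (they are excluded from statistics
    by design); a zero or negative value among reliable entries raises,
    since the reliability filter (count >= 10 => RPKM > 0) should have
    excluded it.
    """
    out = matrix
    if "reliable" in matrix.columns:
        out = matrix.loc[matrix["reliable"]].copy()
    else:
        out = matrix.copy()
    vals = out[value_col].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError(
            "zero or negative expression among reliable entries; "
            "apply the reliability filter before log transformation")
    out[f"log10_{value_col}"] = np.log10(vals)
    return out


def anova_with_checks(groups: dict[str, Sequence[float]],
                      alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across named groups of log-scale values.

    Levene (median-centred) and Shapiro–Wilk (on pooled residuals) p-values
    are reported alongside. When the ANOVA rejects at ``alpha``, a
    Tukey–Kramer HSD table (unequal-n form) is attached with columns
    group1, group2, meandiff, p_adj, stars, reject.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    values = list(arrays.values())
    F, p = sps.f_oneway(*values)
    if all(np.ptp(v) == 0 for v in values) and len({v[0] for v in values}) == 1:
        # identical groups: no variance anywhere, define F=0, p=1
        F, p = 0.0, 1.0
    levene_p = sps.levene(*values, center="median").pvalue
    residuals = np.concatenate([v - v.mean() for v in values])
    if np.ptp(residuals) == 0:
        shapiro_p = float("nan")  # constant residuals: W undefined
    else:
        shapiro_p = sps.shapiro(residuals).pvalue
    means = {k: float(v.mean()) for k, v in arrays.items()}
    tukey = None
    if p < alpha:
        endog = np.concatenate(values)
        labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
        res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
        tukey = pd.DataFrame(res.summary().data[1:],
                             columns=[c.lower() for c in res.summary().data[0]])
        tukey = tukey.rename(columns={"p-adj": "p_adj"})
        tukey["p_adj"] = tukey["p_adj"].astype(float)
        tukey["stars"] = tukey["p_adj"].map(significance_stars)
    return AnovaResult(F=float(F), p=float(p), group_means=means,
                       levene_p=float(levene_p), shapiro_p=float(shapiro_p),
                       tukey=tukey)


def cn_regression(copy_numbers: Sequence[float],
                  log_total_expression: Sequence[float]) -> RegressionResult:
    """OLS of log10 total family expression on copy number.

    Points are replicate-level (each replicate contributes one point), not
    strain means. Requires >= 3 points and non-constant copy number.
    """
    x = np.asarray(copy_numbers, dtype=float)
    y = np.asarray(log_total_expression, dtype=float)
    if x.size != y.size:
        raise ValueError("copy number and expression vectors differ in length")
    if x.size < 3:
        raise ValueError("regression requires at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("copy number is constant; slope undefined")
    if np.ptp(y) == 0:
        # flat response: slope 0, no variance explained, p undefined -> 1
        return RegressionResult(slope=0.0, intercept=float(y[0]), r2=0.0, p=1.0)
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2),
                            p=float(res.pvalue))


def profile_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Pearson correlations between expression profiles.

    ``profiles`` is conditions x profiles (e.g. cell types x paralogs).
    Returns a tidy frame (a, b, r, p, p_adj) with Benjamini–Hochberg
    adjustment across the tested pairs; pairs involving a zero-variance
    profile are reported with NaN statistics and excluded from adjustment.
    """
    if profiles.shape[0] < 3:
        raise ValueError("profile correlation requires >= 3 conditions")
    cols = list(profiles.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = profiles[cols[i]].to_numpy(dtype=float)
            b = profiles[cols[j]].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rows.append((cols[i], cols[j], np.nan, np.nan))
            else:
                r, p = sps.pearsonr(a, b)
                rows.append((cols[i], cols[j], float(r), float(p)))
    out = pd.DataFrame(rows, columns=["a", "b", "r", "p"])
    out["p_adj"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(
            out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def intrastrain_anova(matrix: pd.DataFrame, strain: str,
                      value_col: str = "log10_rpkm",
                      alpha: float = 0.05) -> AnovaResult:
    """Convenience wrapper: ANOVA across a strain's paralogs from the long
    expression frame (columns strain, target, replicate, value_col)."""
    sub = matrix.loc[(matrix["strain"] == strain)
                     & (matrix["target"] != "ALL")]
    groups = {t: g[value_col].to_numpy()
              for t, g in sub.groupby("target")}
    return anova_with_checks(groups, alpha=alpha)
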