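"""Predicted-age-gap statistics: stratification, correlations, comparisons.

The bias-corrected predicted age gap (PAG) of a subject-organ pair is the
corrected predicted age minus chronological age; positive values indicate
accelerated organ aging.  Subjects are stratified per organ with a
threshold theta equal to the cohort SD of the corrected PAGs:

    accelerated (2): PAG >  theta
    typical     (1): |PAG| <= theta
    decelerated (0): PAG < -theta

Cross-organ structure is summarized by the Pearson correlation matrix of
PAGs over complete cases with Bonferroni control over the C(9,2) = 36
pairs, and disease-group contrasts use Welch's unequal-variance t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, DataError

DECELERATED, TYPICAL, ACCELERATED = 0, 1, 2


class StratificationConfig:
    """Per-organ aging thresholds theta (years), all strictly positive."""

    def __init__(self, theta_organ: dict[str, float]):
        for organ, theta in theta_organ.items():
            if not theta > 0:
                raise ConfigurationError(
                    f"theta for {organ!r} must be positive, got {theta}")
        self.theta_organ = dict(theta_organ)

    def __getitem__(self, organ: str) -> float:
        return self.theta_organ[organ]


def compute_pags(pred_corrected, ca) -> np.ndarray:
    """Predicted age gap = corrected predicted age - chronological age."""
    pred = np.asarray(pred_corrected, dtype=np.float64)
    ca = np.asarray(ca, dtype=np.float64)
    return pred - ca


def compute_theta(pags) -> float:
    """Organ threshold theta: sample SD (ddof=1) of corrected PAGs."""
    p = np.asarray(list(pags), dtype=np.float64)
    if p.size < 2:
        raise DataError("need at least 2 PAGs to compute theta")
    theta = float(p.std(ddof=1))
    if theta == 0.0:
        raise DataError("degenerate PAG distribution: theta = 0 is not a "
                        "valid stratification threshold")
    return theta


def stratify_aging(pag, theta: float):
    """Map PAGs to group codes 0/1/2; the boundary |PAG| = theta is typical."""
    if theta <= 0:
        raise ConfigurationError("theta must be positive")
    p = np.asarray(pag, dtype=np.float64)
    group = np.where(p > theta, ACCELERATED,
                     np.where(p < -theta, DECELERATED, TYPICAL))
    if np.ndim(pag) == 0:
        return int(group)
    return group.astype(int)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m for a family of m tests."""
    if m < 1:
        raise ConfigurationError("number of tests must be at least 1")
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must be in (0, 1]")
    return alpha / m


def pairwise_pag_correlations(pag_matrix: pd.DataFrame, alpha: float = 0.05,
                              ) -> dict[str, pd.DataFrame]:
    """Pearson r, two-sided p and Bonferroni significance per organ pair.

    `pag_matrix` holds one column per organ over complete cases.  Returns
    matrices ``r`` (unit diagonal), ``p`` (NaN diagonal) and boolean
    ``significant`` with the per-test threshold alpha / C(k, 2).  Organs
    with zero variance yield NaN (undefined) entries for their pairs.
    """
    df = pd.DataFrame(pag_matrix).dropna()
    organs = list(df.columns)
    k = len(organs)
    if len(df) < 3:
        raise DataError("need at least 3 complete cases")
    m = k * (k - 1) // 2
    thresh = bonferroni_threshold(alpha, m)
    r = pd.DataFrame(np.eye(k), index=organs, columns=organs)
    p = pd.DataFrame(np.nan, index=organs, columns=organs)
    for i in range(k):
        for j in range(i + 1, k):
            xi = df[organs[i]].to_numpy()
            xj = df[organs[j]].to_numpy()
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(xi, xj)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    significant = (p < thresh).fillna(False)
    return {"r": r, "p": p, "significant": significant,
            "threshold": thresh, "n": len(df), "n_tests": m}


def welch_comparison(group_a, group_b) -> dict[str, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(list(group_a), dtype=np.float64)
    b = np.asarray(list(group_b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DataError("both groups need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(a.size + b.size - 2), "p": 1.0}
        raise DataError("both groups are degenerate with different means")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def welch_family(groups: dict[str, tuple], alpha: float = 0.05) -> pd.DataFrame:
    """Run an explicit family of Welch comparisons with Bonferroni control.

    `groups` maps a comparison label to an ``(a, b)`` pair of samples; the
    family size is the number of comparisons (11 in the disease-contrast
    analysis this mirrors).
    """
    thresh = bonferroni_threshold(alpha, len(groups))
    rows = []
    for label, (a, b) in groups.items():
        res = welch_comparison(a, b)
        rows.append({"comparison": label, "t": res["t"], "df": res["df"],
                     "p": res["p"],
                     "mean_diff": float(np.mean(b) - np.mean(a)),
                     "significant": res["p"] < thresh})
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = thresh
    return out


def kde_summary(pags, grid=None, bandwidth=None) -> dict:
    """Gaussian-kernel density of PAGs plus a 1.96*SD normal-range band.

    Scott's rule bandwidth by default; the band ``mean +/- 1.96 SD`` is the
    95% reference interval drawn alongside the densities.
    """
    p = np.asarray(list(pags), dtype=np.float64)
    if p.size < 2:
        raise DataError("need at least 2 observations for a KDE")
    if bandwidth is not None and bandwidth <= 0:
        raise DataError("bandwidth must be positive")
    kde = stats.gaussian_kde(p, bw_method=bandwidth if bandwidth else "scott")
    if grid is None:
        span = 4.0 * p.std(ddof=1) + 1e-9
        grid = np.linspace(p.min() - span, p.max() + span, 512)
    grid = np.asarray(grid, dtype=np.float64)
    mean, sd = float(p.mean()), float(p.std(ddof=1))
    return {"grid": grid, "density": kde(grid), "mean": mean, "sd": sd,
            "band": (mean - 1.96 * sd, mean + 1.96 * sd)}


def pag_table(predictions: pd.DataFrame, cohort: pd.DataFrame,
              bias_fits: dict, theta_subset=None) -> pd.DataFrame:
    """Assemble the per-subject-organ PAG table with group labels.

    `predictions` columns: subject_id, organ, mu (raw predicted age in
    years).  `bias_fits` maps organ -> fitted :class:`~organ_age.bias.BiasFit`.
    Theta is computed per organ from the corrected PAGs of the full
    inference cohort by default; pass `theta_subset` (subject ids, e.g. the
    healthy subcohort) to restrict the threshold estimation.
    """
    ca = cohort.set_index("subject_id")["ca_at_imaging"]
    frames = []
    for organ, sub in predictions.groupby("organ", sort=True):
        sub = sub.copy()
        sub_ca = ca.loc[sub["subject_id"]].to_numpy()
        sub["pag_raw"] = sub["mu"].to_numpy() - sub_ca
        corrected = bias_fits[organ].correct(sub["mu"].to_numpy(), sub_ca)
        sub["pag_corrected"] = compute_pags(corrected, sub_ca)
        if theta_subset is not None:
            basis = sub.loc[sub["subject_id"].isin(set(theta_subset)),
                            "pag_corrected"]
        else:
            basis = sub["pag_corrected"]
        theta = compute_theta(basis)
        sub["theta"] = theta
        sub["group"] = stratify_aging(sub["pag_corrected"].to_numpy(), theta)
        frames.append(sub[["subject_id", "organ", "pag_raw", "pag_corrected",
                           "theta", "group"]])
    return pd.concat(frames, ignore_index=True)
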