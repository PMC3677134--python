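"""Multi-site reproducibility statistics.

Conventions follow the multi-centre validation design: the inter-site
coefficient of variation (CoV) is the N−1-normalized SD across sites divided
by the across-site mean, per volunteer; the intra-site CoV is the voxel
SD/mean within a small homogeneous ROI (caudate head, corpus-callosum genu),
averaged across sites; the inter-site bias is the percent deviation of each
site's mean from the grand mean across all sites and volunteers.  Hypothesis
tests: a two-way within-subject repeated-measures ANOVA over ROI (4 levels) ×
image type (parameter map vs T1w) and one-tailed paired t-tests, without
multiple-comparison correction across the four parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

INTRA_SITE_ROIS = ("caudate", "corpus-callosum")


def inter_site_cov(values) -> float:
    """100 · SD(N−1) / mean across per-site values (one volunteer)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("inter-site CoV needs at least two sites")
    m = v.mean()
    if abs(m) < 1e-12 * max(np.abs(v).max(), 1.0):
        return np.nan
    return float(100.0 * v.std(ddof=1) / m)


def cov_map(site_stack: np.ndarray) -> np.ndarray:
    """Voxel-wise across-site CoV (%), same N−1 convention; display-oriented."""
    if site_stack.shape[0] < 2:
        raise ValueError("need at least two sites")
    m = site_stack.mean(axis=0)
    sd = site_stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(np.abs(m) > 0, 100.0 * sd / m, np.nan)


def intra_site_cov(volume: np.ndarray, roi: np.ndarray, roi_name: str) -> float:
    """100 · voxel-SD / voxel-mean within a homogeneous ROI, one site.

    Restricted to the caudate head and corpus-callosum genu: in larger or
    mixed ROIs the voxel spread reflects tissue architecture rather than
    noise, so the measure would not estimate the intra-site variability.
    """
    if roi_name not in INTRA_SITE_ROIS:
        raise ValueError(
            f"intra-site CoV is only defined for homogeneous ROIs "
            f"{INTRA_SITE_ROIS}, not {roi_name!r}"
        )
    vals = volume[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size < 10:
        raise ValueError(f"ROI {roi_name!r} has fewer than 10 valid voxels")
    return float(100.0 * vals.std(ddof=1) / vals.mean())


def inter_site_bias(cells: pd.DataFrame, value_col: str = "value") -> pd.Series:
    """Per-site bias: 100 · (site mean − grand mean) / grand mean.

    ``cells`` must hold one row per (volunteer, site) with the ROI-averaged
    value; a missing cell of the full grid is an error.
    """
    grid = cells.pivot_table(
        index="volunteer", columns="site", values=value_col, aggfunc="mean"
    )
    if grid.isna().any().any():
        missing = [
            (v, s) for v in grid.index for s in grid.columns
            if pd.isna(grid.loc[v, s])
        ]
        raise ValueError(f"missing cells: {missing}")
    grand = grid.to_numpy().mean()
    return 100.0 * (grid.mean(axis=0) - grand) / grand


def gm_prob_cov(prob_maps: list[np.ndarray], gm_mask: np.ndarray) -> float:
    """Mean across-site CoV (%) of GM probability within the GM mask."""
    if len(prob_maps) < 2:
        raise ValueError("need GM probability maps from at least two sites")
    if not np.any(gm_mask):
        raise ValueError("GM mask is empty")
    stack = np.stack([p[gm_mask] for p in prob_maps], axis=0)
    m = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    ok = m > 0
    return float(100.0 * np.mean(sd[ok] / m[ok]))


def t_confidence_interval(values, level: float = 0.95):
    """t-based confidence interval of the mean across volunteers."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    half = stats.t.ppf(0.5 + level / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return m - half, m + half


def rm_anova(table: pd.DataFrame, depvar: str = "value") -> dict:
    """Two-way within-subject ANOVA with factors ``roi`` and ``type``.

    ``table`` needs columns subject/roi/type plus the dependent variable, one
    row per cell of a complete balanced design.  If only one ROI level is
    present the design collapses to a one-way ANOVA over ``type`` (whose F
    then equals the square of the paired t statistic).  Returns the F, p and
    degrees of freedom of the image-type main effect (and of ROI when present).
    """
    counts = table.groupby(["subject", "roi", "type"]).size()
    if counts.min() != 1 or counts.max() != 1:
        raise ValueError("design is unbalanced: need exactly one value per cell")
    within = ["roi", "type"] if table["roi"].nunique() > 1 else ["type"]
    res = AnovaRM(table, depvar=depvar, subject="subject", within=within).fit()
    tab = res.anova_table
    out = {
        "F_type": float(tab.loc["type", "F Value"]),
        "p_type": float(tab.loc["type", "Pr > F"]),
        "df_type": (
            float(tab.loc["type", "Num DF"]),
            float(tab.loc["type", "Den DF"]),
        ),
    }
    if "roi" in within:
        out.update(
            F_roi=float(tab.loc["roi", "F Value"]),
            p_roi=float(tab.loc["roi", "Pr > F"]),
        )
    return out


def paired_t(x, y, alternative: str = "greater"):
    """One-sided paired t-test on x − y (default alternative: x > y).

    Zero-variance differences are handled exactly: all-zero differences give
    t = 0 and one-sided p = 0.5; constant non-zero differences give p = 0 or 1
    by the sign of the effect relative to the alternative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 0.5
        favourable = d.mean() > 0 if alternative == "greater" else d.mean() < 0
        return (np.inf if favourable else -np.inf), (0.0 if favourable else 1.0)
    res = stats.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ReproReport:
    """Tidy tables of the reproducibility analysis."""

    cells: pd.DataFrame  # volunteer, site, parameter, roi, value
    inter_site: pd.DataFrame  # volunteer, parameter, roi, cov_percent
    intra_site: pd.DataFrame  # volunteer, parameter, roi, cov_percent
    bias: pd.DataFrame  # site, parameter, bias_percent
    gm_prob: pd.DataFrame  # volunteer, source, cov_percent
    tests: dict = field(default_factory=dict)

    def inter_site_summary(self) -> pd.DataFrame:
        """Mean ± SD of the inter-site CoV across volunteers per ROI/parameter."""
        return (
            self.inter_site.groupby(["parameter", "roi"])["cov_percent"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def intra_site_summary(self) -> pd.DataFrame:
        return (
            self.intra_site.groupby(["parameter", "roi"])["cov_percent"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def to_json_dict(self) -> dict:
        def records(df):
            return df.to_dict(orient="records")

        return {
            "cells": records(self.cells),
            "inter_site_cov": records(self.inter_site),
            "inter_site_cov_summary": records(self.inter_site_summary()),
            "intra_site_cov": records(self.intra_site),
            "intra_site_cov_summary": records(self.intra_site_summary()),
            "inter_site_bias": records(self.bias),
            "gm_probability_cov": records(self.gm_prob),
            "tests": self.tests,
        }
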