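"""Design-weighted descriptive estimation.

Point estimates are Hajek ratios sum(w*x)/sum(w); variances use Taylor
linearization with clusters as primary sampling units (the with-replacement
first-stage approximation standard for DHS-type surveys, clusters being the
only design information carried by the data). Confidence intervals are
computed on the logit scale and back-transformed, so they respect [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataset import SurveyDataset

__all__ = ["WeightedEstimate", "weighted_proportion", "coverage_by_subgroup", "category_percentages"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class WeightedEstimate:
    label: str
    n_unweighted: int
    proportion: float
    ci_low: float
    ci_high: float
    variance: float

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and not (
            self.ci_low - 1e-12 <= self.proportion <= self.ci_high + 1e-12
        ):
            raise ValueError("confidence interval must bracket the point estimate")


def weighted_proportion(
    values: np.ndarray,
    weights: np.ndarray,
    cluster_ids: np.ndarray,
    label: str = "overall",
) -> WeightedEstimate:
    """Design-weighted proportion with cluster-linearized variance.

    With a single cluster the point estimate is returned with the CI and
    variance marked undefined (NaN).
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    c = np.asarray(cluster_ids)
    if not (x.shape == w.shape == c.shape):
        raise ValueError("values, weights and cluster_ids must have equal length")
    if x.size == 0:
        return WeightedEstimate(label, 0, np.nan, np.nan, np.nan, np.nan)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")

    wtot = w.sum()
    p = float((w * x).sum() / wtot)

    clusters, cidx = np.unique(c, return_inverse=True)
    n_clust = clusters.size
    if n_clust < 2:
        return WeightedEstimate(label, x.size, p, np.nan, np.nan, np.nan)

    # linearized scores of the ratio estimator, totalled by PSU
    e = w * (x - p) / wtot
    totals = np.bincount(cidx, weights=e, minlength=n_clust)
    var = float(n_clust / (n_clust - 1) * np.sum(totals**2))

    if p <= 0.0 or p >= 1.0 or var == 0.0:
        return WeightedEstimate(label, x.size, p, p, p, var)
    se_logit = np.sqrt(var) / (p * (1 - p))
    lo = float(expit(logit(p) - _Z95 * se_logit))
    hi = float(expit(logit(p) + _Z95 * se_logit))
    return WeightedEstimate(label, x.size, p, lo, hi, var)


def coverage_by_subgroup(
    dataset: SurveyDataset,
    indicator: pd.DataFrame,
    grouping: str | None = None,
) -> list[WeightedEstimate]:
    """Weighted mDFPS coverage overall (grouping=None) or per category.

    The denominator is restricted to demand-positive women. Categories with
    zero demand-positive records are reported with NaN estimates rather
    than dropped.
    """
    if grouping is not None and grouping not in dataset.women.columns:
        raise KeyError(f"unknown grouping field: {grouping!r}")
    df = dataset.women.merge(indicator, on="woman_id")
    df = df[df["has_demand"].astype(bool)]
    if grouping is None:
        return [
            weighted_proportion(
                df["mdfps"].astype(bool).to_numpy(dtype=float),
                df["weight"].to_numpy(),
                df["cluster_id"].to_numpy(),
                label="overall",
            )
        ]
    out = []
    categories = dataset.women[grouping].dropna().unique()
    for cat in sorted(map(str, categories)):
        sub = df[df[grouping].astype(str) == cat]
        if len(sub) == 0:
            out.append(WeightedEstimate(cat, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        out.append(
            weighted_proportion(
                sub["mdfps"].astype(bool).to_numpy(dtype=float),
                sub["weight"].to_numpy(),
                sub["cluster_id"].to_numpy(),
                label=cat,
            )
        )
    return out


def category_percentages(dataset: SurveyDataset, field: str) -> pd.DataFrame:
    """Weighted category percentages of one respondent characteristic.

    Mirrors a descriptive characteristics table: weighted percent plus
    unweighted n per category; percentages of the partition sum to 100.
    """
    if field not in dataset.women.columns:
        raise KeyError(f"unknown field: {field!r}")
    df = dataset.women
    w = df["weight"]
    rows = []
    for cat, sub in df.groupby(field, observed=True):
        rows.append(
            {
                "field": field,
                "category": cat,
                "n": len(sub),
                "percent": 100.0 * sub["weight"].sum() / w.sum(),
            }
        )
    return pd.DataFrame(rows)


def descriptives_table(
    dataset: SurveyDataset,
    indicator: pd.DataFrame,
    groupings: list[str],
) -> pd.DataFrame:
    """Tidy coverage-by-characteristics table across several groupings."""
    rows = []
    for est in coverage_by_subgroup(dataset, indicator, None):
        rows.append(_row("overall", est))
    for g in groupings:
        for est in coverage_by_subgroup(dataset, indicator, g):
            rows.append(_row(g, est))
    return pd.DataFrame(rows)


def _row(grouping: str, est: WeightedEstimate) -> dict:
    return {
        "grouping": grouping,
        "category": est.label,
        "n": est.n_unweighted,
        "proportion": est.proportion,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
    }
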