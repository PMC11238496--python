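"""Survey data containers.

A :class:`SurveyDataset` bundles one period's woman-level records with the
geolocated clusters they belong to. Women are a plain DataFrame (one row
per respondent, documented column dictionary in the README); clusters carry
projected km coordinates and admin-unit membership.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurveyDataset", "WOMAN_COLUMNS", "aggregate_cluster_counts"]

#: Column dictionary for woman-level records.
WOMAN_COLUMNS = {
    "woman_id": "unique respondent identifier",
    "cluster_id": "primary sampling unit (enumeration area) identifier",
    "age_years": "age in completed years, 15-49",
    "residence": "urban | rural",
    "age_group": "15-24 | 25-34 | 35-49",
    "education": "none | primary | secondary_or_higher",
    "head_sex": "male | female household head",
    "wealth_quintile": "poorest | poorer | middle | richer | richest",
    "marital_status": "in_union | never_in_union | formerly_in_union",
    "religion": "configurable categorical (default islam/orthodox/other_christian/other)",
    "parity": "number of live births (non-negative integer)",
    "parity_group": "none | 1-2 | 3-4 | 5plus",
    "pregnant": "currently pregnant (bool)",
    "fecund": "physiologically able to conceive (bool)",
    "fertility_preference": "wants_soon | wants_to_space | wants_to_limit",
    "current_method": "contraceptive method code or 'none'",
    "weight": "positive sampling weight (mean ~1)",
}


@dataclass
class SurveyDataset:
    """One period's survey: woman records plus geolocated clusters."""

    period: str
    women: pd.DataFrame
    clusters: pd.DataFrame  # cluster_id, x_km, y_km, admin_id

    def __post_init__(self) -> None:
        missing = set(self.women["cluster_id"]) - set(self.clusters["cluster_id"])
        if missing:
            raise ValueError(f"woman records reference unknown clusters: {sorted(missing)[:5]}")
        if (self.women["weight"] <= 0).any():
            raise ValueError("sampling weights must be positive")

    @property
    def n_women(self) -> int:
        return len(self.women)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def region_of_cluster(self) -> pd.Series:
        return self.clusters.set_index("cluster_id")["admin_id"]

    def write(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        self.women.to_csv(os.path.join(directory, f"women_{self.period}.csv"), index=False)
        self.clusters.to_csv(os.path.join(directory, f"clusters_{self.period}.csv"), index=False)

    @classmethod
    def read(cls, directory: str, period: str) -> "SurveyDataset":
        women = pd.read_csv(os.path.join(directory, f"women_{period}.csv"))
        clusters = pd.read_csv(os.path.join(directory, f"clusters_{period}.csv"))
        return cls(period=period, women=women, clusters=clusters)


def aggregate_cluster_counts(dataset: SurveyDataset, indicator: pd.DataFrame) -> pd.DataFrame:
    """Collapse woman-level indicator results to cluster-level binomial counts.

    Returns a frame with cluster_id, x_km, y_km, admin_id, n_demand (trials
    N_i) and n_satisfied (successes x_i), restricted to clusters with at
    least one demand-positive woman. Sampling weights do not enter: the
    geostatistical likelihood is on raw counts.
    """
    merged = dataset.women[["woman_id", "cluster_id"]].merge(indicator, on="woman_id")
    demand = merged[merged["has_demand"].astype(bool)]
    grp = demand.groupby("cluster_id")
    counts = pd.DataFrame(
        {
            "n_demand": grp.size(),
            "n_satisfied": grp["mdfps"].apply(lambda s: int(s.astype(bool).sum())),
        }
    ).reset_index()
    out = counts.merge(dataset.clusters, on="cluster_id", how="left")
    return out[["cluster_id", "x_km", "y_km", "admin_id", "n_demand", "n_satisfied"]]
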