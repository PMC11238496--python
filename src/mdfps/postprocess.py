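"""Decision products from posterior prevalence surfaces.

Aggregates pixel-level posterior samples to admin-unit and national
summaries, computes exceedance probabilities against the WHO minimum
coverage target (75% by default), and compares two fitted periods via the
mean posterior change (MPC, in percentage points) with EP(change > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AdminUnits
from .geostat import PosteriorSurface

__all__ = [
    "AreaSummary",
    "ChangeSummary",
    "WHO_TARGET",
    "aggregate_area",
    "exceedance",
    "summarize_area",
    "change_analysis",
    "classify_progress",
]

WHO_TARGET = 0.75

NATIONAL_ID = -1  # area_id used for the national (all unmasked pixels) aggregate


@dataclass(frozen=True)
class AreaSummary:
    area_id: int
    period: str
    posterior_mean: float
    ci_low: float
    ci_high: float
    ep: float
    threshold: float

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.posterior_mean <= self.ci_high + 1e-12):
            raise ValueError("credible interval must bracket the posterior mean")
        if not (0.0 <= self.ep <= 1.0):
            raise ValueError("exceedance probability must lie in [0, 1]")


@dataclass(frozen=True)
class ChangeSummary:
    area_id: int
    mpc: float  # percentage points, period2 - period1
    ci_low: float
    ci_high: float
    ep_increase: float

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-9 <= self.mpc <= self.ci_high + 1e-9):
            raise ValueError("MPC must lie inside its credible interval")
        if not (0.0 <= self.ep_increase <= 1.0):
            raise ValueError("ep_increase must lie in [0, 1]")


def aggregate_area(
    surface: PosteriorSurface,
    admin: AdminUnits,
    weights: np.ndarray | None = None,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Per-draw area means over member pixels (centre-in-polygon membership).

    ``weights``, when given, is a per-pixel weight layer of grid shape
    (e.g. population density); area values are weighted pixel means. The
    second return value is the national aggregate over all unmasked pixels.
    Raises for any polygon containing no unmasked pixel centre.
    """
    centers = surface.pixel_centers()
    member = admin.locate(centers[:, 0], centers[:, 1])
    if weights is None:
        w = np.ones(len(centers))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape == (surface.grid.ny, surface.grid.nx):
            w = w.ravel()[surface.mask.ravel()]
        if w.shape != (len(centers),):
            raise ValueError("weights must match the grid or the unmasked pixels")
        if np.any(w < 0):
            raise ValueError("pixel weights must be non-negative")

    area_samples: dict[int, np.ndarray] = {}
    for area_id in admin.ids:
        sel = member == area_id
        if not sel.any():
            raise ValueError(f"polygon {area_id} contains no unmasked pixel centres")
        wsel = w[sel]
        if wsel.sum() <= 0:
            raise ValueError(f"polygon {area_id} has zero total pixel weight")
        area_samples[area_id] = surface.samples[:, sel] @ (wsel / wsel.sum())
    national = surface.samples @ (w / w.sum())
    return area_samples, national


def exceedance(samples: np.ndarray, t: float) -> float:
    """Fraction of posterior samples strictly greater than the threshold t."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    if np.any(~np.isfinite(samples)):
        raise ValueError("samples must be finite")
    return float(np.mean(samples > t))


def summarize_area(
    area_samples: dict[int, np.ndarray],
    t: float = WHO_TARGET,
    period: str = "",
) -> list[AreaSummary]:
    """Posterior mean, central 95% CI and EP(t) per area."""
    out = []
    for area_id, draws in area_samples.items():
        draws = np.asarray(draws, dtype=float)
        if draws.size < 100:
            warnings.warn(
                f"area {area_id}: only {draws.size} posterior draws (>=100 recommended)",
                stacklevel=2,
            )
        out.append(
            AreaSummary(
                area_id=int(area_id),
                period=period,
                posterior_mean=float(draws.mean()),
                ci_low=float(np.quantile(draws, 0.025)),
                ci_high=float(np.quantile(draws, 0.975)),
                ep=exceedance(draws, t),
                threshold=t,
            )
        )
    return out


def _pair_draws(
    a: np.ndarray, b: np.ndarray, pairing: str, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    if pairing == "indexed":
        if len(a) != len(b):
            raise ValueError("indexed pairing requires equal draw counts")
        return a, b
    if pairing != "independent":
        raise ValueError(f"unknown pairing {pairing!r}")
    n = min(len(a), len(b))
    rng = np.random.default_rng(seed)
    return a[rng.integers(0, len(a), n)], b[rng.integers(0, len(b), n)]


def change_analysis(
    surface_t1: PosteriorSurface,
    surface_t2: PosteriorSurface,
    admin: AdminUnits,
    weights: np.ndarray | None = None,
    pairing: str = "independent",
    seed: int = 0,
) -> tuple[list[ChangeSummary], ChangeSummary]:
    """Between-period change per area and nationally.

    Per paired draw, change = area(t2) - area(t1) in percentage points; MPC
    is the mean of change draws, with a central 95% CI and
    ep_increase = EP(change > 0). Draw pairing across the two independently
    fitted posteriors is independent resampling with a recorded seed by
    default (so identical posteriors give ep_increase ~ 0.5); "indexed"
    pairing is available when draw counts match.
    """
    if surface_t1.grid.signature() != surface_t2.grid.signature() or not np.array_equal(
        surface_t1.mask, surface_t2.mask
    ):
        raise ValueError(
            "surfaces are on different grids: "
            f"{surface_t1.grid.signature()} vs {surface_t2.grid.signature()}"
        )
    a1, nat1 = aggregate_area(surface_t1, admin, weights)
    a2, nat2 = aggregate_area(surface_t2, admin, weights)

    def summarize(d1: np.ndarray, d2: np.ndarray, area_id: int, sub_seed: int) -> ChangeSummary:
        x1, x2 = _pair_draws(d1, d2, pairing, sub_seed)
        change = 100.0 * (x2 - x1)
        return ChangeSummary(
            area_id=area_id,
            mpc=float(change.mean()),
            ci_low=float(np.quantile(change, 0.025)),
            ci_high=float(np.quantile(change, 0.975)),
            ep_increase=exceedance(change, 0.0),
        )

    summaries = [
        summarize(a1[i], a2[i], int(i), seed + k + 1) for k, i in enumerate(admin.ids)
    ]
    national = summarize(nat1, nat2, NATIONAL_ID, seed)
    return summaries, national


def classify_progress(
    summaries: list[ChangeSummary], hi: float = 0.9, lo: float = 0.1
) -> dict[int, str]:
    """Label each area improving / reversing / indeterminate from EP(change>0).

    An area is improving when ep_increase >= hi (default 0.9), reversing
    when ep_increase <= lo (default 0.1), indeterminate otherwise.
    """
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("need 0 < lo < hi < 1")
    out = {}
    for s in summaries:
        if s.ep_increase >= hi:
            out[s.area_id] = "improving"
        elif s.ep_increase <= lo:
            out[s.area_id] = "reversing"
        else:
            out[s.area_id] = "indeterminate"
    return out


def area_table(summaries: list[AreaSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def change_table(summaries: list[ChangeSummary], labels: dict[int, str] | None = None) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in summaries])
    if labels is not None:
        df["progress"] = df["area_id"].map(labels)
    return df
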