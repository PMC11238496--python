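"""DHS-like synthetic surveys with known ground truth.

Every downstream stage (indicator, descriptives, multilevel, geostat,
postprocess) is exercised against data from this generator, whose
parameters — regression coefficients on the logit scale, nested
random-effect standard deviations, Matérn hyperparameters, a between-period
coverage shift — are recorded so each stage has a parameter-recovery test
surface. Two latent mechanisms are available: nested region/cluster random
effects (the multilevel model's data-generating process) and a Matérn
Gaussian process evaluated at cluster coordinates (the geostatistical
model's).

Coefficient keys in ``GroundTruth.beta`` follow one convention:
``"intercept"``; ``"field=level"`` for a woman-level categorical dummy
(e.g. ``"residence=rural"``); a bare raster layer name for a cluster-level
covariate effect on the standardized layer (e.g. ``"education_years"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import zoom
from scipy.spatial.distance import cdist
from scipy.special import expit

from .dataset import SurveyDataset
from .geometry import AdminUnits, GridSpec, make_admin_grid
from .geostat import MaternParams, _chol_with_escalating_jitter, matern_correlation
from .rasters import CovariateStack

__all__ = [
    "GroundTruth",
    "SyntheticSurveyBundle",
    "simulate_covariate_rasters",
    "simulate_survey",
    "simulate_bundle",
    "DEFAULT_MARGINALS",
]

# Category frequencies emulating a rural East-African DHS respondent profile.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "residence": {"urban": 0.19, "rural": 0.81},
    "age_group": {"15-24": 0.233, "25-34": 0.459, "35-49": 0.308},
    "education": {"secondary_or_higher": 0.126, "primary": 0.304, "none": 0.570},
    "head_sex": {"male": 0.843, "female": 0.157},
    "wealth_quintile": {
        "poorest": 0.153,
        "poorer": 0.199,
        "middle": 0.209,
        "richer": 0.203,
        "richest": 0.236,
    },
    "marital_status": {"in_union": 0.936, "never_in_union": 0.022, "formerly_in_union": 0.042},
    "religion": {"islam": 0.296, "orthodox": 0.456, "other_christian": 0.236, "other": 0.012},
    "parity_group": {"none": 0.087, "1-2": 0.284, "3-4": 0.251, "5plus": 0.378},
}

_AGE_RANGES = {"15-24": (15, 24), "25-34": (25, 34), "35-49": (35, 49)}
_PARITY_RANGES = {"none": (0, 0), "1-2": (1, 2), "3-4": (3, 4), "5plus": (5, 9)}

_BACKFILL_MODERN = ["pills", "injectables", "implants", "condom_male", "iud"]
_BACKFILL_TRADITIONAL = ["withdrawal", "rhythm"]

DEFAULT_COVARIATE_LAYERS = [
    "education_years",
    "population_density",
    "care_seeking_probability",
    "poverty_rate",
    "mean_parity",
]


@dataclass
class GroundTruth:
    """Generator parameters; everything downstream models try to recover."""

    beta: dict[str, float]
    sigma_region: float = 0.0
    sigma_cluster: float = 0.0
    gp_variance: float = 1.0
    gp_range: float = 25.0
    gp_smoothness: float = 1.5
    period_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_region < 0 or self.sigma_cluster < 0:
            raise ValueError("random-effect standard deviations must be >= 0")
        if self.gp_variance <= 0 or self.gp_range <= 0:
            raise ValueError("gp_variance and gp_range must be > 0")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "beta": {k: float(v) for k, v in self.beta.items()},
                    "sigma_region": float(self.sigma_region),
                    "sigma_cluster": float(self.sigma_cluster),
                    "gp_variance": float(self.gp_variance),
                    "gp_range": float(self.gp_range),
                    "gp_smoothness": float(self.gp_smoothness),
                    "period_shift": float(self.period_shift),
                    "seed": int(self.seed),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SyntheticSurveyBundle:
    """Two-period synthetic study: surveys, geography, rasters and their truth."""

    surveys: dict[str, SurveyDataset]
    admin_units: AdminUnits
    covariates: dict[str, CovariateStack]
    truth: GroundTruth

    @property
    def periods(self) -> list[str]:
        return sorted(self.surveys)


def _smooth_field(grid: GridSpec, rng: np.random.Generator, coarse: int = 6) -> np.ndarray:
    """Low-frequency standard-normal-ish field by bicubic upsampling of coarse noise."""
    base = rng.standard_normal((coarse, coarse))
    out = zoom(base, (grid.ny / coarse, grid.nx / coarse), order=3, mode="nearest")
    return out[: grid.ny, : grid.nx]


def simulate_covariate_rasters(
    grid: GridSpec,
    truth: GroundTruth | None = None,
    seed: int | None = None,
    layers: list[str] | None = None,
) -> CovariateStack:
    """Spatially smooth covariate layers with realistic marginal ranges.

    Probability-type layers are kept in [0, 1] by construction (inverse
    logit); education years, density and parity are positive.
    """
    if grid.n_pixels < 4:
        raise ValueError("grid must have at least 4 pixels")
    if seed is None:
        seed = truth.seed if truth is not None else 0
    rng = np.random.default_rng(seed)
    layers = list(layers) if layers is not None else list(DEFAULT_COVARIATE_LAYERS)
    built: dict[str, np.ndarray] = {}
    for name in layers:
        f = _smooth_field(grid, rng)
        if name == "education_years":
            built[name] = 4.0 * np.exp(0.5 * f)
        elif name == "population_density":
            built[name] = np.exp(4.0 + 1.0 * f)
        elif name == "care_seeking_probability":
            built[name] = expit(0.5 + 0.8 * f)
        elif name == "poverty_rate":
            built[name] = expit(-0.5 + 0.8 * f)
        elif name == "mean_parity":
            built[name] = np.clip(3.0 + 1.0 * f, 0.0, None)
        else:  # generic standardized smooth layer
            built[name] = f
    return CovariateStack(grid=grid, layers=built)


def _sample_cluster_coords(
    admin_units: AdminUnits, n_clusters: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform cluster coordinates, allocated to regions proportional to area."""
    alloc = _allocate_clusters(admin_units, n_clusters)
    coords, admin_of_cluster = [], []
    for admin_id, k in zip(admin_units.ids, alloc):
        if k == 0:
            continue
        pts = admin_units.sample_points(admin_id, k, rng)
        coords.append(pts)
        admin_of_cluster.extend([admin_id] * k)
    return np.vstack(coords), np.asarray(admin_of_cluster)


def _allocate_clusters(admin: AdminUnits, n_clusters: int) -> list[int]:
    """Clusters per region, proportional to area (largest-remainder rounding)."""
    areas = np.array([p.area for p in admin.polygons], dtype=float)
    quota = n_clusters * areas / areas.sum()
    alloc = np.floor(quota).astype(int)
    short = n_clusters - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:short]] += 1
    return alloc.tolist()


def _draw_categories(
    rng: np.random.Generator, n: int, marginals: dict[str, dict[str, float]]
) -> pd.DataFrame:
    cols = {}
    for fieldname, dist in marginals.items():
        levels = list(dist)
        probs = np.array([dist[lv] for lv in levels], dtype=float)
        probs = probs / probs.sum()
        cols[fieldname] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(cols)


def simulate_survey(
    truth: GroundTruth,
    admin_units: AdminUnits,
    covariates: CovariateStack | None,
    n_clusters: int,
    n_women_per_cluster: int,
    mechanism: str,
    period: str = "t1",
    seed: int | None = None,
    apply_shift: bool = False,
    shift_region_ids: list[int] | None = None,
    demand_rate: float = 0.84,
    marginals: dict | None = None,
    coords: np.ndarray | None = None,
    latent: np.ndarray | None = None,
) -> SurveyDataset:
    """One synthetic survey with the chosen latent mechanism.

    mechanism="multilevel": independent Normal region and cluster effects
    with truth.sigma_region / truth.sigma_cluster.
    mechanism="geostatistical": a Matérn GP (truth.gp_variance,
    truth.gp_range, truth.gp_smoothness) evaluated at cluster coordinates.
    With apply_shift, truth.period_shift is added to the linear predictor
    (in shift_region_ids only, when given — a regionally localized
    improvement).

    Raw contraception fields are back-filled to be consistent with the
    simulated outcome, so the indicator module reconstructs the intended
    (demand, mdfps) flags exactly; the intended flags are kept in
    ``sim_demand`` / ``sim_mdfps`` for verification.
    """
    if mechanism not in ("multilevel", "geostatistical"):
        raise ValueError(f"unknown mechanism: {mechanism!r}")
    if n_clusters < 2:
        raise ValueError("need n_clusters >= 2")
    if n_women_per_cluster < 1:
        raise ValueError("need n_women_per_cluster >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    marginals = marginals or DEFAULT_MARGINALS

    if coords is None:
        coords, admin_of_cluster = _sample_cluster_coords(admin_units, n_clusters, rng)
    else:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n_clusters, 2):
            raise ValueError("coords must be (n_clusters, 2)")
        admin_of_cluster = admin_units.locate(coords[:, 0], coords[:, 1])
        if np.any(admin_of_cluster < 0):
            raise ValueError("supplied cluster coordinates fall outside the admin units")
    cluster_ids = np.arange(1, n_clusters + 1)

    clusters = pd.DataFrame(
        {
            "cluster_id": cluster_ids,
            "x_km": coords[:, 0],
            "y_km": coords[:, 1],
            "admin_id": admin_of_cluster,
        }
    )  # sim_latent (the realized latent term per cluster) is appended below

    # latent spatial / hierarchical term per cluster
    if latent is not None:
        latent = np.asarray(latent, dtype=float)
        if latent.shape != (n_clusters,):
            raise ValueError("latent must have one value per cluster")
    elif mechanism == "multilevel":
        region_index = {a: i for i, a in enumerate(admin_units.ids)}
        region_eff = truth.sigma_region * rng.standard_normal(len(admin_units))
        cluster_eff = truth.sigma_cluster * rng.standard_normal(n_clusters)
        latent = cluster_eff + region_eff[[region_index[a] for a in admin_of_cluster]]
    else:
        corr = matern_correlation(cdist(coords, coords), truth.gp_range, truth.gp_smoothness)
        L = _chol_with_escalating_jitter(corr, 1e-8)
        latent = np.sqrt(truth.gp_variance) * (L @ rng.standard_normal(n_clusters))

    clusters["sim_latent"] = latent

    shift = np.zeros(n_clusters)
    if apply_shift:
        if shift_region_ids is None:
            shift[:] = truth.period_shift
        else:
            shift[np.isin(admin_of_cluster, shift_region_ids)] = truth.period_shift

    n = n_clusters * n_women_per_cluster
    cluster_idx = np.repeat(np.arange(n_clusters), n_women_per_cluster)
    women = _draw_categories(rng, n, marginals)
    women.insert(0, "woman_id", np.arange(1, n + 1))
    women.insert(1, "cluster_id", cluster_ids[cluster_idx])

    lo, hi = np.vectorize(lambda g: _AGE_RANGES[g])(women["age_group"])
    women["age_years"] = rng.integers(lo, hi + 1)
    plo, phi_ = np.vectorize(lambda g: _PARITY_RANGES[g])(women["parity_group"])
    women["parity"] = rng.integers(plo, phi_ + 1)

    # linear predictor from truth.beta
    eta = np.zeros(n)
    cluster_cov = None
    for key, coef in truth.beta.items():
        if key == "intercept":
            eta += coef
        elif "=" in key:
            fieldname, level = key.split("=", 1)
            if fieldname not in women.columns:
                raise ValueError(f"beta references unknown woman field {fieldname!r}")
            eta += coef * (women[fieldname].to_numpy() == level)
        else:
            if covariates is None or key not in covariates.names:
                raise ValueError(f"covariate stack missing layer {key!r} referenced by beta")
            if cluster_cov is None:
                cluster_cov = {}
            if key not in cluster_cov:
                from .rasters import extract_covariates

                cluster_cov[key] = extract_covariates(covariates, coords, True, [key])[:, 0]
            eta += coef * cluster_cov[key][cluster_idx]
    eta += latent[cluster_idx] + shift[cluster_idx]

    has_demand = rng.uniform(size=n) < demand_rate
    outcome = np.zeros(n, dtype=bool)
    outcome[has_demand] = rng.uniform(size=int(has_demand.sum())) < expit(eta[has_demand])

    # back-fill raw fields consistently with (has_demand, outcome)
    fecund = np.ones(n, dtype=bool)
    pregnant = np.zeros(n, dtype=bool)
    pref = np.empty(n, dtype=object)
    method = np.full(n, "none", dtype=object)

    demand_idx = np.flatnonzero(has_demand)
    pref[demand_idx] = rng.choice(["wants_to_space", "wants_to_limit"], size=demand_idx.size)
    sat = demand_idx[outcome[demand_idx]]
    unsat = demand_idx[~outcome[demand_idx]]
    method[sat] = rng.choice(_BACKFILL_MODERN, size=sat.size)
    trad = unsat[rng.uniform(size=unsat.size) < 0.3]
    method[trad] = rng.choice(_BACKFILL_TRADITIONAL, size=trad.size)

    nod = np.flatnonzero(~has_demand)
    pref[nod] = "wants_soon"
    u = rng.uniform(size=nod.size)
    fecund[nod[u < 0.5]] = False  # infecund
    pregnant[nod[u >= 0.9]] = True  # pregnant non-users (no current demand)

    women["pregnant"] = pregnant
    women["fecund"] = fecund
    women["fertility_preference"] = pref
    women["current_method"] = method

    w = rng.lognormal(mean=0.0, sigma=0.3, size=n)
    women["weight"] = w / w.mean()
    women["sim_demand"] = has_demand.astype(int)
    women["sim_mdfps"] = np.where(has_demand, outcome.astype(float), np.nan)

    return SurveyDataset(period=period, women=women, clusters=clusters)


def simulate_bundle(
    truth: GroundTruth,
    n_regions: int = 10,
    extent_km: float = 160.0,
    n_clusters: int = 300,
    n_women_per_cluster: int = 20,
    mechanism: str = "geostatistical",
    pixel_km: float = 5.0,
    periods: tuple[str, str] = ("t1", "t2"),
    shift_region_ids: list[int] | None = None,
    demand_rate: float = 0.84,
    shared_field: bool = True,
) -> SyntheticSurveyBundle:
    """Paired two-period synthetic study on a shared admin geography.

    Period 2 receives ``truth.period_shift`` on the logit scale (optionally
    only inside ``shift_region_ids``); each period gets its own clusters and
    covariate rasters, emulating two independent survey rounds. With
    ``shared_field`` (geostatistical mechanism only) the two periods share
    one latent spatial realization — drawn jointly over both periods'
    cluster locations — emulating geographic patterns that persist between
    survey rounds; the between-period difference is then the period shift
    alone, up to sampling noise.
    """
    if len(periods) != 2 or periods[0] == periods[1]:
        raise ValueError("exactly two distinct period labels are required")
    admin = make_admin_grid(n_regions, extent_km)
    grid = GridSpec(
        0.0, 0.0, pixel_km, int(round(extent_km / pixel_km)), int(round(extent_km / pixel_km))
    )
    seeds = np.random.SeedSequence(truth.seed).generate_state(6) % (2**31 - 1)

    coords = {p: None for p in periods}
    latent = {p: None for p in periods}
    if shared_field and mechanism == "geostatistical":
        rng = np.random.default_rng(seeds[4])
        c1, _ = _sample_cluster_coords(admin, n_clusters, rng)
        c2, _ = _sample_cluster_coords(admin, n_clusters, rng)
        both = np.vstack([c1, c2])
        corr = matern_correlation(cdist(both, both), truth.gp_range, truth.gp_smoothness)
        L = _chol_with_escalating_jitter(corr, 1e-8)
        s_all = np.sqrt(truth.gp_variance) * (L @ rng.standard_normal(len(both)))
        coords = {periods[0]: c1, periods[1]: c2}
        latent = {periods[0]: s_all[:n_clusters], periods[1]: s_all[n_clusters:]}

    surveys, stacks = {}, {}
    for j, period in enumerate(periods):
        stack = simulate_covariate_rasters(grid, seed=int(seeds[2 * j]))
        survey = simulate_survey(
            truth,
            admin,
            stack,
            n_clusters,
            n_women_per_cluster,
            mechanism,
            period=period,
            seed=int(seeds[2 * j + 1]),
            apply_shift=(j == 1),
            shift_region_ids=shift_region_ids,
            demand_rate=demand_rate,
            coords=coords[period],
            latent=latent[period],
        )
        surveys[period] = survey
        stacks[period] = stack
    return SyntheticSurveyBundle(surveys=surveys, admin_units=admin, covariates=stacks, truth=truth)
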