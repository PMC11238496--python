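"""Three-level Bayesian logistic regression for mDFPS determinants.

Women (level 1) are nested in clusters (level 2) nested in regions
(level 3):

    logit P(y_kji = 1) = beta0 + beta' X_kji + u_i + v_ji,
    u_i ~ N(0, sigma2_region),  v_ji ~ N(0, sigma2_cluster),

fitted by Hamiltonian MCMC on a non-centred parameterisation with
Normal(0, 10^2) priors on coefficients and half-Normal(0, 1) priors on the
random-effect standard deviations. The likelihood is unweighted: sampling
weights enter the descriptive estimates only. Coefficients are reported as
adjusted odds ratios with central 95% credible intervals; variance
components on the variance scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import SurveyDataset
from .samplers import ess, rhat, run_chains

logger = logging.getLogger(__name__)

__all__ = [
    "DesignBundle",
    "MultilevelLogistic",
    "build_design",
    "log_posterior",
    "fit_multilevel",
    "summarize_or",
    "DEFAULT_REFERENCE",
]

#: Default reference levels (the most advantaged / modal categories).
DEFAULT_REFERENCE = {
    "residence": "urban",
    "age_group": "35-49",
    "education": "secondary_or_higher",
    "head_sex": "male",
    "wealth_quintile": "richest",
    "marital_status": "in_union",
    "religion": "islam",
    "parity_group": "3-4",
}

DEFAULT_COVARIATES = list(DEFAULT_REFERENCE)


@dataclass
class DesignBundle:
    y: np.ndarray                  # outcome 0/1, demand-positive women only
    X: np.ndarray                  # dummy-coded covariates, reference levels omitted
    columns: list[tuple[str, str]]  # (field, level) per X column
    cluster_idx: np.ndarray        # 0-based dense cluster index per row
    region_idx: np.ndarray         # 0-based dense region index per row
    region_of_cluster: np.ndarray  # region index of each cluster (nested consistency)
    n_clusters: int = 0
    n_regions: int = 0

    def __post_init__(self) -> None:
        self.n_clusters = int(self.cluster_idx.max()) + 1 if self.cluster_idx.size else 0
        self.n_regions = int(self.region_idx.max()) + 1 if self.region_idx.size else 0


def build_design(
    dataset: SurveyDataset,
    indicator: pd.DataFrame,
    covariates: list[str] | None = None,
    reference: dict[str, str] | None = None,
) -> DesignBundle:
    """Outcome vector, dummy matrix and nested indices for demand-positive women."""
    covariates = list(covariates if covariates is not None else DEFAULT_COVARIATES)
    reference = dict(DEFAULT_REFERENCE if reference is None else reference)

    df = dataset.women.merge(indicator, on="woman_id")
    df = df[df["has_demand"].astype(bool)].reset_index(drop=True)
    y = df["mdfps"].astype(bool).to_numpy(dtype=float)

    cols, names = [], []
    for fieldname in covariates:
        if fieldname not in df.columns:
            raise KeyError(f"covariate field {fieldname!r} not in woman records")
        ref = reference.get(fieldname)
        observed = sorted(map(str, df[fieldname].dropna().unique()))
        if ref is None:
            ref = observed[0]
        if ref not in observed:
            raise ValueError(
                f"reference level {ref!r} of field {fieldname!r} absent from the data "
                f"(observed: {observed})"
            )
        for level in observed:
            if level == ref:
                continue
            cols.append((df[fieldname].astype(str) == level).to_numpy(dtype=float))
            names.append((fieldname, level))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))

    clusters, cluster_idx = np.unique(df["cluster_id"].to_numpy(), return_inverse=True)
    region_of = dataset.region_of_cluster()
    region_ids = region_of.loc[clusters].to_numpy()
    regions, region_of_cluster = np.unique(region_ids, return_inverse=True)
    region_idx = region_of_cluster[cluster_idx]

    return DesignBundle(
        y=y,
        X=X,
        columns=names,
        cluster_idx=cluster_idx,
        region_idx=region_idx,
        region_of_cluster=region_of_cluster,
    )


def log_posterior(
    design: DesignBundle,
    beta: np.ndarray,
    region_effects: np.ndarray,
    cluster_effects: np.ndarray,
    sigma2_region: float,
    sigma2_cluster: float,
    prior_beta_sd: float = 10.0,
    prior_sigma_sd: float = 1.0,
) -> float:
    """Joint log density of Eq.-style three-level logistic model (centred form).

    Bernoulli-logit likelihood + Normal(0, sigma2) densities of the region
    and cluster effects + Normal prior on beta (including the intercept as
    beta[0]) + half-Normal priors on the random-effect sds. Non-positive
    variances return -inf (rejected region).
    """
    if sigma2_region <= 0 or sigma2_cluster <= 0:
        return -np.inf
    beta = np.asarray(beta, dtype=float)
    u = np.asarray(region_effects, dtype=float)
    v = np.asarray(cluster_effects, dtype=float)
    Xb = design.X @ beta[1:] if beta.size > 1 else 0.0
    eta = beta[0] + Xb + u[design.region_idx] + v[design.cluster_idx]
    ll = float(np.sum(design.y * eta - np.logaddexp(0.0, eta)))
    lp = ll
    lp += -0.5 * np.sum(u**2) / sigma2_region - 0.5 * u.size * np.log(2 * np.pi * sigma2_region)
    lp += -0.5 * np.sum(v**2) / sigma2_cluster - 0.5 * v.size * np.log(2 * np.pi * sigma2_cluster)
    lp += float(
        -0.5 * np.sum(beta**2) / prior_beta_sd**2
        - beta.size * 0.5 * np.log(2 * np.pi * prior_beta_sd**2)
    )
    for s2 in (sigma2_region, sigma2_cluster):
        s = np.sqrt(s2)
        lp += -0.5 * s2 / prior_sigma_sd**2 + 0.5 * np.log(2 / (np.pi * prior_sigma_sd**2))
    return float(lp)


class MultilevelLogistic:
    """Three-level Bayesian logistic model, sklearn-style estimator.

    Fitted attributes: ``beta_draws_`` (draws x [intercept + dummies]),
    ``sigma2_cluster_draws_``, ``sigma2_region_draws_``, ``columns_``,
    ``diagnostics_``. The fit raises if split-Rhat of any reported
    parameter exceeds ``max_rhat``.
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        reference: dict[str, str] | None = None,
        prior_beta_sd: float = 10.0,
        prior_sigma_sd: float = 1.0,
        n_chains: int = 2,
        n_warmup: int = 400,
        n_draws: int = 400,
        seed: int = 0,
        max_leapfrog: int = 24,
        target_accept: float = 0.8,
        max_rhat: float = 1.05,
        max_divergent_frac: float = 0.1,
        check_convergence: bool = True,
    ):
        self.covariates = covariates
        self.reference = reference
        self.prior_beta_sd = prior_beta_sd
        self.prior_sigma_sd = prior_sigma_sd
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.seed = seed
        self.max_leapfrog = max_leapfrog
        self.target_accept = target_accept
        self.max_rhat = max_rhat
        self.max_divergent_frac = max_divergent_frac
        self.check_convergence = check_convergence

    def get_params(self, deep: bool = True) -> dict:
        import inspect

        keys = [p for p in inspect.signature(type(self).__init__).parameters if p != "self"]
        return {k: getattr(self, k) for k in keys}

    def set_params(self, **params) -> "MultilevelLogistic":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for {type(self).__name__}")
            setattr(self, k, v)
        return self

    def fit(self, dataset: SurveyDataset, indicator: pd.DataFrame) -> "MultilevelLogistic":
        design = build_design(dataset, indicator, self.covariates, self.reference)
        if design.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if design.n_clusters < 2 * design.n_regions:
            warnings.warn("fewer than 2 clusters per region on average", stacklevel=2)
        if design.y.min() == design.y.max():
            raise ValueError("outcome must include both classes")
        self._warn_separation(design)

        y, X = design.y, design.X
        n, p_x = X.shape
        p = p_x + 1
        R, C = design.n_regions, design.n_clusters
        ridx, cidx = design.region_idx, design.cluster_idx
        dim = p + R + C + 2
        idx_lsr, idx_lsc = dim - 2, dim - 1
        bsd2 = self.prior_beta_sd**2
        ssd2 = self.prior_sigma_sd**2

        def logp_grad(x):
            beta = x[:p]
            zr = x[p : p + R]
            zc = x[p + R : p + R + C]
            lsr, lsc = x[idx_lsr], x[idx_lsc]
            if abs(lsr) > 20.0 or abs(lsc) > 20.0:  # pre-empt exp overflow
                return -np.inf, np.zeros(dim)
            sr, sc = np.exp(lsr), np.exp(lsc)
            eta = beta[0] + X @ beta[1:] + sr * zr[ridx] + sc * zc[cidx]
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            resid = y - expit(eta)
            lp = (
                ll
                - 0.5 * float(beta @ beta) / bsd2
                - 0.5 * float(zr @ zr)
                - 0.5 * float(zc @ zc)
                - 0.5 * sr**2 / ssd2
                + lsr
                - 0.5 * sc**2 / ssd2
                + lsc
            )
            g = np.empty(dim)
            g[0] = float(resid.sum()) - beta[0] / bsd2
            g[1:p] = X.T @ resid - beta[1:] / bsd2
            rsum = np.bincount(ridx, weights=resid, minlength=R)
            csum = np.bincount(cidx, weights=resid, minlength=C)
            g[p : p + R] = sr * rsum - zr
            g[p + R : p + R + C] = sc * csum - zc
            g[idx_lsr] = sr * float(zr @ rsum) - sr**2 / ssd2 + 1.0
            g[idx_lsc] = sc * float(zc @ csum) - sc**2 / ssd2 + 1.0
            return lp, g

        rate = np.clip(y.mean(), 1e-3, 1 - 1e-3)
        b0 = float(np.log(rate / (1 - rate)))

        def init(rng):
            x0 = np.zeros(dim)
            x0[0] = b0 + 0.1 * rng.standard_normal()
            x0[1:p] = 0.1 * rng.standard_normal(p - 1)
            x0[p : p + R + C] = 0.1 * rng.standard_normal(R + C)
            x0[idx_lsr] = np.log(0.3) + 0.2 * rng.standard_normal()
            x0[idx_lsc] = np.log(0.3) + 0.2 * rng.standard_normal()
            return x0

        results = run_chains(
            logp_grad,
            init,
            self.n_chains,
            self.n_warmup,
            self.n_draws,
            self.seed,
            max_leapfrog=self.max_leapfrog,
            target_accept=self.target_accept,
        )
        chains = np.asarray([r.draws for r in results])
        draws = chains.reshape(-1, dim)

        self.design_ = design
        self.columns_ = [("intercept", "")] + design.columns
        self.beta_draws_ = draws[:, :p]
        self.sigma2_region_draws_ = np.exp(2 * draws[:, idx_lsr])
        self.sigma2_cluster_draws_ = np.exp(2 * draws[:, idx_lsc])

        diag: dict[str, dict] = {}
        for j, (fieldname, level) in enumerate(self.columns_):
            nm = f"beta[{fieldname}{'=' + level if level else ''}]"
            diag[nm] = {"rhat": rhat(chains[:, :, j]), "ess": ess(chains[:, :, j])}
        diag["log_sigma_region"] = {
            "rhat": rhat(chains[:, :, idx_lsr]),
            "ess": ess(chains[:, :, idx_lsr]),
        }
        diag["log_sigma_cluster"] = {
            "rhat": rhat(chains[:, :, idx_lsc]),
            "ess": ess(chains[:, :, idx_lsc]),
        }
        diag["accept_rate"] = float(np.mean([r.accept_rate for r in results]))
        diag["divergent_frac"] = float(
            np.sum([r.n_divergent for r in results]) / max(draws.shape[0], 1)
        )
        self.diagnostics_ = diag

        if diag["divergent_frac"] > self.max_divergent_frac:
            raise RuntimeError(
                f"divergent transitions in {diag['divergent_frac']:.1%} of kept draws"
            )
        if self.check_convergence:
            bad = {
                k: round(v["rhat"], 3)
                for k, v in diag.items()
                if isinstance(v, dict) and v["rhat"] > self.max_rhat
            }
            if bad:
                raise RuntimeError(
                    f"convergence failure, split-Rhat above {self.max_rhat}: {bad}"
                )
        return self

    @staticmethod
    def _warn_separation(design: DesignBundle) -> None:
        for j, (fieldname, level) in enumerate(design.columns):
            sel = design.X[:, j] == 1.0
            if sel.any():
                ymean = design.y[sel].mean()
                if ymean in (0.0, 1.0):
                    warnings.warn(
                        f"separation: level {fieldname}={level} has all-"
                        f"{int(ymean)} outcomes",
                        stacklevel=3,
                    )

    def summarize(self) -> pd.DataFrame:
        """Adjusted odds ratios with 95% credible intervals, plus variance components."""
        if not hasattr(self, "beta_draws_"):
            raise RuntimeError("model is not fitted")
        rows = []
        for j, (fieldname, level) in enumerate(self.columns_):
            orr = np.exp(self.beta_draws_[:, j])
            rows.append(
                {
                    "field": fieldname,
                    "level": level,
                    "or_mean": float(orr.mean()),
                    "or_2.5%": float(np.quantile(orr, 0.025)),
                    "or_97.5%": float(np.quantile(orr, 0.975)),
                }
            )
        for nm, d in (
            ("cluster_variance", self.sigma2_cluster_draws_),
            ("region_variance", self.sigma2_region_draws_),
        ):
            rows.append(
                {
                    "field": nm,
                    "level": "",
                    "or_mean": float(d.mean()),
                    "or_2.5%": float(np.quantile(d, 0.025)),
                    "or_97.5%": float(np.quantile(d, 0.975)),
                }
            )
        return pd.DataFrame(rows)


def fit_multilevel(
    dataset: SurveyDataset, indicator: pd.DataFrame, **params
) -> MultilevelLogistic:
    """Thin functional wrapper over :class:`MultilevelLogistic`."""
    return MultilevelLogistic(**params).fit(dataset, indicator)


def summarize_or(fit: MultilevelLogistic) -> pd.DataFrame:
    return fit.summarize()
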