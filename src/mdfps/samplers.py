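"""Adaptive Hamiltonian Monte Carlo with optional Gibbs sub-steps.

A deliberately small sampler: dual-averaging step-size adaptation to a
target acceptance rate, a diagonal mass matrix estimated from late warmup,
and jittered leapfrog trajectory lengths. Model modules supply a log
density and its gradient; parameters that are awkward for gradients (the
Matérn range, whose gradient would require differentiating a Cholesky
factor) can instead be moved by a caller-supplied Gibbs/Metropolis update
run once per iteration, with their coordinates frozen during leapfrog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCResult", "hmc_sample", "run_chains", "rhat", "ess"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCResult:
    draws: np.ndarray          # (n_draws, dim)
    accept_rate: float
    step_size: float
    n_divergent: int


def _find_initial_step(logp_grad: LogpGrad, x: np.ndarray, active: np.ndarray,
                       rng: np.random.Generator) -> float:
    """Double/halve until one leapfrog step has acceptance prob near 0.5."""
    eps = 0.1
    lp0, g0 = logp_grad(x)
    p = rng.standard_normal(x.size) * active
    for _ in range(50):
        x1 = x + eps * (p + 0.5 * eps * g0 * active) * active
        lp1, g1 = logp_grad(x1)
        p1 = p + 0.5 * eps * (g0 + g1) * active
        dh = (lp1 - 0.5 * p1 @ p1) - (lp0 - 0.5 * p @ p)
        if not np.isfinite(dh):
            eps *= 0.5
            continue
        if dh > np.log(0.5):
            eps *= 2.0
        else:
            break
    return min(eps, 1.0)


def hmc_sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed: int,
    *,
    target_accept: float = 0.8,
    max_leapfrog: int = 24,
    frozen: np.ndarray | None = None,
    gibbs_update: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
    divergence_threshold: float = 1000.0,
) -> HMCResult:
    """Run one HMC chain.

    frozen: boolean mask of coordinates excluded from leapfrog dynamics
    (their momenta are pinned at zero); gibbs_update(x, rng, in_warmup), if
    given, is applied to the state once per iteration (warmup included) and
    is responsible for its own detailed balance (it may adapt proposal
    scales while in_warmup is True).
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float)
    dim = x.size
    active = np.ones(dim) if frozen is None else (~np.asarray(frozen)).astype(float)

    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, x, active, rng)

    # dual averaging (Hoffman & Gelman 2014 defaults), restartable
    gamma, t0, kappa = 0.05, 10.0, 0.75
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0

    def da_update(alpha: float) -> float:
        nonlocal log_eps_bar, h_bar, da_count
        da_count += 1
        h_bar = (1 - 1 / (da_count + t0)) * h_bar + (target_accept - alpha) / (da_count + t0)
        log_eps = mu - np.sqrt(da_count) / gamma * h_bar
        w = da_count**-kappa
        log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
        return float(np.exp(log_eps))

    draws = np.empty((n_draws, dim))
    n_accept = 0.0
    n_div = 0
    lp, grad = logp_grad(x)

    # warmup schedule: step-size adaptation, mass-estimation window, re-adaptation
    w1 = max(int(0.25 * n_warmup), 1)
    w2 = max(int(0.6 * n_warmup), 2)
    warm_buf: list[np.ndarray] = []

    total = n_warmup + n_draws
    for it in range(total):
        if gibbs_update is not None:
            x = gibbs_update(x, rng, it < n_warmup)
            lp, grad = logp_grad(x)

        sd = np.sqrt(inv_mass)
        p = rng.standard_normal(dim) / np.where(sd > 0, sd, 1.0) * active
        h0 = lp - 0.5 * np.sum(inv_mass * p * p)
        n_leap = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))

        x_new, p_new, lp_new, g_new = x, p, lp, grad
        diverged = False
        p_new = p_new + 0.5 * eps * g_new * active
        for step in range(n_leap):
            x_new = x_new + eps * inv_mass * p_new * active
            lp_new, g_new = logp_grad(x_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            if step < n_leap - 1:
                p_new = p_new + eps * g_new * active
        if not diverged:
            p_new = p_new + 0.5 * eps * g_new * active
            with np.errstate(over="ignore"):
                h1 = lp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
            dh = h1 - h0
            if not np.isfinite(dh) or dh < -divergence_threshold:
                diverged = True

        if diverged:
            alpha = 0.0
            n_div += it >= n_warmup
        else:
            alpha = min(1.0, float(np.exp(min(dh, 0.0))))
            if rng.uniform() < alpha:
                x, lp, grad = x_new, lp_new, g_new

        if it < n_warmup:
            eps = da_update(alpha)
            if w1 <= it < w2:
                warm_buf.append(x.copy())
            if it == w2 - 1 and len(warm_buf) >= 10:
                var = np.var(np.asarray(warm_buf), axis=0)
                med = np.median(var[var > 0]) if np.any(var > 0) else 1.0
                inv_mass = np.where(active > 0, np.clip(var, 1e-3 * med, None), 1.0)
                # step size must be re-tuned under the new metric
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x
            n_accept += alpha

    return HMCResult(
        draws=draws,
        accept_rate=n_accept / max(n_draws, 1),
        step_size=eps,
        n_divergent=n_div,
    )


def run_chains(
    logp_grad: LogpGrad,
    init: Callable[[np.random.Generator], np.ndarray],
    n_chains: int,
    n_warmup: int,
    n_draws: int,
    seed: int,
    **kwargs,
) -> list[HMCResult]:
    """Independent chains with seeds derived from ``seed`` via SeedSequence."""
    child = np.random.SeedSequence(seed).spawn(n_chains)
    results = []
    for c in range(n_chains):
        rng = np.random.default_rng(child[c])
        x0 = init(rng)
        chain_seed = int(child[c].generate_state(1)[0] % (2**31 - 1))
        results.append(hmc_sample(logp_grad, x0, n_warmup, n_draws, chain_seed, **kwargs))
    return results


def _split_chains(x: np.ndarray) -> np.ndarray:
    """(chains, draws) -> (2*chains, draws//2), dropping an odd trailing draw."""
    c, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)


def rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a scalar parameter; chains is (n_chains, n_draws)."""
    x = _split_chains(np.asarray(chains, dtype=float))
    m, n = x.shape
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def ess(chains: np.ndarray) -> float:
    """Bulk effective sample size via initial-positive-sequence autocorrelation."""
    x = np.asarray(chains, dtype=float)
    m, n = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    # mean autocorrelation across chains by FFT
    npad = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, npad, axis=1)
    acov = np.fft.irfft(f * np.conj(f), npad, axis=1)[:, :n].real / n
    denom = acov[:, :1]
    denom = np.where(denom > 0, denom, 1.0)
    rho = (acov / denom).mean(axis=0)
    tau = 1.0
    for t in range(1, n - 2, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2 * pair
    return float(m * n / max(tau, 1.0))
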