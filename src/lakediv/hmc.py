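"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

Gradient-based sampler used by the hierarchical gradient models: leapfrog
dynamics with a diagonal mass matrix, dual-averaging step-size adaptation
towards a target acceptance rate, a windowed mass-matrix estimate mid
warmup, and randomized path lengths (the number of leapfrog steps is drawn
uniformly each iteration) to avoid resonant trajectories.  Transitions
whose energy error exceeds a large threshold are counted as divergences.

The model supplies ``logp_grad(theta) -> (float, ndarray)``; everything
here is model-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMCDraws", "sample_hmc"]

_ENERGY_DIVERGENCE = 1000.0


def _energy(lp, inv_mass, r):
    """Hamiltonian lp - kinetic; -inf whenever anything is non-finite."""
    with np.errstate(over="ignore", invalid="ignore"):
        k = 0.5 * float(np.sum(inv_mass * r * r))
    if not (np.isfinite(k) and np.isfinite(lp)):
        return -np.inf
    return lp - k


@dataclass
class HMCDraws:
    draws: np.ndarray          # (chains, draws, dim)
    divergences: int
    accept_rate: float
    step_sizes: np.ndarray     # per chain


def _leapfrog(theta, r, eps, n_steps, logp_grad, inv_mass):
    lp, grad = logp_grad(theta)
    for _ in range(n_steps):
        r = r + 0.5 * eps * grad
        theta = theta + eps * inv_mass * r
        if not np.all(np.isfinite(theta)):
            return theta, r, -np.inf
        lp, grad = logp_grad(theta)
        if not (np.isfinite(lp) and np.all(np.isfinite(grad))):
            return theta, r, -np.inf
        r = r + 0.5 * eps * grad
    return theta, r, lp


def _find_initial_step(theta, logp_grad, inv_mass, rng):
    eps = 0.1
    lp0, _ = logp_grad(theta)
    r0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = _energy(lp0, inv_mass, r0)
    t1, r1, lp1 = _leapfrog(theta, r0.copy(), eps, 1, logp_grad, inv_mass)
    h1 = _energy(lp1, inv_mass, r1)
    ratio = h1 - h0
    direction = 1.0 if ratio > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0 ** direction)
        t1, r1, lp1 = _leapfrog(theta, r0.copy(), eps, 1, logp_grad, inv_mass)
        h1 = _energy(lp1, inv_mass, r1)
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return eps


def sample_hmc(
    logp_grad,
    init: np.ndarray,
    chains: int = 4,
    warmup: int = 500,
    draws: int = 500,
    seed: int = 0,
    target_accept: float = 0.8,
    max_leapfrog: int = 32,
    init_jitter: float = 0.5,
) -> HMCDraws:
    """Run ``chains`` independent adaptive-HMC chains from jittered inits."""
    dim = init.size
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)
    all_draws = np.empty((chains, draws, dim))
    total_div = 0
    accepts = []
    final_eps = np.empty(chains)

    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = init + init_jitter * rng.standard_normal(dim)
        inv_mass = np.ones(dim)

        # --- warmup: three windows -------------------------------------
        # [0, w1): adapt step, identity mass
        # [w1, w2): adapt step, collect samples for mass estimate
        # [w2, warmup): re-adapt step under the new mass
        w1, w2 = warmup // 4, (3 * warmup) // 4
        window: list[np.ndarray] = []

        def run_phase(theta, n_iter, eps0, adapt, collect):
            mu = np.log(10.0 * eps0)
            log_eps, log_eps_bar, h_bar = np.log(eps0), 0.0, 0.0
            gamma, t0, kappa = 0.05, 10.0, 0.75
            lp, _ = logp_grad(theta)
            for m in range(1, n_iter + 1):
                eps = float(np.exp(log_eps))
                n_steps = int(rng.integers(1, max_leapfrog + 1))
                r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
                h0 = _energy(lp, inv_mass, r0)
                th1, r1, lp1 = _leapfrog(theta, r0, eps, n_steps, logp_grad, inv_mass)
                h1 = _energy(lp1, inv_mass, r1)
                log_alpha = min(0.0, h1 - h0) if np.isfinite(h1) else -np.inf
                if np.log(rng.random()) < log_alpha:
                    theta, lp = th1, lp1
                alpha = np.exp(log_alpha) if np.isfinite(log_alpha) else 0.0
                if adapt:
                    frac = 1.0 / (m + t0)
                    h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha)
                    log_eps = mu - np.sqrt(m) / gamma * h_bar
                    eta = m ** (-kappa)
                    log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
                if collect:
                    window.append(theta.copy())
            return theta, float(np.exp(log_eps_bar if adapt else log_eps))

        eps0 = _find_initial_step(theta, logp_grad, inv_mass, rng)
        theta, eps1 = run_phase(theta, w1, eps0, adapt=True, collect=False)
        theta, eps2 = run_phase(theta, w2 - w1, eps1, adapt=True, collect=True)
        if len(window) >= 10:
            var = np.var(np.asarray(window), axis=0)
            inv_mass = np.clip(var, 1e-6, 1e6)
        theta, eps = run_phase(theta, warmup - w2, eps2, adapt=True, collect=False)
        final_eps[c] = eps

        # --- sampling ----------------------------------------------------
        lp, _ = logp_grad(theta)
        n_acc = 0
        for m in range(draws):
            n_steps = int(rng.integers(1, max_leapfrog + 1))
            r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = _energy(lp, inv_mass, r0)
            th1, r1, lp1 = _leapfrog(theta, r0, eps, n_steps, logp_grad, inv_mass)
            h1 = _energy(lp1, inv_mass, r1)
            if not np.isfinite(h1) or (h0 - h1) > _ENERGY_DIVERGENCE:
                total_div += 1
                log_alpha = -np.inf
            else:
                log_alpha = min(0.0, h1 - h0)
            if np.log(rng.random()) < log_alpha:
                theta, lp = th1, lp1
                n_acc += 1
            all_draws[c, m] = theta
        accepts.append(n_acc / draws)

    return HMCDraws(
        draws=all_draws,
        divergences=total_div,
        accept_rate=float(np.mean(accepts)),
        step_sizes=final_eps,
    )
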