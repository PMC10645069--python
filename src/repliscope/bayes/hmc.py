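"""Adaptive Hamiltonian Monte Carlo with an interleaved Metropolis sweep
for the random-slope correlation parameters.

The sampler follows the standard windowed-adaptation recipe: dual-averaged
step size targeting a given acceptance rate, a diagonal mass matrix
re-estimated in doubling warmup windows, and jittered leapfrog trajectory
lengths during sampling.  Proposals whose Hamiltonian error explodes are
counted as divergences.  Correlation parameters (canonical partial
correlations of the LKJ prior) are non-differentiable state for the HMC
part and are refreshed once per iteration with coordinate-wise
random-walk Metropolis on their conditional target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .posterior import HorseshoePosterior

DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, dim) unconstrained positions
    cpc_draws: np.ndarray  # (n_draws, n_cpc)
    accept_rate: float
    divergences: int
    step_size: float


def _leapfrog(post, theta, r, eps, n_steps, inv_mass):
    logp, grad = post.logp_grad(theta)
    r = r + 0.5 * eps * grad
    for step in range(n_steps):
        theta = theta + eps * inv_mass * r
        logp, grad = post.logp_grad(theta)
        if not np.isfinite(logp):
            return theta, r, -np.inf
        r = r + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return theta, r, logp


class _DualAveraging:
    """Nesterov dual averaging of log step size (Stan defaults)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))


def run_chain(
    post: HorseshoePosterior,
    rng: np.random.Generator,
    warmup: int = 500,
    draws: int = 500,
    target_accept: float = 0.9,
    max_leapfrog: int = 32,
    cpc_step: float = 0.2,
) -> ChainResult:
    dim = post.layout.size
    theta = post.initial_position(rng)
    omega = np.zeros(post.n_cpc)
    post.set_cpc(omega)

    inv_mass = np.ones(dim)
    eps = 0.1
    da = _DualAveraging(eps, target_accept)

    # doubling mass-adaptation windows between step-size-only buffers
    init_buf, term_buf = min(75, warmup // 4), min(50, warmup // 5)
    windows: list[tuple[int, int]] = []
    start, w = init_buf, 25
    while start < warmup - term_buf:
        end = min(start + w, warmup - term_buf)
        if (warmup - term_buf) - end < w:
            end = warmup - term_buf
        windows.append((start, end))
        start, w = end, w * 2
    window_samples: list[np.ndarray] = []

    out = np.empty((draws, dim))
    out_cpc = np.empty((draws, post.n_cpc))
    n_accept = 0
    divergences = 0
    total = warmup + draws

    for it in range(total):
        sampling = it >= warmup
        r = rng.normal(size=dim) / np.sqrt(inv_mass)
        logp0, _ = post.logp_grad(theta)
        h0 = logp0 - 0.5 * float(np.sum(r * r * inv_mass))
        n_steps = int(rng.integers(max(1, max_leapfrog // 4), max_leapfrog + 1))
        theta_new, r_new, logp_new = _leapfrog(post, theta, r, eps, n_steps, inv_mass)
        if np.isfinite(logp_new):
            with np.errstate(over="ignore"):
                h_new = logp_new - 0.5 * float(np.sum(r_new * r_new * inv_mass))
            delta = h_new - h0 if np.isfinite(h_new) else -np.inf
        else:
            delta = -np.inf
        if delta < -DIVERGENCE_THRESHOLD:
            accept_prob = 0.0
            if sampling:
                divergences += 1
        else:
            accept_prob = min(1.0, float(np.exp(min(delta, 0.0))))
        if rng.random() < accept_prob:
            theta = theta_new
            if sampling:
                n_accept += 1

        if not sampling:
            eps = da.update(accept_prob)
            for ws, we in windows:
                if ws <= it < we:
                    window_samples.append(theta.copy())
                    if it == we - 1 and len(window_samples) >= 10:
                        var = np.var(np.asarray(window_samples), axis=0)
                        n_w = len(window_samples)
                        # regularized variance estimate (Stan-style)
                        inv_mass = (n_w / (n_w + 5.0)) * var + 1e-3 * (
                            5.0 / (n_w + 5.0)
                        )
                        window_samples = []
                        da = _DualAveraging(float(np.exp(da.log_eps)), target_accept)
                    break
            if it == warmup - 1:
                eps = float(np.exp(da.log_eps_bar))

        # correlation parameters: random-scan coordinate MH (bounded cost
        # per iteration; these are weakly identified nuisance parameters)
        if post.n_cpc:
            n_upd = min(post.n_cpc, 16)
            coords = (
                np.arange(post.n_cpc)
                if post.n_cpc == n_upd
                else rng.choice(post.n_cpc, size=n_upd, replace=False)
            )
            current_lp = post.cpc_logp(omega, theta)
            for j in coords:
                prop = omega.copy()
                prop[j] += rng.normal(0.0, cpc_step)
                prop_lp = post.cpc_logp(prop, theta)
                if np.log(rng.random()) < prop_lp - current_lp:
                    omega, current_lp = prop, prop_lp
            post.set_cpc(omega)

        if sampling:
            out[it - warmup] = theta
            out_cpc[it - warmup] = omega

    return ChainResult(
        draws=out,
        cpc_draws=out_cpc,
        accept_rate=n_accept / max(draws, 1),
        divergences=divergences,
        step_size=eps,
    )
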