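"""Log posterior and analytic gradients for the horseshoe GLMMs.

One class covers the three likelihoods (cumulative-logit ordinal, Bernoulli
logit, Gaussian) sharing a common prior structure:

* fixed effects ``beta_j = z_j * tau * lambda_j`` with ``z ~ N(0,1)``,
  local scales ``lambda_j ~ half-t(df)`` and a global ``tau ~ half-Cauchy(0, s)``
  (non-centered horseshoe; a regularized/slab variant is optional);
* group-level (cohort) random intercept + slopes, non-centered:
  ``b_g = diag(sigma) @ L @ u_g`` with ``u ~ N(0, I)``,
  ``sigma_k ~ half-normal(0, 0.5)`` and ``L`` the Cholesky factor of an
  LKJ-distributed correlation matrix (updated outside HMC, see sampler);
* intercept / cutpoints with student-t(3, 0, 2.5) priors and, for the
  Gaussian likelihood, residual scale with a half-t(3, 0, 2.5) prior.

All scale parameters are sampled on the log scale with the Jacobian folded
into the target.  Gradients are exact and covered by finite-difference
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LIKELIHOODS = ("ordinal", "bernoulli", "gaussian")


def _exp(x):
    """exp() that overflows to inf instead of raising (np.float64 keeps
    downstream arithmetic exception-free as well)."""
    with np.errstate(over="ignore"):
        return np.float64(np.exp(x))


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_half_t(x, log_x, df, scale):
    """log density (up to constants) of half-t(df, scale) at x = exp(log_x),
    including the log-scale Jacobian, plus its gradient wrt log_x."""
    r2 = (x / scale) ** 2
    logp = -0.5 * (df + 1.0) * np.log1p(r2 / df) + log_x
    grad = -(df + 1.0) * r2 / (df + r2) + 1.0
    return logp, grad


def _log_student_t(x, df, scale):
    """Central student-t log density (up to constants) and gradient wrt x."""
    r2 = (x / scale) ** 2
    logp = -0.5 * (df + 1.0) * np.log1p(r2 / df)
    grad = -(df + 1.0) * x / (df * scale**2 + x**2)
    return logp, grad


def cpc_to_cholesky(z: np.ndarray, q: int) -> np.ndarray:
    """Build the Cholesky factor of a correlation matrix from canonical
    partial correlations ``z`` (row-major lower triangle, length q(q-1)/2)."""
    L = np.zeros((q, q))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, q):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[idx] * math.sqrt(rem)
            rem *= 1.0 - z[idx] ** 2
            idx += 1
        L[i, i] = math.sqrt(max(rem, 1e-300))
    return L


def lkj_cpc_log_prior(omega: np.ndarray, q: int, eta: float) -> float:
    """Log target for the unconstrained CPC vector ``omega`` (z = tanh(omega))
    under LKJ(eta), including the tanh Jacobian.

    The CPC in 0-based column ``j`` follows a shifted Beta(b_j, b_j) on
    (-1, 1) with ``b_j = eta + (q - 2 - j) / 2``; combined with the Jacobian
    ``dz/domega = 1 - z^2`` the per-coordinate term is ``b_j * log(1 - z^2)``.
    """
    z = np.tanh(omega)
    logp = 0.0
    idx = 0
    for i in range(1, q):
        for j in range(i):
            b = eta + (q - 2 - j) / 2.0
            logp += b * math.log(max(1.0 - z[idx] ** 2, 1e-300))
            idx += 1
    return logp


@dataclass
class ParamLayout:
    """Slices of the flat unconstrained parameter vector."""

    z_beta: slice
    log_lambda: slice
    log_tau: slice
    extra: slice  # cutpoints (ordinal), [alpha] (bernoulli), [alpha, log_sigma] (gaussian)
    u: slice
    log_sigma_u: slice
    size: int


class HorseshoePosterior:
    """Differentiable log posterior for one model."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        group_idx: np.ndarray,
        likelihood: str,
        n_levels: int = 5,
        horseshoe_df: float = 3.0,
        global_scale: float = 1.0,
        slab_width: float | None = None,
        random_slope_sd: float = 0.5,
        random_effects: str = "intercept_slopes",
        lkj_eta: float = 1.0,
        prior_only: bool = False,
    ):
        if likelihood not in LIKELIHOODS:
            raise ValueError(f"likelihood must be one of {LIKELIHOODS}")
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.group_idx = np.asarray(group_idx, dtype=int)
        self.likelihood = likelihood
        self.K = n_levels
        self.df = horseshoe_df
        self.global_scale = global_scale
        self.slab_width = slab_width
        self.sd_u = random_slope_sd
        self.random_effects = random_effects
        self.lkj_eta = lkj_eta
        self.prior_only = prior_only

        self.n, self.p = self.X.shape
        self.J = int(self.group_idx.max()) + 1 if self.n else 0
        if random_effects == "intercept_slopes":
            self.q = self.p + 1
        elif random_effects == "intercept":
            self.q = 1
        elif random_effects == "none":
            self.q = 0
        else:
            raise ValueError(f"unknown random_effects {random_effects!r}")
        if self.q:
            self.Z = (
                np.hstack([np.ones((self.n, 1)), self.X])[:, : self.q]
                if self.n
                else np.zeros((0, self.q))
            )
        else:
            self.Z = np.zeros((self.n, 0))
        if self.q and self.n:
            # flat indices for one-shot bincount group sums in the gradient
            self._grp_flat = (
                self.group_idx[:, None] * self.q + np.arange(self.q)[None, :]
            ).ravel()
        else:
            self._grp_flat = None

        n_extra = {"ordinal": self.K - 1, "bernoulli": 1, "gaussian": 2}[likelihood]
        pos = 0

        def take(k):
            nonlocal pos
            s = slice(pos, pos + k)
            pos += k
            return s

        self.layout = ParamLayout(
            z_beta=take(self.p),
            log_lambda=take(self.p),
            log_tau=take(1),
            extra=take(n_extra),
            u=take(self.J * self.q),
            log_sigma_u=take(self.q),
            size=0,
        )
        self.layout.size = pos
        self.n_cpc = self.q * (self.q - 1) // 2
        # current correlation-Cholesky state (updated by the sampler)
        self.L = np.eye(self.q) if self.q else np.zeros((0, 0))

    # -- parameter bookkeeping ------------------------------------------------

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(self.layout.size)
        theta[self.layout.z_beta] = rng.normal(0, 0.1, self.p)
        theta[self.layout.log_lambda] = rng.normal(0, 0.1, self.p)
        theta[self.layout.log_tau] = math.log(0.1)
        theta[self.layout.u] = rng.normal(0, 0.1, self.J * self.q)
        theta[self.layout.log_sigma_u] = math.log(0.1)
        if self.likelihood == "ordinal":
            if self.n:
                freq = np.bincount(self.y - 1, minlength=self.K) + 0.5
                cum = np.cumsum(freq)[:-1] / freq.sum()
                cuts = np.log(cum / (1 - cum))
            else:
                cuts = np.linspace(-1, 1, self.K - 1)
            raw = np.empty(self.K - 1)
            raw[0] = cuts[0]
            raw[1:] = np.log(np.maximum(np.diff(cuts), 1e-3))
            theta[self.layout.extra] = raw
        elif self.likelihood == "gaussian":
            sd = float(np.std(self.y)) if self.n else 1.0
            theta[self.layout.extra] = [float(np.mean(self.y)) if self.n else 0.0,
                                        math.log(max(sd, 1e-3))]
        return theta

    def beta(self, theta: np.ndarray) -> np.ndarray:
        """Fixed-effect coefficients implied by the unconstrained vector."""
        z = theta[self.layout.z_beta]
        lam = np.exp(theta[self.layout.log_lambda])
        tau = _exp(theta[self.layout.log_tau][0])
        if self.slab_width is not None:
            c2 = self.slab_width**2
            lam = np.sqrt(c2 * lam**2 / (c2 + tau**2 * lam**2))
        return z * lam * tau

    def cutpoints(self, theta: np.ndarray) -> np.ndarray:
        raw = theta[self.layout.extra]
        c = np.empty(self.K - 1)
        c[0] = raw[0]
        c[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
        return c

    def random_coefs(self, theta: np.ndarray) -> np.ndarray:
        """Group-level coefficients b (J, q)."""
        if not self.q:
            return np.zeros((self.J, 0))
        u = theta[self.layout.u].reshape(self.J, self.q)
        sigma = np.exp(theta[self.layout.log_sigma_u])
        return (u @ self.L.T) * sigma[None, :]

    def linear_predictor(self, theta: np.ndarray) -> np.ndarray:
        eta = self.X @ self.beta(theta)
        if self.q:
            b = self.random_coefs(theta)
            eta = eta + np.sum(self.Z * b[self.group_idx], axis=1)
        return eta

    # -- likelihood -----------------------------------------------------------

    def _loglik_and_grads(self, theta: np.ndarray):
        """Return (loglik, dl/deta, dl/dextra)."""
        eta = self.linear_predictor(theta)
        extra = theta[self.layout.extra]
        if self.prior_only or self.n == 0:
            return 0.0, np.zeros(self.n), np.zeros(len(extra))
        if self.likelihood == "gaussian":
            alpha, log_s = extra
            s = _exp(log_s)
            resid = self.y - alpha - eta
            ll = float(-0.5 * np.sum((resid / s) ** 2) - self.n * log_s)
            g_eta = resid / s**2
            g_extra = np.array(
                [float(np.sum(g_eta)), float(np.sum((resid / s) ** 2) - self.n)]
            )
            return ll, g_eta, g_extra
        if self.likelihood == "bernoulli":
            alpha = extra[0]
            mu = _sigmoid(alpha + eta)
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            ll = float(np.sum(np.where(self.y == 1, np.log(mu), np.log(1 - mu))))
            g_eta = self.y - mu
            return ll, g_eta, np.array([float(np.sum(g_eta))])
        # ordinal cumulative logit: P(Y <= k) = sigmoid(c_k - eta)
        c = self.cutpoints(theta)
        k = self.y - 1  # 0-based level
        upper = np.where(k < self.K - 1, c[np.minimum(k, self.K - 2)] - eta, np.inf)
        lower = np.where(k > 0, c[np.maximum(k - 1, 0)] - eta, -np.inf)
        Fu = np.where(np.isinf(upper), 1.0, _sigmoid(upper))
        Fl = np.where(np.isneginf(lower), 0.0, _sigmoid(lower))
        prob = np.clip(Fu - Fl, 1e-300, None)
        ll = float(np.sum(np.log(prob)))
        fu = np.where(np.isinf(upper), 0.0, Fu * (1.0 - Fu))
        fl = np.where(np.isneginf(lower), 0.0, Fl * (1.0 - Fl))
        g_eta = (fl - fu) / prob
        # accumulate dl/dc then map through the ordered transform
        g_c = np.bincount(
            np.clip(k, 0, self.K - 2),
            weights=np.where(k < self.K - 1, fu / prob, 0.0),
            minlength=self.K - 1,
        ) - np.bincount(
            np.clip(k - 1, 0, self.K - 2),
            weights=np.where(k > 0, fl / prob, 0.0),
            minlength=self.K - 1,
        )
        raw = theta[self.layout.extra]
        g_raw = np.empty(self.K - 1)
        g_raw[0] = np.sum(g_c)
        for m in range(1, self.K - 1):
            g_raw[m] = np.sum(g_c[m:]) * _exp(raw[m])
        return ll, g_eta, g_raw

    # -- full target ----------------------------------------------------------

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        # far-out leapfrog excursions can overflow exp(); they are rejected
        # (or flagged divergent) by the sampler once logp comes back non-finite
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            logp, grad = self._logp_grad_impl(theta)
        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros(self.layout.size)
        return logp, grad

    def _logp_grad_impl(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        lay = self.layout
        grad = np.zeros(lay.size)
        z = theta[lay.z_beta]
        log_lam = theta[lay.log_lambda]
        lam = np.exp(log_lam)
        log_tau = theta[lay.log_tau][0]
        tau = _exp(log_tau)

        ll, g_eta, g_extra = self._loglik_and_grads(theta)
        logp = ll
        grad[lay.extra] += g_extra

        gX = self.X.T @ g_eta if self.n else np.zeros(self.p)
        beta = self.beta(theta)
        if self.slab_width is not None:
            c2 = self.slab_width**2
            kappa = c2 / (c2 + tau**2 * lam**2)
            lam_tilde = np.sqrt(c2 * lam**2 / (c2 + tau**2 * lam**2))
        else:
            kappa = np.ones(self.p)
            lam_tilde = lam
        grad[lay.z_beta] += gX * lam_tilde * tau
        grad[lay.log_lambda] += gX * beta * kappa
        grad[lay.log_tau] += float(np.sum(gX * beta * kappa))

        # horseshoe priors
        logp += float(-0.5 * np.sum(z * z))
        grad[lay.z_beta] += -z
        lp_lam, g_lam = _log_half_t(lam, log_lam, self.df, 1.0)
        logp += float(np.sum(lp_lam))
        grad[lay.log_lambda] += g_lam
        lp_tau, g_tau = _log_half_t(
            np.array([tau]), np.array([log_tau]), 1.0, self.global_scale
        )
        logp += float(lp_tau[0])
        grad[lay.log_tau] += g_tau[0]

        # intercept / cutpoints / residual-scale priors
        extra = theta[lay.extra]
        if self.likelihood == "ordinal":
            c = self.cutpoints(theta)
            lp_c, g_c_prior = _log_student_t(c, 3.0, 2.5)
            logp += float(np.sum(lp_c)) + float(np.sum(extra[1:]))  # + Jacobian
            grad[lay.extra.start] += float(np.sum(g_c_prior))
            for m in range(1, self.K - 1):
                grad[lay.extra.start + m] += (
                    float(np.sum(g_c_prior[m:])) * _exp(extra[m]) + 1.0
                )
        else:
            lp_a, g_a = _log_student_t(np.array([extra[0]]), 3.0, 2.5)
            logp += float(lp_a[0])
            grad[lay.extra.start] += float(g_a[0])
            if self.likelihood == "gaussian":
                s = _exp(extra[1])
                lp_s, g_s = _log_half_t(
                    np.array([s]), np.array([extra[1]]), 3.0, 2.5
                )
                logp += float(lp_s[0])
                grad[lay.extra.start + 1] += float(g_s[0])

        # random effects
        if self.q:
            u = theta[lay.u].reshape(self.J, self.q)
            log_sig = theta[lay.log_sigma_u]
            sig = np.exp(log_sig)
            b = (u @ self.L.T) * sig[None, :]
            if self.n:
                Ggrp = np.bincount(
                    self._grp_flat,
                    weights=(self.Z * g_eta[:, None]).ravel(),
                    minlength=self.J * self.q,
                ).reshape(self.J, self.q)
                grad[lay.u] += ((Ggrp * sig[None, :]) @ self.L).ravel()
                grad[lay.log_sigma_u] += np.sum(Ggrp * b, axis=0)
            logp += float(-0.5 * np.sum(u * u))
            grad[lay.u] += -u.ravel()
            # half-normal(0, sd_u) on sigma, log-scale Jacobian included
            logp += float(np.sum(-0.5 * (sig / self.sd_u) ** 2 + log_sig))
            grad[lay.log_sigma_u] += -((sig / self.sd_u) ** 2) + 1.0

        return logp, grad

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    # -- CPC (correlation) conditional target, for the MH update --------------

    def cpc_logp(self, omega: np.ndarray, theta: np.ndarray) -> float:
        """Conditional log target for the correlation parameters given theta."""
        if self.n_cpc == 0:
            return 0.0
        saved = self.L
        self.L = cpc_to_cholesky(np.tanh(omega), self.q)
        try:
            ll, _, _ = self._loglik_and_grads(theta)
        finally:
            self.L = saved
        return ll + lkj_cpc_log_prior(omega, self.q, self.lkj_eta)

    def set_cpc(self, omega: np.ndarray) -> None:
        if self.n_cpc:
            self.L = cpc_to_cholesky(np.tanh(omega), self.q)
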