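"""MCMC posterior sampling for the survey/census fusion model.

The kernel is Metropolis-within-Gibbs with three blocks per sweep:

* latent field ``Z``: given the scalar parameters the ``Z_i`` are
  conditionally independent, so every cell is updated simultaneously with an
  independence Metropolis-Hastings proposal drawn from the Gaussian
  precision-weighted combination of its survey and census terms, truncated to
  ``[0, 1]``.  The accept/reject step uses the exact truncated-normal
  likelihood (including the Z-dependent truncation constants the Gaussian
  combination ignores), so the approximation in the proposal costs acceptance
  rate, never correctness.
* bias coefficients ``(delta1, delta2, theta1..4)``: joint adaptive
  random-walk Metropolis on standardized coordinates, with the empirical
  covariance learned during the adaptation phase (frozen afterwards).
* error sds ``sigma``, ``tau``: log-scale random walks inside their uniform
  prior supports.

Coordinates are standardized internally (mean 0, sd 1); coefficient draws are
reported back on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .data import CensusLayer, SurveyTable
from .model import CoordScaler, PriorSpec, bias_surface
from .truncnorm import sample_trunc_interval

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "sample_posterior",
    "check_convergence",
    "summarize_posterior",
    "total_extent",
]

_COEF_NAMES = ("delta1", "delta2", "theta1", "theta2", "theta3", "theta4")
_SCALAR_NAMES = _COEF_NAMES + ("sigma", "tau")


def _ordered_scalars(scalars: dict) -> list[str]:
    order = _SCALAR_NAMES + ("z_mu", "z_sd")
    return [name for name in order if name in scalars]

# above this many cells, per-draw z vectors are summarized (running moments
# and per-draw totals) instead of stored in full
_Z_STORE_MAX = 20_000

# numerical floor on the error sds: duplicated/noise-free layers make the
# posterior pile onto sigma or tau -> 0 (likelihood ~ sd^-n at zero residual),
# which underflows; prior mass below the floor is negligible in any real fit
_SD_FLOOR = 1e-7


@dataclass(frozen=True)
class SamplerConfig:
    """Chain layout and adaptation settings for the Gibbs sampler."""

    n_chains: int = 3
    n_adapt: int = 2000
    n_burnin: int = 5000
    n_iter: int = 10_000
    thin: int = 10
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required")
        for name in ("n_adapt", "n_burnin", "n_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.thin < 1 or self.n_iter % self.thin:
            raise ValueError("thin must be >= 1 and divide n_iter evenly")


@dataclass
class PosteriorDraws:
    """Posterior draws, with the latent field stored or summarized.

    ``scalars`` maps each scalar parameter name to an array of shape
    ``(n_chains, n_kept)`` on the original coordinate scale.  ``z`` has shape
    ``(n_chains, n_kept, n_cells)`` when stored, else ``None`` with running
    per-chain moments in ``z_sum``/``z_sumsq``.  ``z_total`` (per-draw sum of
    the latent field, in cell-proportion units) is always stored.
    """

    scalars: dict[str, np.ndarray]
    z_total: np.ndarray
    z: Optional[np.ndarray]
    z_sum: np.ndarray
    z_sumsq: np.ndarray
    cell_id: np.ndarray
    accept_rates: dict[str, float]
    config: SamplerConfig
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.z_total.shape[0]

    @property
    def n_kept(self) -> int:
        return self.z_total.shape[1]

    @property
    def n_cells(self) -> int:
        return len(self.cell_id)

    def stacked(self, name: str) -> np.ndarray:
        """All kept draws of a scalar parameter, chains concatenated."""
        return self.scalars[name].reshape(-1)

    def z_mean(self) -> np.ndarray:
        """Posterior mean of each latent proportion (pooled over chains)."""
        n_draws = self.n_chains * self.n_kept
        return self.z_sum.sum(axis=0) / n_draws

    def scalar_frame(self) -> pd.DataFrame:
        """Long-format table of scalar draws with chain/draw indices."""
        chains, kept = self.n_chains, self.n_kept
        out = {
            "chain": np.repeat(np.arange(chains), kept),
            "draw": np.tile(np.arange(kept), chains),
        }
        for name in _ordered_scalars(self.scalars):
            out[name] = self.scalars[name].reshape(-1)
        out["z_total"] = self.z_total.reshape(-1)
        return pd.DataFrame(out)


@dataclass
class ConvergenceReport:
    """Split-Rhat / effective-sample-size diagnostics for a fitted model."""

    table: pd.DataFrame
    flagged: bool
    threshold: float
    flagged_params: list[str]

    def __str__(self) -> str:
        status = (
            "NOT CONVERGED: parameter estimates should not be trusted "
            f"(Rhat > {self.threshold} for {', '.join(self.flagged_params)})"
            if self.flagged
            else "converged: no Rhat above threshold"
        )
        return f"{status}\n{self.table.to_string(index=False)}"


# --------------------------------------------------------------------------
# sampler internals


def _expand_fixed(fixed: Optional[dict]) -> dict[str, float]:
    if not fixed:
        return {}
    out: dict[str, float] = {}
    for key, value in fixed.items():
        if key == "theta":
            for name in ("theta1", "theta2", "theta3", "theta4"):
                out[name] = float(value)
        elif key in _COEF_NAMES:
            out[key] = float(value)
        else:
            raise ValueError(f"cannot fix unknown parameter {key!r}")
    if "delta1" in out and not ({"theta1", "theta2"} <= out.keys()):
        raise ValueError("fixing delta1 requires fixing theta1 and theta2")
    if "delta2" in out and not ({"theta3", "theta4"} <= out.keys()):
        raise ValueError("fixing delta2 requires fixing theta3 and theta4")
    return out


def _standardized_fixed(fixed: dict[str, float], scaler: CoordScaler) -> dict[int, float]:
    """Map original-scale fixed coefficients to standardized slots."""
    out: dict[int, float] = {}
    get = fixed.get
    if "theta1" in fixed:
        out[2] = fixed["theta1"] * scaler.north_sd
    if "theta2" in fixed:
        out[3] = fixed["theta2"] * scaler.east_sd
    if "theta3" in fixed:
        out[4] = fixed["theta3"] * scaler.north_sd
    if "theta4" in fixed:
        out[5] = fixed["theta4"] * scaler.east_sd
    if "delta1" in fixed:
        out[0] = (
            fixed["delta1"]
            + get("theta1", 0.0) * scaler.north_mean
            + get("theta2", 0.0) * scaler.east_mean
        )
    if "delta2" in fixed:
        out[1] = (
            fixed["delta2"]
            + get("theta3", 0.0) * scaler.north_mean
            + get("theta4", 0.0) * scaler.east_mean
        )
    return out


class _ChainState:
    """Mutable state and cached log-likelihood terms for one chain."""

    def __init__(self, problem, rng):
        self.p = problem
        self.rng = rng

    def init(self, from_prior: bool = False):
        p = self.p
        pri = p.priors
        if from_prior:
            self.c = self.rng.normal(0.0, pri.coef_sd, size=6)
            self.sigma = self.rng.uniform(pri.sigma_lower, pri.sigma_upper)
            self.tau = self.rng.uniform(0.0, pri.tau_upper)
            self.z = self.rng.uniform(0.0, 1.0, size=p.n)
            if p.hier:
                self.mu_z = self.rng.uniform(*pri.z_mu_range)
                self.s_z = self.rng.uniform(*pri.z_sd_range)
        else:
            self.c = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
            self.sigma = 0.5 * (pri.sigma_lower + pri.sigma_upper)
            # start tau at the scale of the census spread, not the prior
            # midpoint: a too-large tau makes the truncation constant dominate
            # and can trap the chain in a collapsed (beta ~ 0) basin
            q_sd = float(np.std(p.q)) if p.n else 0.0
            self.tau = float(
                np.clip(0.5 * q_sd if q_sd > 0 else 0.1, 1e-3, 0.9 * pri.tau_upper)
            )
            self.z = np.clip(p.q, 1e-3, 1.0 - 1e-3)
            if len(p.survey_idx):
                self.z[p.survey_idx] = np.clip(p.y, 1e-3, 1.0 - 1e-3)
            if p.hier:
                mu_lo, mu_hi = pri.z_mu_range
                sd_lo, sd_hi = pri.z_sd_range
                z_mean = float(self.z.mean()) if p.n else 0.5
                z_sd = float(self.z.std()) if p.n else 0.2
                self.mu_z = float(np.clip(z_mean, mu_lo + 1e-3, mu_hi - 1e-3))
                self.s_z = float(np.clip(1.5 * z_sd + 1e-3, sd_lo * 1.01, sd_hi * 0.99))
        if not p.hier:
            self.mu_z, self.s_z = 0.5, np.inf
        for idx, value in p.fixed_std.items():
            self.c[idx] = value
        self.refresh_census()
        self.refresh_survey()

    def zprior_quad(self, z) -> np.ndarray:
        """Per-cell quadratic part of the latent-field prior log-density."""
        r = (z - self.mu_z) / self.s_z
        return -0.5 * r * r

    def zprior_quad_at(self, z, mu: float, s: float) -> np.ndarray:
        r = (z - mu) / s
        return -0.5 * r * r

    def zprior_norm(self, mu: float, s: float) -> float:
        """Per-cell constant of the TN_[0,1](mu, s^2) prior log-density."""
        from scipy.special import ndtr

        return -np.log(s) - np.log(ndtr((1.0 - mu) / s) - ndtr(-mu / s))

    # cached per-cell log-likelihood terms (2*pi constants dropped)
    def refresh_census(self):
        p = self.p
        self.alpha = self.c[0] + self.c[2] * p.ns + self.c[3] * p.es
        self.beta = self.c[1] + self.c[4] * p.ns + self.c[5] * p.es
        self.llc = self._census_ll(self.alpha + self.beta * self.z, self.tau)

    def refresh_survey(self):
        p = self.p
        self.lls = self._survey_ll(self.z[p.survey_idx], self.sigma)

    def _census_ll(self, mean, tau):
        q = self.p.q
        r = (q - mean) / tau
        return -0.5 * r * r - np.log(tau) - log_ndtr(mean / tau)

    def _survey_ll(self, z_s, sigma):
        y = self.p.y
        r = (y - z_s) / sigma
        return -0.5 * r * r - np.log(sigma) - log_ndtr(z_s / sigma)

    def finite(self) -> bool:
        return bool(
            np.all(np.isfinite(self.llc)) and np.all(np.isfinite(self.lls))
        )


class _Problem:
    """Immutable per-fit data in canonical (cell_id-sorted) order."""

    def __init__(self, census, survey, priors, fixed):
        order = np.argsort(census.cell_id, kind="stable")
        self.cell_id = census.cell_id[order]
        self.q = census.q[order]
        self.n = len(self.q)
        self.scaler = CoordScaler.fit(census)
        es, ns = self.scaler.transform(census.easting[order], census.northing[order])
        self.es, self.ns = es, ns
        sorted_census = CensusLayer(
            cell_id=self.cell_id,
            easting=census.easting[order],
            northing=census.northing[order],
            q=self.q,
        )
        if len(survey):
            s_order = np.argsort(survey.cell_id, kind="stable")
            self.survey_idx = sorted_census.index_of(survey.cell_id[s_order])
            self.y = np.asarray(survey.y, dtype=float)[s_order]
        else:
            self.survey_idx = np.empty(0, dtype=int)
            self.y = np.empty(0)
        self.priors = priors
        self.hier = priors.z_prior == "hierarchical"
        self.fixed = _expand_fixed(fixed)
        self.fixed_std = _standardized_fixed(self.fixed, self.scaler)
        self.free = np.array([i not in self.fixed_std for i in range(6)])


def _update_z(state: _ChainState, cond=None) -> float:
    p = state.p
    if p.n == 0:
        return 1.0
    rng = state.rng
    if cond is None:
        cond = _z_conditional(
            p, state.alpha, state.beta, state.sigma, state.tau, state.mu_z, state.s_z
        )
    m, s = cond
    z_new = sample_trunc_interval(m, s, 0.0, 1.0, rng)
    llc_new = state._census_ll(state.alpha + state.beta * z_new, state.tau)
    delta = llc_new - state.llc
    # proposal-density correction (shared truncation constant cancels)
    rz_old = (state.z - m) / s
    rz_new = (z_new - m) / s
    delta += 0.5 * (rz_new * rz_new - rz_old * rz_old)
    if p.hier:
        delta += state.zprior_quad(z_new) - state.zprior_quad(state.z)
    if len(p.survey_idx):
        lls_new = state._survey_ll(z_new[p.survey_idx], state.sigma)
        delta[p.survey_idx] += lls_new - state.lls
    accept = np.log(rng.uniform(size=p.n)) < delta
    state.z[accept] = z_new[accept]
    state.llc[accept] = llc_new[accept]
    if len(p.survey_idx):
        acc_s = accept[p.survey_idx]
        state.lls[acc_s] = lls_new[acc_s]
    return float(accept.mean())


def _update_coefs(state: _ChainState, chol: np.ndarray, scale: float) -> bool:
    p = state.p
    free = p.free
    n_free = int(free.sum())
    if n_free == 0:
        return False
    step = scale * (chol @ state.rng.normal(size=n_free))
    c_new = state.c.copy()
    c_new[free] += step
    alpha_new = c_new[0] + c_new[2] * p.ns + c_new[3] * p.es
    beta_new = c_new[1] + c_new[4] * p.ns + c_new[5] * p.es
    llc_new = state._census_ll(alpha_new + beta_new * state.z, state.tau)
    inv_var = 1.0 / p.priors.coef_sd**2
    delta = (
        llc_new.sum()
        - state.llc.sum()
        - 0.5 * inv_var * (np.sum(c_new[free] ** 2) - np.sum(state.c[free] ** 2))
    )
    if np.log(state.rng.uniform()) < delta:
        state.c = c_new
        state.alpha, state.beta, state.llc = alpha_new, beta_new, llc_new
        return True
    return False


def _update_scale_param(state: _ChainState, which: str, step_sd: float) -> bool:
    pri = state.p.priors
    old = state.sigma if which == "sigma" else state.tau
    new = old * np.exp(step_sd * state.rng.normal())
    lo, hi = (
        (pri.sigma_lower, pri.sigma_upper) if which == "sigma" else (0.0, pri.tau_upper)
    )
    if not (max(lo, _SD_FLOOR) < new < hi):
        return False
    if which == "sigma":
        ll_new = state._survey_ll(state.z[state.p.survey_idx], new)
        delta = ll_new.sum() - state.lls.sum()
    else:
        ll_new = state._census_ll(state.alpha + state.beta * state.z, new)
        delta = ll_new.sum() - state.llc.sum()
    delta += np.log(new) - np.log(old)  # log-walk Jacobian
    if np.log(state.rng.uniform()) < delta:
        if which == "sigma":
            state.sigma, state.lls = new, ll_new
        else:
            state.tau, state.llc = new, ll_new
        return True
    return False


def _mills(u):
    """Inverse Mills ratio phi(u)/Phi(u), stable for large negative u."""
    u = np.clip(u, -30.0, 30.0)
    return np.exp(-0.5 * u * u - 0.5 * np.log(2 * np.pi) - log_ndtr(u))


def _z_conditional(p, alpha, beta, sigma, tau, mu_z, s_z):
    """Laplace approximation (mean, sd) of every latent cell's conditional.

    First combines the census term, the survey term where present, and (in
    the hierarchical case) the latent prior as untruncated Gaussians in z;
    then applies a one-step Newton correction restoring the gradient and
    curvature of the z-dependent truncation constants (-log Phi terms) of
    both observation models.  The remaining approximation error is absorbed
    exactly by the Metropolis-Hastings correction of whichever move consumes
    the result as a proposal.
    """
    inv_tau2 = 1.0 / tau**2
    prec = beta**2 * inv_tau2
    num = beta * (p.q - alpha) * inv_tau2
    if p.hier:
        inv_s2 = 1.0 / s_z**2
        prec = prec + inv_s2
        num = num + mu_z * inv_s2
    else:
        prec = prec.copy()
        num = num.copy()
    if len(p.survey_idx):
        inv_sig2 = 1.0 / sigma**2
        prec[p.survey_idx] += inv_sig2
        num[p.survey_idx] += p.y * inv_sig2
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = np.where(prec > 0, num / np.maximum(prec, 1e-300), 0.5)
    m0 = np.clip(m0, -10.0, 11.0)

    # Newton step for T(z) = -log Phi((alpha+beta z)/tau) [- log Phi(z/sigma)]
    u = (alpha + beta * m0) / tau
    lam = _mills(u)
    grad = -(beta / tau) * lam
    curv = (beta / tau) ** 2 * lam * (np.clip(u, -30, 30) + lam)
    if len(p.survey_idx):
        v = m0[p.survey_idx] / sigma
        lam_s = _mills(v)
        grad[p.survey_idx] += -lam_s / sigma
        curv[p.survey_idx] += lam_s * (np.clip(v, -30, 30) + lam_s) / sigma**2
    prec1 = np.maximum(prec - curv, 0.05 * np.maximum(prec, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(prec1 > 0, 1.0 / np.sqrt(np.maximum(prec1, 1e-300)), 3.0)
    s = np.minimum(s, 3.0)
    shift = np.clip(grad / np.maximum(prec1, 1e-300), -3.0 * s, 3.0 * s)
    m = np.clip(m0 + np.where(prec > 0, shift, 0.0), -10.0, 11.0)
    return m, s


def _logq_z01(z, m, s) -> float:
    """Log-density of independent N(m, s^2) draws truncated to [0, 1]."""
    from scipy.special import ndtr

    norm = ndtr((1.0 - m) / s) - ndtr(-m / s)
    if np.any(norm <= 1e-300):
        return -np.inf
    r = (z - m) / s
    return float(np.sum(-0.5 * r * r - np.log(s) - np.log(norm)))


def _update_joint(state: _ChainState, chol: np.ndarray, scale: float, cond=None):
    """Joint move: random-walk all scalars, refresh z from its conditional.

    Proposing the latent field from its Gaussianized conditional under the
    *proposed* scalars makes this behave like a random walk on the marginal
    posterior of the scalars, breaking the ridge between the bias
    coefficients and the latent field that single-block updates cannot cross
    when tau is small.  The proposal density of the refresh appears in the
    acceptance ratio, so the Gaussianization does not bias the target.
    """
    p = state.p
    free = p.free
    v = np.concatenate(
        [
            state.c[free],
            [np.log(state.sigma), np.log(state.tau)],
            [state.mu_z, np.log(state.s_z)] if p.hier else [],
        ]
    )
    v_new = v + scale * (chol @ state.rng.normal(size=len(v)))
    n_free = int(free.sum())
    c_new = state.c.copy()
    c_new[free] = v_new[:n_free]
    sigma_new = float(np.exp(v_new[n_free]))
    tau_new = float(np.exp(v_new[n_free + 1]))
    pri = p.priors
    if not (max(pri.sigma_lower, _SD_FLOOR) < sigma_new < pri.sigma_upper):
        return False
    if not (_SD_FLOOR < tau_new < pri.tau_upper):
        return False
    if p.hier:
        mu_new = float(v_new[n_free + 2])
        s_new = float(np.exp(v_new[n_free + 3]))
        if not (pri.z_mu_range[0] <= mu_new <= pri.z_mu_range[1]):
            return False
        if not (pri.z_sd_range[0] <= s_new <= pri.z_sd_range[1]):
            return False
    else:
        mu_new, s_new = state.mu_z, state.s_z

    alpha_new = c_new[0] + c_new[2] * p.ns + c_new[3] * p.es
    beta_new = c_new[1] + c_new[4] * p.ns + c_new[5] * p.es
    m_new, s_prop_new = _z_conditional(
        p, alpha_new, beta_new, sigma_new, tau_new, mu_new, s_new
    )
    if p.n:
        z_new = sample_trunc_interval(m_new, s_prop_new, 0.0, 1.0, state.rng)
    else:
        z_new = state.z
    llc_new = state._census_ll(alpha_new + beta_new * z_new, tau_new)
    lls_new = (
        state._survey_ll(z_new[p.survey_idx], sigma_new)
        if len(p.survey_idx)
        else np.empty(0)
    )

    inv_var = 1.0 / pri.coef_sd**2
    delta = (
        llc_new.sum()
        - state.llc.sum()
        + lls_new.sum()
        - state.lls.sum()
        - 0.5 * inv_var * (np.sum(c_new[free] ** 2) - np.sum(state.c[free] ** 2))
        + np.log(sigma_new / state.sigma)
        + np.log(tau_new / state.tau)  # log-scale Jacobians
    )
    if p.hier and p.n:
        delta += float(
            np.sum(state.zprior_quad_at(z_new, mu_new, s_new))
            - np.sum(state.zprior_quad(state.z))
        ) + p.n * (
            state.zprior_norm(mu_new, s_new)
            - state.zprior_norm(state.mu_z, state.s_z)
        )
    if p.hier:
        delta += np.log(s_new / state.s_z)
    if p.n:
        if cond is None:
            cond = _z_conditional(
                p, state.alpha, state.beta, state.sigma, state.tau,
                state.mu_z, state.s_z,
            )
        m_cur, s_prop_cur = cond
        delta += _logq_z01(state.z, m_cur, s_prop_cur) - _logq_z01(
            z_new, m_new, s_prop_new
        )
    if not np.isfinite(delta):
        return False
    if np.log(state.rng.uniform()) < delta:
        state.c = c_new
        state.sigma, state.tau = sigma_new, tau_new
        state.mu_z, state.s_z = mu_new, s_new
        state.z = z_new
        state.alpha, state.beta = alpha_new, beta_new
        state.llc, state.lls = llc_new, lls_new
        return True
    return False


def _update_z_hyper(state: _ChainState, step_mu: float, step_s: float):
    """Random-walk updates for the latent-prior hyperparameters (mu_z, s_z)."""
    p = state.p
    acc_mu = acc_s = False
    if not p.hier or p.n == 0:
        return acc_mu, acc_s
    mu_lo, mu_hi = p.priors.z_mu_range
    sd_lo, sd_hi = p.priors.z_sd_range
    n = p.n

    mu_new = state.mu_z + step_mu * state.rng.normal()
    if mu_lo <= mu_new <= mu_hi:
        r_new = (state.z - mu_new) / state.s_z
        delta = (
            -0.5 * float(r_new @ r_new)
            - float(state.zprior_quad(state.z).sum())
            + n * (state.zprior_norm(mu_new, state.s_z) - state.zprior_norm(state.mu_z, state.s_z))
        )
        if np.log(state.rng.uniform()) < delta:
            state.mu_z = float(mu_new)
            acc_mu = True

    s_new = state.s_z * np.exp(step_s * state.rng.normal())
    if sd_lo <= s_new <= sd_hi:
        r_new = (state.z - state.mu_z) / s_new
        delta = (
            -0.5 * float(r_new @ r_new)
            - float(state.zprior_quad(state.z).sum())
            + n * (state.zprior_norm(state.mu_z, s_new) - state.zprior_norm(state.mu_z, state.s_z))
            + np.log(s_new) - np.log(state.s_z)  # log-walk Jacobian
        )
        if np.log(state.rng.uniform()) < delta:
            state.s_z = float(s_new)
            acc_s = True
    return acc_mu, acc_s


def _run_chain(problem: _Problem, config: SamplerConfig, seed_seq, store_z: bool):
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    state = _ChainState(problem, rng)
    state.init()
    for attempt in range(20):
        if state.finite():
            break
        state.init(from_prior=True)
    else:
        raise RuntimeError("could not find a finite-density initial state")

    n_free = int(problem.free.sum())
    chol = 0.1 * np.eye(n_free)
    log_scale_c = 0.0
    log_step_sig = np.log(0.5)
    log_step_tau = np.log(0.5)
    log_step_mu = np.log(0.05)
    log_step_szd = np.log(0.2)
    # running moments of the free coefficients for adaptive covariance
    am_count, am_mean = 0, np.zeros(n_free)
    am_m2 = np.zeros((n_free, n_free))
    # joint scalar block: [c_free, log sigma, log tau, (mu_z, log s_z)]
    d_joint = n_free + 2 + (2 if problem.hier else 0)
    joint_init_sd = np.concatenate(
        [
            np.full(n_free, 0.1),
            [0.2, 0.2],
            [0.05, 0.2] if problem.hier else [],
        ]
    )
    chol_v = np.diag(joint_init_sd)
    log_scale_v = 0.0
    amv_count, amv_mean = 0, np.zeros(d_joint)
    amv_m2 = np.zeros((d_joint, d_joint))

    kept = config.n_iter // config.thin
    c_draws = np.empty((kept, 6))
    sig_draws = np.empty(kept)
    tau_draws = np.empty(kept)
    hyper_draws = np.empty((kept, 2)) if problem.hier else None
    z_draws = np.empty((kept, problem.n)) if store_z else None
    z_total = np.empty(kept)
    z_sum = np.zeros(problem.n)
    z_sumsq = np.zeros(problem.n)
    acc = {"z": 0.0, "coefs": 0, "sigma": 0, "tau": 0, "z_hyper": 0, "joint": 0}

    total_iters = config.n_adapt + config.n_burnin + config.n_iter
    keep_from = config.n_adapt + config.n_burnin
    k = 0
    for t in range(total_iters):
        # the conditional depends on the scalars only, so the z-update and
        # the joint move's reverse density can share it within one sweep
        cond = (
            _z_conditional(
                problem, state.alpha, state.beta, state.sigma, state.tau,
                state.mu_z, state.s_z,
            )
            if problem.n
            else None
        )
        acc["z"] += _update_z(state, cond)
        acc_j = _update_joint(state, chol_v, np.exp(log_scale_v), cond)
        acc["joint"] += acc_j
        acc_c = _update_coefs(state, chol, np.exp(log_scale_c))
        acc["coefs"] += acc_c
        acc_s = _update_scale_param(state, "sigma", np.exp(log_step_sig))
        acc["sigma"] += acc_s
        acc_t = _update_scale_param(state, "tau", np.exp(log_step_tau))
        acc["tau"] += acc_t
        acc_mu, acc_sz = _update_z_hyper(
            state, np.exp(log_step_mu), np.exp(log_step_szd)
        )
        acc["z_hyper"] += 0.5 * (acc_mu + acc_sz)

        if t < config.n_adapt:
            gamma = (t + 10.0) ** -0.6
            log_scale_c += gamma * (acc_c - 0.25)
            log_step_sig += gamma * (acc_s - 0.44)
            log_step_tau += gamma * (acc_t - 0.44)
            log_step_mu += gamma * (acc_mu - 0.44)
            log_step_szd += gamma * (acc_sz - 0.44)
            log_scale_v += gamma * (acc_j - 0.25)
            if n_free:
                am_count += 1
                diff = state.c[problem.free] - am_mean
                am_mean += diff / am_count
                am_m2 += np.outer(diff, state.c[problem.free] - am_mean)
                if am_count >= 100 and am_count % 100 == 0:
                    cov = am_m2 / (am_count - 1)
                    cov[np.diag_indices_from(cov)] += 1e-10
                    try:
                        chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
            v_now = np.concatenate(
                [
                    state.c[problem.free],
                    [np.log(state.sigma), np.log(state.tau)],
                    [state.mu_z, np.log(state.s_z)] if problem.hier else [],
                ]
            )
            amv_count += 1
            diffv = v_now - amv_mean
            amv_mean += diffv / amv_count
            amv_m2 += np.outer(diffv, v_now - amv_mean)
            if amv_count >= 200 and amv_count % 100 == 0:
                covv = amv_m2 / (amv_count - 1)
                covv[np.diag_indices_from(covv)] += 1e-10
                try:
                    chol_v = np.linalg.cholesky(covv)
                except np.linalg.LinAlgError:
                    pass

        if t >= keep_from and (t - keep_from) % config.thin == config.thin - 1:
            c_draws[k] = state.c
            sig_draws[k] = state.sigma
            tau_draws[k] = state.tau
            if problem.hier:
                hyper_draws[k] = (state.mu_z, state.s_z)
            if store_z:
                z_draws[k] = state.z
            z_total[k] = state.z.sum()
            z_sum += state.z
            z_sumsq += state.z**2
            k += 1

    rates = {key: val / total_iters for key, val in acc.items()}
    return c_draws, sig_draws, tau_draws, hyper_draws, z_draws, z_total, z_sum, z_sumsq, rates


def sample_posterior(
    census: CensusLayer,
    survey: SurveyTable,
    priors: PriorSpec,
    config: SamplerConfig,
    fixed: Optional[dict] = None,
    store_z: Optional[bool] = None,
) -> PosteriorDraws:
    """Draw from the joint posterior of the fusion model.

    Parameters
    ----------
    fixed
        Optional mapping pinning coefficients at known values on the original
        coordinate scale, e.g. ``{"delta2": 1.0, "theta": 0.0}``.
    store_z
        Force storing full latent-field draws; by default they are stored
        when the census has at most 20,000 cells, otherwise only per-draw
        totals and running moments are kept.
    """
    problem = _Problem(census, survey, priors, fixed)
    if store_z is None:
        store_z = problem.n <= _Z_STORE_MAX

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    kept = config.n_iter // config.thin
    chains = config.n_chains
    c_all = np.empty((chains, kept, 6))
    scalars = {name: np.empty((chains, kept)) for name in _SCALAR_NAMES}
    if problem.hier:
        scalars["z_mu"] = np.empty((chains, kept))
        scalars["z_sd"] = np.empty((chains, kept))
    z_all = np.empty((chains, kept, problem.n)) if store_z else None
    z_total = np.empty((chains, kept))
    z_sum = np.empty((chains, problem.n))
    z_sumsq = np.empty((chains, problem.n))
    rate_acc: dict[str, float] = {}

    for ci, ss in enumerate(seeds):
        c_d, sig_d, tau_d, hyper_d, z_d, zt, zs, zss, rates = _run_chain(
            problem, config, ss, store_z
        )
        c_all[ci] = c_d
        scalars["sigma"][ci] = sig_d
        scalars["tau"][ci] = tau_d
        if problem.hier:
            scalars["z_mu"][ci] = hyper_d[:, 0]
            scalars["z_sd"][ci] = hyper_d[:, 1]
        if store_z:
            z_all[ci] = z_d
        z_total[ci] = zt
        z_sum[ci] = zs
        z_sumsq[ci] = zss
        for key, val in rates.items():
            rate_acc[key] = rate_acc.get(key, 0.0) + val / chains

    # back-transform coefficient draws to the original coordinate scale
    sc = problem.scaler
    theta1 = c_all[..., 2] / sc.north_sd
    theta2 = c_all[..., 3] / sc.east_sd
    theta3 = c_all[..., 4] / sc.north_sd
    theta4 = c_all[..., 5] / sc.east_sd
    scalars["delta1"] = c_all[..., 0] - theta1 * sc.north_mean - theta2 * sc.east_mean
    scalars["delta2"] = c_all[..., 1] - theta3 * sc.north_mean - theta4 * sc.east_mean
    scalars["theta1"], scalars["theta2"] = theta1, theta2
    scalars["theta3"], scalars["theta4"] = theta3, theta4

    return PosteriorDraws(
        scalars=scalars,
        z_total=z_total,
        z=z_all,
        z_sum=z_sum,
        z_sumsq=z_sumsq,
        cell_id=problem.cell_id,
        accept_rates=rate_acc,
        config=config,
        fixed=problem.fixed,
    )


# --------------------------------------------------------------------------
# diagnostics and summaries


def check_convergence(
    draws: PosteriorDraws,
    config: Optional[SamplerConfig] = None,
    n_z_subsample: int = 100,
) -> ConvergenceReport:
    """Split-Rhat and effective sample size for every scalar parameter and a
    random subsample of latent-field components.

    A parameter whose split-Rhat exceeds the configured threshold flags the
    whole fit; flagged fits still yield summaries but must carry the
    not-converged marker downstream.
    """
    import arviz as az

    if config is None:
        config = draws.config
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")

    arrays: dict[str, np.ndarray] = {}
    for name in _ordered_scalars(draws.scalars):
        if name in draws.fixed or (
            name.startswith("theta") and "theta" in draws.fixed
        ):
            continue
        arrays[name] = draws.scalars[name]
    if draws.z is not None and draws.n_cells:
        rng = np.random.Generator(np.random.PCG64(draws.config.seed + 1))
        take = min(n_z_subsample, draws.n_cells)
        cells = rng.choice(draws.n_cells, size=take, replace=False)
        for cell in cells:
            arrays[f"z[{cell}]"] = draws.z[:, :, cell]
    else:
        arrays["z_total"] = draws.z_total

    rows = []
    for name, ary in arrays.items():
        # degenerate draws: all chains at one constant are trivially
        # converged; chains stuck at different constants are maximally not
        within = np.var(ary, axis=1)
        if np.any(within < 1e-300):
            rhat = 1.0 if np.ptp(ary) == 0 else np.inf
            rows.append((name, rhat, float("nan")))
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat = float(az.rhat(ary))
            ess = float(az.ess(ary))
        if not np.isfinite(rhat):
            rhat = np.inf
        rows.append((name, rhat, ess))
    table = pd.DataFrame(rows, columns=["param", "rhat", "ess"])
    flagged_params = table.loc[
        table["rhat"] > config.rhat_threshold, "param"
    ].tolist()
    return ConvergenceReport(
        table=table,
        flagged=bool(flagged_params),
        threshold=config.rhat_threshold,
        flagged_params=flagged_params,
    )


def summarize_posterior(
    draws: PosteriorDraws,
    quantiles: tuple[float, ...] = (0.025, 0.5, 0.975),
    diagnostics: Optional[ConvergenceReport] = None,
) -> pd.DataFrame:
    """Posterior quantiles for every scalar parameter and the latent total.

    Coefficients are reported on the original coordinate scale.  When a
    convergence report is supplied the summary carries an explicit
    ``converged`` column (and ``attrs['converged']``); a flagged fit means the
    quantiles should not be trusted.
    """
    if draws.n_kept == 0:
        raise ValueError("no posterior draws to summarize")
    rows = {}
    for name in _ordered_scalars(draws.scalars):
        rows[name] = np.quantile(draws.stacked(name), quantiles)
    rows["z_total"] = np.quantile(draws.z_total.reshape(-1), quantiles)
    table = pd.DataFrame(
        rows, index=[f"{100 * q:g}%" for q in quantiles]
    ).T.reset_index(names="param")
    table.attrs["converged"] = None
    if diagnostics is not None:
        table["converged"] = not diagnostics.flagged
        table.attrs["converged"] = not diagnostics.flagged
    return table


def total_extent(
    draws: PosteriorDraws, cell_area: float = 1.0, area_scale: float = 1.0
) -> tuple[float, float, float]:
    """Posterior median and central 95% interval of the total habitat extent.

    Per draw the extent is ``sum_i Z_i * cell_area * area_scale``; with 1 km^2
    cells reported in thousands of hectares use ``cell_area=100`` (ha) and
    ``area_scale=1/1000``.
    """
    if draws.z_total.size == 0:
        raise ValueError("draws carry no latent-field totals")
    totals = draws.z_total.reshape(-1) * cell_area * area_scale
    lower, median, upper = np.quantile(totals, [0.025, 0.5, 0.975])
    return float(median), float(lower), float(upper)
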