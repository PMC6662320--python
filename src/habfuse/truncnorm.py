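"""Zero-truncated normal distribution: the observation-noise model.

Both data layers are modelled as normal draws truncated at zero — proportions
cannot be negative, but classification and mapping noise is otherwise
symmetric.  ``N0(m, s^2)`` denotes the N(m, s^2) density restricted to
``[0, inf)`` and renormalized.  This module provides the exact log-density,
tail-safe sampling, and the Gaussian-combination update used to build
full-conditional proposals in the MCMC sampler.

Truncation is at 0 only; the proportion's upper bound of 1 is enforced by the
prior on the latent field, not by the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "TruncNormSpec",
    "truncnorm_logpdf",
    "truncnorm_sample",
    "truncnorm_conditional_update",
    "sample_trunc_interval",
]

# mean/sd below this ratio the inverse-CDF map loses double precision;
# delegate those draws to scipy's rejection-based sampler
_TAIL_RATIO = -6.0


@dataclass(frozen=True)
class TruncNormSpec:
    """Normal distribution truncated below at ``lower`` (default 0).

    ``mean`` and ``sd`` are the parameters of the parent (untruncated)
    normal, not the moments of the truncated law.
    """

    mean: float
    sd: float
    lower: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError(f"sd must be strictly positive, got {self.sd}")
        if not (np.isfinite(self.mean) and np.isfinite(self.sd)):
            raise ValueError("mean and sd must be finite")


def truncnorm_logpdf(x, spec: TruncNormSpec):
    """Log-density of the truncated normal; ``-inf`` below the truncation point.

    Vectorized over ``x``.  The normalizing constant ``P(X >= lower)`` is
    evaluated with ``log_ndtr`` so specs whose mean sits far below the
    truncation point stay finite.
    """
    x = np.asarray(x, dtype=float)
    z = (x - spec.mean) / spec.sd
    log_norm = special.log_ndtr((spec.mean - spec.lower) / spec.sd)
    out = -0.5 * z * z - 0.5 * np.log(2.0 * np.pi) - np.log(spec.sd) - log_norm
    out = np.where(x < spec.lower, -np.inf, out)
    return out if out.ndim else float(out)


def truncnorm_sample(spec: TruncNormSpec, n: int, rng: np.random.Generator):
    """Draw ``n`` reproducible samples from the truncated normal.

    Inverse-CDF transform for well-conditioned specs; when the mean lies more
    than ``6 sd`` below the truncation point the CDF saturates in double
    precision and the draw is delegated to scipy's truncnorm sampler, which
    handles far tails by rejection.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty(0)
    a = (spec.lower - spec.mean) / spec.sd
    if -a < _TAIL_RATIO:  # mean far below the truncation point
        return stats.truncnorm.rvs(
            a, np.inf, loc=spec.mean, scale=spec.sd, size=n, random_state=rng
        )
    p_lo = special.ndtr(a)
    u = rng.uniform(size=n)
    return spec.mean + spec.sd * special.ndtri(p_lo + u * (1.0 - p_lo))


def sample_trunc_interval(mean, sd, lower, upper, rng: np.random.Generator):
    """Vectorized draws from normals truncated to ``[lower, upper]``.

    Hot-loop primitive for the sampler's latent-field proposals: all
    parameters may be arrays of a common shape.  Inverse-CDF in the bulk;
    elements whose interval lies deep in a tail (CDF saturated) fall back to
    scipy's rejection sampler.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    p_lo = special.ndtr(a)
    p_hi = special.ndtr(b)
    u = rng.uniform(size=mean.shape)
    with np.errstate(invalid="ignore"):
        x = mean + sd * special.ndtri(p_lo + u * (p_hi - p_lo))
    bad = ~((x >= lower) & (x <= upper)) | (p_hi - p_lo < 1e-12)
    if np.any(bad):
        x = np.array(x, copy=True)
        x[bad] = stats.truncnorm.rvs(
            a[bad], b[bad], loc=mean[bad], scale=sd[bad], random_state=rng
        )
    return x


def truncnorm_conditional_update(
    prior_mean: float,
    prior_sd: float,
    obs_terms: list[tuple[float, float, float, float]],
) -> TruncNormSpec:
    """Precision-weighted Gaussian combination of a prior and linear-Gaussian
    observation terms, returned as a zero-truncated spec.

    Each observation term ``(coef, offset, value, sd)`` contributes a
    ``N0(offset + coef * Z, sd^2)`` likelihood for the observed ``value``.
    The combination treats these terms as *untruncated* Gaussians in ``Z``:
    the Z-dependence of each term's truncation constant is ignored, which is
    accurate when ``sd`` is small relative to the term's mean and is in any
    case corrected by the Metropolis accept/reject step that consumes the
    resulting spec as a proposal.
    """
    if not (prior_sd > 0):
        raise ValueError("prior_sd must be strictly positive")
    prec = 1.0 / prior_sd**2
    num = prior_mean / prior_sd**2
    for coef, offset, value, sd in obs_terms:
        if not (sd > 0):
            raise ValueError("observation sd must be strictly positive")
        prec += coef * coef / sd**2
        num += coef * (value - offset) / sd**2
    return TruncNormSpec(mean=num / prec, sd=1.0 / np.sqrt(prec))
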