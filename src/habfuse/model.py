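"""Joint observation model for fusing survey and census habitat proportions.

The latent quantity is ``Z_i``, the true proportion of grid cell ``i`` covered
by the habitat.  Two imperfect observation layers inform it:

* ground survey (sparse, unbiased):      ``Y_i ~ N0(Z_i, sigma^2)``
* remote-sensing census (dense, biased): ``Q_i ~ N0(alpha_i + beta_i Z_i, tau^2)``

where ``N0`` is the normal distribution truncated at zero and the bias surface
varies linearly with location:

    alpha_i = delta1 + theta1 * northing_i + theta2 * easting_i
    beta_i  = delta2 + theta3 * northing_i + theta4 * easting_i

Priors: ``Z_i ~ U(0, 1)`` independently (the weakest proper prior that also
enforces the proportion's upper bound, absent from the truncated-normal
likelihood); ``sigma ~ U(sigma_lower, sigma_upper)`` — informative, elicited
from QA repeat visits; ``tau ~ U(0, tau_upper)`` — weak; the bias coefficients
get diffuse zero-mean Gaussians *on standardized coordinates* (easting and
northing centred and scaled to unit sd), which keeps the prior meaningful
regardless of whether coordinates are metres or grid indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import CensusLayer, QATable, SurveyTable
from .truncnorm import TruncNormSpec, truncnorm_logpdf

__all__ = [
    "ModelParams",
    "PriorSpec",
    "CoordScaler",
    "bias_surface",
    "log_joint",
    "elicit_sigma_prior",
    "InsufficientQAError",
    "DegeneratePriorWarning",
]

_COEF_NAMES = ("delta1", "delta2", "theta1", "theta2", "theta3", "theta4")


class InsufficientQAError(ValueError):
    """QA table too small to elicit a survey-error prior."""


class DegeneratePriorWarning(UserWarning):
    """Elicited prior has zero width and must be widened by the caller."""


@dataclass
class ModelParams:
    """The eight scalar model parameters plus the latent proportion field.

    Coefficients are on the *original* coordinate scale of the census layer.
    """

    delta1: float
    delta2: float
    theta1: float
    theta2: float
    theta3: float
    theta4: float
    sigma: float
    tau: float
    z: np.ndarray = field(default_factory=lambda: np.empty(0))
    z_mu: float = 0.5
    z_sd: float = 2.0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        for name in _COEF_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def validate(self, n_cells: int) -> None:
        if not (self.sigma > 0 and self.tau > 0):
            raise ValueError("sigma and tau must be strictly positive")
        if len(self.z) != n_cells:
            raise ValueError("latent field length must equal census size")
        if len(self.z) and (self.z.min() < 0 or self.z.max() > 1):
            raise ValueError("latent field must lie in [0, 1]")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the prior distributions.

    sigma_lower, sigma_upper
        Bounds of the uniform prior on the survey error sd (proportion
        units); typically elicited from QA resurveys.
    tau_upper
        Upper bound of the weak uniform prior on the census error sd;
        default 1 leaves it highly flexible.
    coef_sd
        sd of the diffuse zero-mean Gaussian priors on the bias coefficients,
        applied on standardized coordinates; default 10.
    z_prior
        ``"hierarchical"`` (default): ``Z_i ~ TN_[0,1](z_mu, z_sd^2)`` with
        hyperpriors ``z_mu ~ U(*z_mu_range)`` and ``z_sd ~ U(*z_sd_range)``,
        so the latent field learns its own location and spread — essential
        for identifiability when the habitat is sparse (true proportions far
        more concentrated than uniform).  ``"uniform"``: independent U(0, 1)
        per cell (the diffuse limit; used by reduced-model oracles).
    """

    sigma_lower: float = 0.0
    sigma_upper: float = 0.1
    tau_upper: float = 1.0
    coef_sd: float = 10.0
    z_prior: str = "hierarchical"
    z_mu_range: tuple[float, float] = (0.0, 1.0)
    z_sd_range: tuple[float, float] = (0.01, 2.0)

    def __post_init__(self) -> None:
        if not (0 <= self.sigma_lower < self.sigma_upper):
            raise ValueError("need 0 <= sigma_lower < sigma_upper")
        if not (self.tau_upper > 0):
            raise ValueError("tau_upper must be positive")
        if not (self.coef_sd > 0):
            raise ValueError("coef_sd must be positive")
        if self.z_prior not in ("hierarchical", "uniform"):
            raise ValueError("z_prior must be 'hierarchical' or 'uniform'")
        if not (0 <= self.z_mu_range[0] < self.z_mu_range[1] <= 1):
            raise ValueError("z_mu_range must be a sub-interval of [0, 1]")
        if not (0 < self.z_sd_range[0] < self.z_sd_range[1]):
            raise ValueError("z_sd_range must be a positive interval")


@dataclass(frozen=True)
class CoordScaler:
    """Centre/scale statistics mapping raw coordinates to standardized ones."""

    east_mean: float
    east_sd: float
    north_mean: float
    north_sd: float

    @classmethod
    def fit(cls, census: CensusLayer) -> "CoordScaler":
        if len(census) == 0:
            return cls(0.0, 1.0, 0.0, 1.0)
        e_sd = float(np.std(census.easting))
        n_sd = float(np.std(census.northing))
        return cls(
            east_mean=float(np.mean(census.easting)),
            east_sd=e_sd if e_sd > 0 else 1.0,
            north_mean=float(np.mean(census.northing)),
            north_sd=n_sd if n_sd > 0 else 1.0,
        )

    def transform(self, easting, northing):
        return (
            (np.asarray(easting, dtype=float) - self.east_mean) / self.east_sd,
            (np.asarray(northing, dtype=float) - self.north_mean) / self.north_sd,
        )

    def coefs_to_standardized(self, params: ModelParams) -> np.ndarray:
        """Map original-scale (delta, theta) to standardized-coordinate coefs.

        With ``n_s = (n - mn)/sn`` and ``e_s = (e - me)/se`` the linear
        predictors are unchanged when
        ``theta_s = theta * s`` and ``delta_s = delta + theta1*mn + theta2*me``.
        """
        t1s = params.theta1 * self.north_sd
        t2s = params.theta2 * self.east_sd
        t3s = params.theta3 * self.north_sd
        t4s = params.theta4 * self.east_sd
        d1s = params.delta1 + params.theta1 * self.north_mean + params.theta2 * self.east_mean
        d2s = params.delta2 + params.theta3 * self.north_mean + params.theta4 * self.east_mean
        return np.array([d1s, d2s, t1s, t2s, t3s, t4s])

    def coefs_from_standardized(self, coefs: np.ndarray) -> dict[str, float]:
        d1s, d2s, t1s, t2s, t3s, t4s = coefs
        theta1 = t1s / self.north_sd
        theta2 = t2s / self.east_sd
        theta3 = t3s / self.north_sd
        theta4 = t4s / self.east_sd
        return {
            "delta1": float(d1s - theta1 * self.north_mean - theta2 * self.east_mean),
            "delta2": float(d2s - theta3 * self.north_mean - theta4 * self.east_mean),
            "theta1": float(theta1),
            "theta2": float(theta2),
            "theta3": float(theta3),
            "theta4": float(theta4),
        }


def bias_surface(easting, northing, params: ModelParams):
    """Evaluate the spatially varying bias fields (alpha, beta).

    Vectorized over coordinates; coefficients are on the same (original)
    coordinate scale as the inputs.
    """
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    alpha = params.delta1 + params.theta1 * northing + params.theta2 * easting
    beta = params.delta2 + params.theta3 * northing + params.theta4 * easting
    return alpha, beta


def log_joint(
    census: CensusLayer,
    survey: SurveyTable,
    params: ModelParams,
    priors: PriorSpec,
) -> float:
    """Unnormalized log posterior density: likelihood of both layers + priors.

    Returns ``-inf`` whenever a parameter falls outside its prior support
    (sigma or tau outside their uniform bounds, any ``z`` outside [0, 1]).
    Survey cells must resolve to census cells.  The coefficient prior is
    evaluated on standardized coordinates (see module docstring); this is the
    same density the MCMC sampler targets.
    """
    n = len(census)
    if len(params.z) != n:
        raise ValueError("latent field length must equal census size")
    if not (priors.sigma_lower < params.sigma < priors.sigma_upper):
        return -np.inf
    if not (0.0 < params.tau < priors.tau_upper):
        return -np.inf
    if n and (params.z.min() < 0.0 or params.z.max() > 1.0):
        return -np.inf

    total = 0.0
    # survey layer: Y_i ~ N0(Z_i, sigma^2)
    if len(survey):
        idx = census.index_of(survey.cell_id)
        z_s = params.z[idx]
        total += float(
            np.sum(_tn_logpdf_vec(survey.y, z_s, params.sigma))
        )
    # census layer: Q_i ~ N0(alpha_i + beta_i Z_i, tau^2)
    if n:
        alpha, beta = bias_surface(census.easting, census.northing, params)
        total += float(
            np.sum(_tn_logpdf_vec(census.q, alpha + beta * params.z, params.tau))
        )

    # priors
    scaler = CoordScaler.fit(census)
    coefs_s = scaler.coefs_to_standardized(params)
    total += float(
        np.sum(-0.5 * (coefs_s / priors.coef_sd) ** 2)
        - len(coefs_s) * (0.5 * np.log(2 * np.pi) + np.log(priors.coef_sd))
    )
    total += -np.log(priors.sigma_upper - priors.sigma_lower)  # sigma ~ U
    total += -np.log(priors.tau_upper)  # tau ~ U(0, tau_upper)
    if priors.z_prior == "hierarchical":
        mu_lo, mu_hi = priors.z_mu_range
        sd_lo, sd_hi = priors.z_sd_range
        if not (mu_lo <= params.z_mu <= mu_hi and sd_lo <= params.z_sd <= sd_hi):
            return -np.inf
        total += float(np.sum(trunc01_logpdf(params.z, params.z_mu, params.z_sd)))
        total += -np.log(mu_hi - mu_lo) - np.log(sd_hi - sd_lo)
    # uniform z prior contributes 0 on its support
    return total


def trunc01_logpdf(z, mu, sd):
    """Log-density of N(mu, sd^2) doubly truncated to [0, 1] (vectorized)."""
    from scipy.special import ndtr

    z = np.asarray(z, dtype=float)
    r = (z - mu) / sd
    norm = ndtr((1.0 - mu) / sd) - ndtr(-mu / sd)
    out = -0.5 * r * r - 0.5 * np.log(2 * np.pi) - np.log(sd) - np.log(norm)
    return np.where((z < 0) | (z > 1), -np.inf, out)


def _tn_logpdf_vec(x, mean, sd):
    """Zero-truncated normal log-density with array mean (internal)."""
    from scipy import special

    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    zed = (x - mean) / sd
    out = (
        -0.5 * zed * zed
        - 0.5 * np.log(2 * np.pi)
        - np.log(sd)
        - special.log_ndtr(mean / sd)
    )
    return np.where(x < 0, -np.inf, out)


def elicit_sigma_prior(qa: QATable, inflation: float = 2.0) -> tuple[float, float]:
    """Uniform prior bounds for the survey error sd from QA repeat visits.

    Each visit observes the truth with independent error of sd ``sigma``, so
    the between-visit difference has sd ``sigma * sqrt(2)``; the point
    estimate is ``sd(y_first - y_second) / sqrt(2)``.  The returned bounds
    ``(0, inflation * sigma_hat)`` widen the point estimate into a proper
    uniform prior; ``inflation`` defaults to 2.
    """
    if len(qa) < 2:
        raise InsufficientQAError("need at least 2 QA rows to elicit a prior")
    if inflation < 1:
        raise ValueError("inflation must be >= 1")
    diffs = qa.y_first - qa.y_second
    sigma_hat = float(np.std(diffs, ddof=1) / np.sqrt(2.0))
    if sigma_hat == 0.0:
        warnings.warn(
            "all QA repeat visits identical: elicited prior is degenerate "
            "(0, 0); widen it before fitting",
            DegeneratePriorWarning,
            stacklevel=2,
        )
    return 0.0, inflation * sigma_hat
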