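"""Latent (liability) to observed (binary) scale heritability conversion.

A threshold trait analysed on the liability scale has additive variance
sigma2_a in latent units; on the observed 0/1 scale part of that variance
becomes non-additive through the probit link, so observed-scale
heritability is always strictly smaller.  For a probit link the Gaussian
integrals have closed forms: with linear predictor mu_j on design row j and
total non-residual random variance sigma2_re (animal + maternal),

    t_j    = mu_j / sqrt(1 + sigma2_re)
    p_j    = Phi(t_j)                       expected proportion male, row j
    Psi_j  = phi(t_j) / sqrt(1 + sigma2_re) d p_j / d mu_j

    p            = mean_j p_j
    sigma2_a,obs = (mean_j Psi_j)^2 * sigma2_a
    var_obs      = mean_j[p_j (1 - p_j)] + Var_j(p_j)  =  p (1 - p)
    h2_obs       = sigma2_a,obs / var_obs

With a single design row this reduces to the classic Dempster–Lerner
formula h2_obs = h2_lat * z^2 / (p (1 - p)) with z the normal density at
the threshold quantile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .animal_model import PosteriorSamples

__all__ = [
    "LatentParams",
    "ObservedParams",
    "latent_to_observed",
    "dempster_lerner",
    "posterior_observed_h2",
]


@dataclass(frozen=True)
class LatentParams:
    """Latent-scale parameters of one posterior draw (residual variance 1).

    ``mu_values`` holds the fixed-effect linear predictor over the observed
    design rows (a single value when the model has only an intercept);
    ``sigma2_re`` is the total non-residual random variance
    (sigma2_a + sigma2_m).
    """

    mu_values: np.ndarray
    sigma2_a: float
    sigma2_re: float

    def __post_init__(self):
        object.__setattr__(self, "mu_values", np.atleast_1d(np.asarray(self.mu_values, dtype=float)))
        if self.mu_values.size == 0:
            raise ValueError("no design rows")
        if self.sigma2_a < 0 or self.sigma2_re < 0:
            raise ValueError("variances must be non-negative")
        if self.sigma2_a > self.sigma2_re + 1e-9:
            raise ValueError("sigma2_a cannot exceed total random variance")

    @property
    def h2_latent(self) -> float:
        return self.sigma2_a / (self.sigma2_re + 1.0)


@dataclass(frozen=True)
class ObservedParams:
    """Observed-scale parameters implied by one latent draw."""

    p: float
    var_obs: float
    sigma2_a_obs: float
    h2_obs: float


def latent_to_observed(lp: LatentParams) -> ObservedParams:
    """Exact probit-link conversion, averaging over design rows."""
    s = np.sqrt(1.0 + lp.sigma2_re)
    t = lp.mu_values / s
    p_j = norm.cdf(t)
    psi_j = norm.pdf(t) / s
    p = float(p_j.mean())
    sigma2_a_obs = float(psi_j.mean() ** 2 * lp.sigma2_a)
    var_obs = float(np.mean(p_j * (1.0 - p_j)) + np.var(p_j))
    h2 = sigma2_a_obs / var_obs if var_obs > 0 else 0.0
    return ObservedParams(p=p, var_obs=var_obs, sigma2_a_obs=sigma2_a_obs, h2_obs=float(h2))


def dempster_lerner(h2_lat: float, p: float) -> float:
    """Closed-form threshold-trait conversion h2_obs = h2_lat z^2 / (p(1-p)).

    ``p`` is the trait prevalence (proportion male) and z the standard
    normal density at the threshold quantile Phi^-1(p).  At p = 1/2 the
    factor equals 2/pi.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("degenerate prevalence: p must lie in (0, 1)")
    if not (0.0 <= h2_lat <= 1.0):
        raise ValueError("h2_lat must lie in [0, 1]")
    z = norm.pdf(norm.ppf(p))
    return float(h2_lat * z * z / (p * (1.0 - p)))


def posterior_observed_h2(
    samples: PosteriorSamples,
    design: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Observed-scale heritability for every posterior draw.

    Per draw, the linear predictor over the observed design rows (X beta)
    and the variance components define a :class:`LatentParams`; the probit
    conversion is applied draw by draw so the posterior of h2_obs reflects
    the joint posterior of all components.
    """
    if samples.sigma2_a is None:
        raise ValueError("samples contain no additive variance component")
    X = design if design is not None else samples.design_matrix
    if X is None:
        raise ValueError("design required")
    p = samples.beta.shape[-1]
    if X.ndim != 2 or X.shape[1] != p:
        raise ValueError("shape mismatch between design and coefficient draws")
    betas = samples.beta.reshape(-1, p)
    sa = samples.stacked("sigma2_a")
    sm = samples.stacked("sigma2_m") if samples.sigma2_m is not None else np.zeros_like(sa)
    mu = X @ betas.T  # rows x draws
    out = np.empty(len(sa))
    for k in range(len(sa)):
        lp = LatentParams(mu_values=mu[:, k], sigma2_a=sa[k], sigma2_re=sa[k] + sm[k])
        out[k] = latent_to_observed(lp).h2_obs
    return out
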