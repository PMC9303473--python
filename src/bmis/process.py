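"""Bivariate hierarchical random-walk process model on probit-scale
sensitivity and specificity.

Each country carries a latent time series of probit-transformed sensitivity
and specificity over the estimation grid of T years.  The series is
parameterized by its *mean level* plus its T-1 *first-order differences*:
with W the (T-1) x T differencing matrix and D = W' (W W')^-1 its
pseudo-inverse reconstruction,

    eta_{1:T} = eta_mean + D @ xi,        xi = W @ eta_{1:T}.

Country mean levels are bivariate-normal around global levels with
between-country SDs (sigma_sens, sigma_spec) and correlation rho; the
year-over-year innovations are zero-mean bivariate normal with SDs
(delta_sens, delta_spec) and correlation phi.  Probabilities are recovered
with the standard-normal CDF.

Priors: uniform(0,1) on the two global probabilities, uniform(-1,1) on both
correlations, standard half-normal on the four SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "Hyperparameters",
    "CountryLatent",
    "RWBasis",
    "build_rw_basis",
    "reconstruct_series",
    "probit_to_prob",
    "prob_to_probit",
    "bvn_logpdf",
    "log_prior",
    "sample_prior",
]

HYPERPARAMETER_NAMES = (
    "lambda_global_sens",
    "lambda_global_spec",
    "rho",
    "sigma_sens",
    "sigma_spec",
    "phi",
    "delta_sens",
    "delta_spec",
)


def probit_to_prob(eta):
    """Probability from its probit: the standard-normal CDF."""
    return ndtr(eta)


def prob_to_probit(p):
    """Probit (inverse standard-normal CDF) of a probability in (0,1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("probability must be strictly inside (0, 1)")
    out = ndtri(p)
    return float(out) if out.ndim == 0 else out


def _cov2(sd1: float, sd2: float, corr: float) -> np.ndarray:
    off = corr * sd1 * sd2
    return np.array([[sd1**2, off], [off, sd2**2]])


@dataclass(frozen=True)
class Hyperparameters:
    """Global levels and variance components of the hierarchical model.

    Parameters
    ----------
    lambda_global_sens, lambda_global_spec
        Global sensitivity and specificity, probability scale, in (0, 1).
    sigma_sens, sigma_spec
        Between-country SDs of the mean probit levels (> 0).
    rho
        Between-country correlation of mean levels, in (-1, 1).
    delta_sens, delta_spec
        SDs of the year-over-year probit-scale innovations (> 0).
    phi
        Correlation of the paired innovations, in (-1, 1).
    """

    lambda_global_sens: float
    lambda_global_spec: float
    sigma_sens: float
    sigma_spec: float
    rho: float
    delta_sens: float
    delta_spec: float
    phi: float

    def __post_init__(self):
        for name in ("lambda_global_sens", "lambda_global_spec"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("sigma_sens", "sigma_spec", "delta_sens", "delta_spec"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("rho", "phi"):
            v = getattr(self, name)
            if not (-1.0 < v < 1.0):
                raise ValueError(f"{name} must be in (-1,1), got {v}")

    @property
    def eta_global(self) -> np.ndarray:
        """Global mean levels on the probit scale, shape (2,)."""
        return np.array(
            [prob_to_probit(self.lambda_global_sens), prob_to_probit(self.lambda_global_spec)]
        )

    def level_cov(self) -> np.ndarray:
        """Between-country covariance of (probit sens, probit spec) levels."""
        return _cov2(self.sigma_sens, self.sigma_spec, self.rho)

    def innovation_cov(self) -> np.ndarray:
        """Covariance of the paired first-order differences."""
        return _cov2(self.delta_sens, self.delta_spec, self.phi)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in HYPERPARAMETER_NAMES])


@dataclass(frozen=True)
class CountryLatent:
    """One country's latent state: mean probit levels and differences."""

    eta_mean_sens: float
    eta_mean_spec: float
    xi_sens: np.ndarray  # length T-1
    xi_spec: np.ndarray  # length T-1


@dataclass(frozen=True)
class RWBasis:
    """First-difference matrix W and its reconstruction pseudo-inverse D."""

    W: np.ndarray  # (T-1, T)
    D: np.ndarray  # (T, T-1)

    @property
    def T(self) -> int:
        return self.W.shape[1]


def build_rw_basis(T: int) -> RWBasis:
    """Build W (rows -1, 1 on the diagonal band) and D = W' (W W')^-1."""
    if T < 2:
        raise ValueError(f"grid length must be >= 2, got {T}")
    W = np.zeros((T - 1, T))
    idx = np.arange(T - 1)
    W[idx, idx] = -1.0
    W[idx, idx + 1] = 1.0
    D = W.T @ np.linalg.inv(W @ W.T)
    return RWBasis(W=W, D=D)


def reconstruct_series(mean_level: float, diffs: np.ndarray, basis: RWBasis) -> np.ndarray:
    """Series with the given mean and first-order differences: mean + D @ diffs."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.shape != (basis.T - 1,):
        raise ValueError(
            f"expected {basis.T - 1} differences, got shape {diffs.shape}"
        )
    return mean_level + basis.D @ diffs


def bvn_logpdf(x: np.ndarray, mean: np.ndarray, sd1: float, sd2: float, corr: float):
    """Log-density of N2(mean, cov(sd1, sd2, corr)) at rows of x, closed form."""
    x = np.atleast_2d(x)
    a = (x[..., 0] - mean[0]) / sd1
    b = (x[..., 1] - mean[1]) / sd2
    om = 1.0 - corr**2
    quad = (a**2 - 2.0 * corr * a * b + b**2) / om
    return -np.log(2.0 * np.pi * sd1 * sd2 * np.sqrt(om)) - 0.5 * quad


def _halfnormal_logpdf(x: float, scale: float = 1.0) -> float:
    if x <= 0:
        return float("-inf")
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


def log_prior(hyper, latents: list[CountryLatent]) -> float:
    """Joint log-density of hyperpriors and latent country states.

    Sums the hyperprior terms (uniform globals and correlations, standard
    half-normal SDs), the bivariate-normal density of each country's mean
    levels around the global levels, and the bivariate-normal density of
    each paired innovation.  ``hyper`` may be any object exposing the
    hyperparameter fields; out-of-support values yield ``-inf``.
    """
    lp = 0.0
    for name in ("lambda_global_sens", "lambda_global_spec"):
        v = getattr(hyper, name)
        if not (0.0 < v < 1.0):
            return float("-inf")
    for name in ("rho", "phi"):
        v = getattr(hyper, name)
        if not (-1.0 < v < 1.0):
            return float("-inf")
        lp += np.log(0.5)
    for name in ("sigma_sens", "sigma_spec", "delta_sens", "delta_spec"):
        term = _halfnormal_logpdf(getattr(hyper, name))
        if not np.isfinite(term):
            return float("-inf")
        lp += term

    mu = np.array(
        [ndtri(hyper.lambda_global_sens), ndtri(hyper.lambda_global_spec)]
    )
    means = np.array([[c.eta_mean_sens, c.eta_mean_spec] for c in latents])
    lp += bvn_logpdf(means, mu, hyper.sigma_sens, hyper.sigma_spec, hyper.rho).sum()
    xi = np.concatenate(
        [np.column_stack([c.xi_sens, c.xi_spec]) for c in latents], axis=0
    )
    lp += bvn_logpdf(
        xi, np.zeros(2), hyper.delta_sens, hyper.delta_spec, hyper.phi
    ).sum()
    return float(lp)


def sample_prior(
    hyper: Hyperparameters,
    n_countries: int,
    T: int,
    seed: int | np.random.Generator = 0,
):
    """Draw country latents from the hierarchy and return probability series.

    Returns ``(latents, sens, spec)`` where ``sens`` and ``spec`` are
    (n_countries, T) arrays of probabilities.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    basis = build_rw_basis(T)
    mu = hyper.eta_global
    means = rng.multivariate_normal(mu, hyper.level_cov(), size=n_countries)
    xi = rng.multivariate_normal(
        np.zeros(2), hyper.innovation_cov(), size=(n_countries, T - 1)
    )
    latents = []
    eta = np.empty((n_countries, T, 2))
    for c in range(n_countries):
        latents.append(
            CountryLatent(
                eta_mean_sens=float(means[c, 0]),
                eta_mean_spec=float(means[c, 1]),
                xi_sens=xi[c, :, 0].copy(),
                xi_spec=xi[c, :, 1].copy(),
            )
        )
        eta[c, :, 0] = reconstruct_series(means[c, 0], xi[c, :, 0], basis)
        eta[c, :, 1] = reconstruct_series(means[c, 1], xi[c, :, 1], basis)
    return latents, probit_to_prob(eta[:, :, 0]), probit_to_prob(eta[:, :, 1])
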