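"""Cell probabilities and exact likelihoods for misclassified death counts.

A death in the CRVS envelope falls in one of four cells — T+ (maternal,
coded maternal), F+ (non-maternal, coded maternal), F- (maternal, coded
non-maternal), T- (non-maternal, coded non-maternal) — with probabilities
parameterized by sensitivity ``se``, specificity ``sp`` and the true
maternal proportion ``g``::

    P(T+) = se * g          P(F-) = (1 - se) * g
    P(T-) = sp * (1 - g)    P(F+) = (1 - sp) * (1 - g)

Study counts are multinomial draws from these cells.  Studies that report
only the study-confirmed maternal total and the CRVS-coded maternal total
give two *overlapping* marginals of the latent 2x2 table; their exact
likelihood is obtained by enumerating every latent table consistent with
the marginals and summing the multinomial probabilities.  The table set is
one-dimensional: fixing the T+ count determines the other three cells.

Cell vectors throughout this module use the order ``(T+, F+, F-, T-)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

__all__ = [
    "MisclassParams",
    "CellProbabilities",
    "LatentTable",
    "cell_probs",
    "reported_pm_prob",
    "multinomial_logpmf",
    "enumerate_tables",
    "table_array",
    "exclusion_quantile",
    "exclusion_indicator",
    "loglik_true_total",
    "loglik_dispatch",
]

#: Binomial success probability used when pruning negligible latent tables:
#: tables are dropped when their T- count falls below the 0.025 quantile of
#: Binomial(z_crvs - z_true, EXCLUSION_P).
EXCLUSION_P = 0.97
EXCLUSION_QUANTILE = 0.025

CELL_ORDER = ("tpos", "fpos", "fneg", "tneg")


@dataclass(frozen=True)
class MisclassParams:
    """Sensitivity, specificity and true maternal proportion within the CRVS."""

    sens: float
    spec: float
    gamma_true: float

    def __post_init__(self):
        if not (0.0 < self.sens < 1.0):
            raise ValueError(f"sens must be in (0,1), got {self.sens}")
        if not (0.0 < self.spec < 1.0):
            raise ValueError(f"spec must be in (0,1), got {self.spec}")
        if not (1e-4 < self.gamma_true < 1.0):
            raise ValueError(
                f"gamma_true must be in (0.0001, 1), got {self.gamma_true}"
            )


@dataclass(frozen=True)
class CellProbabilities:
    """Probabilities of the four classification cells; they sum to one."""

    g_tpos: float
    g_fpos: float
    g_fneg: float
    g_tneg: float

    def __post_init__(self):
        total = self.g_tpos + self.g_fpos + self.g_fneg + self.g_tneg
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"cell probabilities sum to {total!r}, not 1")
        for name in CELL_ORDER:
            v = getattr(self, f"g_{name}")
            if not (-1e-15 <= v <= 1.0 + 1e-15):
                raise ValueError(f"g_{name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.g_tpos, self.g_fpos, self.g_fneg, self.g_tneg])

    @property
    def g_mat(self) -> float:
        """Probability a CRVS death is *coded* maternal."""
        return self.g_tpos + self.g_fpos

    @property
    def g_true(self) -> float:
        """Probability a CRVS death is *truly* maternal."""
        return self.g_tpos + self.g_fneg


@dataclass(frozen=True)
class LatentTable:
    """One complete 2x2 table of counts consistent with a study's marginals."""

    tpos: int
    fpos: int
    fneg: int
    tneg: int

    def as_array(self) -> np.ndarray:
        return np.array([self.tpos, self.fpos, self.fneg, self.tneg])

    @property
    def total(self) -> int:
        return self.tpos + self.fpos + self.fneg + self.tneg


def cell_probs(params: MisclassParams) -> CellProbabilities:
    """Map (sensitivity, specificity, true proportion) to the four cells."""
    g = params.gamma_true
    g_tpos = params.sens * g
    g_fneg = g - g_tpos
    g_tneg = params.spec * (1.0 - g)
    g_fpos = (1.0 - g) - g_tneg
    return CellProbabilities(g_tpos=g_tpos, g_fpos=g_fpos, g_fneg=g_fneg, g_tneg=g_tneg)


def reported_pm_prob(params: MisclassParams) -> float:
    """Probability a CRVS death is coded maternal: se*g + (1-sp)*(1-g)."""
    return params.sens * params.gamma_true + (1.0 - params.spec) * (
        1.0 - params.gamma_true
    )


def multinomial_logpmf(counts, probs, total: int | None = None) -> float:
    """Multinomial log-pmf via log-gamma factorials (overflow-safe).

    ``counts`` and ``probs`` may cover the four cells or any merged set of
    categories.  Cells with zero probability contribute ``-inf`` unless
    their count is zero.
    """
    counts = np.asarray(counts)
    probs = np.asarray(probs, dtype=float)
    if counts.shape != probs.shape:
        raise ValueError(f"length mismatch: {counts.shape} vs {probs.shape}")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    n = int(counts.sum())
    if total is not None and total != n:
        raise ValueError(f"counts sum to {n}, expected total {total}")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(probs)
    terms = np.where(counts == 0, 0.0, terms)
    return float(gammaln(n + 1) - gammaln(counts + 1).sum() + terms.sum())


def _tpos_bounds(z_crvs: int, z_mat: int, z_true: int) -> tuple[int, int]:
    lo = max(0, z_mat + z_true - z_crvs)
    hi = min(z_mat, z_true)
    if z_mat > z_crvs or z_true > z_crvs or lo > hi:
        raise ValueError(
            f"infeasible marginals: z_crvs={z_crvs}, z_mat={z_mat}, z_true={z_true}"
        )
    return lo, hi


def table_array(z_crvs: int, z_mat: int, z_true: int) -> np.ndarray:
    """All latent tables consistent with the marginals, as an (S, 4) array.

    Columns follow :data:`CELL_ORDER`; row ``s`` has
    ``tpos = lo + s, fpos = z_mat - tpos, fneg = z_true - tpos,
    tneg = z_crvs - z_mat - z_true + tpos``.
    """
    lo, hi = _tpos_bounds(z_crvs, z_mat, z_true)
    tpos = np.arange(lo, hi + 1)
    return np.column_stack(
        [tpos, z_mat - tpos, z_true - tpos, z_crvs - z_mat - z_true + tpos]
    )


def enumerate_tables(z_crvs: int, z_mat: int, z_true: int) -> list[LatentTable]:
    """Enumerate latent tables matching overlapping marginals (one per T+)."""
    return [LatentTable(*map(int, row)) for row in table_array(z_crvs, z_mat, z_true)]


def exclusion_quantile(z_crvs: int, z_true: int, p: float = EXCLUSION_P) -> float:
    """Pruning threshold for T-: the 0.025 quantile of Binomial(z_crvs - z_true, p)."""
    n = z_crvs - z_true
    if n < 0:
        raise ValueError("z_true exceeds z_crvs")
    if n == 0:
        return 0.0
    return float(binom.ppf(EXCLUSION_QUANTILE, n, p))


def exclusion_indicator(
    table: LatentTable, z_crvs: int, z_true: int, p: float = EXCLUSION_P
) -> int:
    """1 if the table is kept, 0 if pruned as having negligible probability.

    A table survives iff its T- count strictly exceeds the binomial
    threshold of :func:`exclusion_quantile` — i.e. tables whose implied
    specificity-side count is implausibly low are dropped.  Pruning only
    matters computationally: it shrinks the enumeration sum for studies
    with very large envelopes.
    """
    return int(table.tneg > exclusion_quantile(z_crvs, z_true, p))


def _keep_mask(tables: np.ndarray, z_crvs: int, z_true: int) -> np.ndarray:
    q = exclusion_quantile(z_crvs, z_true)
    return tables[:, 3] > q


def loglik_true_total(
    z_crvs: int,
    z_mat: int,
    z_true: int,
    probs: CellProbabilities,
    apply_exclusion: bool = True,
) -> float:
    """Exact log-likelihood of overlapping totals (z_true, z_mat) given z_crvs.

    Sums the multinomial pmf over every latent table consistent with the
    marginals (optionally pruned by the exclusion rule), in log space.
    With ``apply_exclusion=False`` this is the exact marginal likelihood of
    the pair (z_true, z_mat).
    """
    tables = table_array(z_crvs, z_mat, z_true)
    if apply_exclusion:
        tables = tables[_keep_mask(tables, z_crvs, z_true)]
        if tables.shape[0] == 0:
            warnings.warn(
                f"all latent tables excluded for (z_crvs={z_crvs}, "
                f"z_mat={z_mat}, z_true={z_true}); returning -inf",
                RuntimeWarning,
                stacklevel=2,
            )
            return float("-inf")
    logp = np.log(np.clip(probs.as_array(), 0.0, None))
    coef = gammaln(z_crvs + 1) - gammaln(tables + 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        terms = tables * logp
    terms = np.where(tables == 0, 0.0, terms)
    return float(logsumexp(coef + terms.sum(axis=1)))


def loglik_dispatch(obs, probs: CellProbabilities, apply_exclusion: bool = True) -> float:
    """Log-likelihood of one study observation under its reporting pattern."""
    from .data import ReportingPattern

    if obs.pattern is ReportingPattern.FULL_BREAKDOWN:
        counts = [obs.z_tpos, obs.z_fpos, obs.z_fneg, obs.z_tneg]
        return multinomial_logpmf(counts, probs.as_array(), total=obs.z_crvs)
    if obs.pattern is ReportingPattern.PARTIAL_FNEG:
        counts = [obs.z_fneg, obs.z_tneg, obs.z_mat]
        merged = [probs.g_fneg, probs.g_tneg, probs.g_mat]
        return multinomial_logpmf(counts, merged, total=obs.z_crvs)
    if obs.pattern is ReportingPattern.TRUE_TOTAL_ONLY:
        return loglik_true_total(
            obs.z_crvs, obs.z_mat, obs.z_true, probs, apply_exclusion=apply_exclusion
        )
    raise ValueError(f"unknown reporting pattern {obs.pattern!r}")
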