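"""Adaptive Metropolis-within-Gibbs sampler for the misclassification model.

The posterior factorizes as

    p(theta | data)  ∝  exp( log_prior(hyper, latents)
                             + sum_i loglik(study_i | sens, spec, gamma_i) )

with the study likelihood evaluated at each study's country and midyear.
The sampler exploits two structural facts:

* Given the latent country states, the eight hyperparameters touch only
  cheap bivariate-normal prior terms.
* Given the hyperparameters, countries are conditionally independent, so
  the country-mean and innovation updates are proposed and accepted for
  *all countries simultaneously* with vectorized likelihood evaluations.

Study likelihoods are evaluated in flat arrays grouped by reporting
pattern; for overlapping-total studies the latent-table enumeration is
precomputed once (the table set depends only on the data) and the
log-sum-exp over tables is done with segmented reductions.

Proposal scales adapt per component during burn-in (Robbins-Monro toward
standard acceptance targets) and are frozen afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ndtr, ndtri

from .data import Dataset, ReportingPattern
from .likelihood import exclusion_quantile, table_array
from .process import build_rw_basis

try:  # pragma: no cover - exercised implicitly everywhere when available
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _loglik_kernel(
    eta_mid,
    gamma,
    f_idx,
    F,
    F_coef,
    p_idx,
    P,
    P_coef,
    tt_idx,
    seg_starts,
    seg_len,
    Z,
    Z_coef,
    tt_dead,
    out,
):
    """Single-pass per-study log-likelihoods (compiled hot path).

    Mirrors :meth:`LikelihoodData._logliks_numpy`; cell probabilities are
    floored at 1e-300 so observed counts on zero-probability cells give a
    huge negative (finite) penalty instead of NaN products.
    """
    SQRT1_2 = 0.7071067811865476
    for j in range(f_idx.shape[0]):
        i = f_idx[j]
        se = 0.5 * math.erfc(-eta_mid[i, 0] * SQRT1_2)
        sp = 0.5 * math.erfc(-eta_mid[i, 1] * SQRT1_2)
        g = gamma[i]
        c0 = se * g
        c2 = g - c0
        c3 = sp * (1.0 - g)
        c1 = (1.0 - g) - c3
        out[i] = (
            F_coef[j]
            + F[j, 0] * math.log(max(c0, 1e-300))
            + F[j, 1] * math.log(max(c1, 1e-300))
            + F[j, 2] * math.log(max(c2, 1e-300))
            + F[j, 3] * math.log(max(c3, 1e-300))
        )
    for j in range(p_idx.shape[0]):
        i = p_idx[j]
        se = 0.5 * math.erfc(-eta_mid[i, 0] * SQRT1_2)
        sp = 0.5 * math.erfc(-eta_mid[i, 1] * SQRT1_2)
        g = gamma[i]
        gm = se * g + (1.0 - sp) * (1.0 - g)
        out[i] = (
            P_coef[j]
            + P[j, 0] * math.log(max((1.0 - se) * g, 1e-300))
            + P[j, 1] * math.log(max(sp * (1.0 - g), 1e-300))
            + P[j, 2] * math.log(max(gm, 1e-300))
        )
    for j in range(tt_idx.shape[0]):
        i = tt_idx[j]
        if tt_dead[j]:
            out[i] = -np.inf
            continue
        se = 0.5 * math.erfc(-eta_mid[i, 0] * SQRT1_2)
        sp = 0.5 * math.erfc(-eta_mid[i, 1] * SQRT1_2)
        g = gamma[i]
        c0 = se * g
        c2 = g - c0
        c3 = sp * (1.0 - g)
        c1 = (1.0 - g) - c3
        l0 = math.log(max(c0, 1e-300))
        l1 = math.log(max(c1, 1e-300))
        l2 = math.log(max(c2, 1e-300))
        l3 = math.log(max(c3, 1e-300))
        start = seg_starts[j]
        L = seg_len[j]
        # The per-table log-pmf is concave in the T+ index (sum of -lgamma
        # of linear arguments plus a linear term), hence unimodal: locate
        # the peak by bisection on the discrete slope, then accumulate
        # outward until terms underflow (exp(-37) is zero at double
        # precision relative to the peak).
        lo_k = 0
        hi_k = L - 1
        while hi_k - lo_k > 1:
            mid = (lo_k + hi_k) // 2
            r = start + mid
            s_mid = (
                Z_coef[r] + Z[r, 0] * l0 + Z[r, 1] * l1 + Z[r, 2] * l2 + Z[r, 3] * l3
            )
            r += 1
            s_next = (
                Z_coef[r] + Z[r, 0] * l0 + Z[r, 1] * l1 + Z[r, 2] * l2 + Z[r, 3] * l3
            )
            if s_next > s_mid:
                lo_k = mid + 1
            else:
                hi_k = mid
        km = lo_k
        r = start + lo_k
        m = Z_coef[r] + Z[r, 0] * l0 + Z[r, 1] * l1 + Z[r, 2] * l2 + Z[r, 3] * l3
        if hi_k != lo_k:
            r = start + hi_k
            s_hi = (
                Z_coef[r] + Z[r, 0] * l0 + Z[r, 1] * l1 + Z[r, 2] * l2 + Z[r, 3] * l3
            )
            if s_hi > m:
                m = s_hi
                km = hi_k
        tot = 0.0
        k = km
        while k >= 0:
            r = start + k
            d = (
                Z_coef[r] + Z[r, 0] * l0 + Z[r, 1] * l1 + Z[r, 2] * l2 + Z[r, 3] * l3
            ) - m
            if d <= -37.0:
                break
            tot += math.exp(d)
            k -= 1
        k = km + 1
        while k < L:
            r = start + k
            d = (
                Z_coef[r] + Z[r, 0] * l0 + Z[r, 1] * l1 + Z[r, 2] * l2 + Z[r, 3] * l3
            ) - m
            if d <= -37.0:
                break
            tot += math.exp(d)
            k += 1
        out[i] = math.log(tot) + m

GAMMA_LO = 1e-4  # lower support bound of the per-study true-proportion prior

_ADAPT_EVERY = 50
_TARGET_SCALAR = 0.44
_TARGET_BLOCK = 0.30


# ---------------------------------------------------------------------------
# Likelihood data: studies flattened into pattern groups
# ---------------------------------------------------------------------------


class LikelihoodData:
    """Dataset compiled to flat arrays for vectorized likelihood evaluation."""

    def __init__(self, dataset: Dataset, apply_exclusion: bool = True):
        self.dataset = dataset
        self.countries = dataset.countries
        self.C = len(self.countries)
        self.T = dataset.n_years
        cindex = {c: i for i, c in enumerate(self.countries)}
        studies = dataset.studies
        self.n_studies = len(studies)
        self.c_idx = np.array([cindex[s.country] for s in studies], dtype=np.intp)
        self.t_idx = np.array(
            [dataset.time_index(s.t_mid) for s in studies], dtype=np.intp
        )
        self.z_crvs = np.array([s.z_crvs for s in studies], dtype=float)

        full, part, tt = [], [], []
        for i, s in enumerate(studies):
            if s.pattern is ReportingPattern.FULL_BREAKDOWN:
                full.append(i)
            elif s.pattern is ReportingPattern.PARTIAL_FNEG:
                part.append(i)
            else:
                tt.append(i)
        self.full_idx = np.array(full, dtype=np.intp)
        self.part_idx = np.array(part, dtype=np.intp)
        self.tt_idx = np.array(tt, dtype=np.intp)

        F = np.array(
            [
                [studies[i].z_tpos, studies[i].z_fpos, studies[i].z_fneg, studies[i].z_tneg]
                for i in full
            ],
            dtype=float,
        ).reshape(len(full), 4)
        self.F = F
        self.F_coef = gammaln(F.sum(axis=1) + 1) - gammaln(F + 1).sum(axis=1)
        P = np.array(
            [[studies[i].z_fneg, studies[i].z_tneg, studies[i].z_mat] for i in part],
            dtype=float,
        ).reshape(len(part), 3)
        self.P = P
        self.P_coef = gammaln(P.sum(axis=1) + 1) - gammaln(P + 1).sum(axis=1)

        # Overlapping-total studies: flatten all admissible latent tables.
        blocks, seg_len = [], []
        self.tt_dead = np.zeros(len(tt), dtype=bool)  # all tables pruned
        for j, i in enumerate(tt):
            s = studies[i]
            tables = table_array(s.z_crvs, s.z_mat, s.z_true)
            if apply_exclusion:
                q = exclusion_quantile(s.z_crvs, s.z_true)
                kept = tables[tables[:, 3] > q]
                if kept.shape[0] == 0:
                    warnings.warn(
                        f"study {s.study_id}: every latent table pruned by the "
                        "exclusion rule; its likelihood is identically zero",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    self.tt_dead[j] = True
                    kept = tables[:1]  # placeholder segment, result overridden
                tables = kept
            blocks.append(tables.astype(float))
            seg_len.append(tables.shape[0])
        Z = (
            np.concatenate(blocks, axis=0) if blocks else np.zeros((0, 4))
        )
        self.Z = Z
        self.seg_len = np.asarray(seg_len, dtype=np.int64)
        self.seg_starts = np.concatenate(
            [[0], np.cumsum(self.seg_len)[:-1]]
        ).astype(np.int64)
        self.row_study = np.repeat(np.arange(len(tt)), self.seg_len)
        self.Z_coef = gammaln(Z.sum(axis=1) + 1) - gammaln(Z + 1).sum(axis=1)
        self.max_tables = int(self.seg_len.max()) if tt else 0

    # -- evaluation ---------------------------------------------------------

    @staticmethod
    def _cell_logprobs(se, sp, g):
        """(m, 4) log cell probabilities in order (T+, F+, F-, T-).

        Probabilities are floored at 1e-300 so that a boundary cell yields
        a log-probability around -690 rather than -inf; a proposal that
        puts mass zero on an observed cell is then effectively (not
        literally) impossible, which keeps 0 * log(0) products out of the
        vectorized sums.
        """
        cells = np.empty((len(g), 4))
        cells[:, 0] = se * g
        cells[:, 2] = g - cells[:, 0]
        cells[:, 3] = sp * (1.0 - g)
        cells[:, 1] = (1.0 - g) - cells[:, 3]
        return np.log(np.clip(cells, 1e-300, None))

    def logliks(self, eta_mid: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        """Per-study log-likelihoods.

        ``eta_mid`` is (n_studies, 2): probit sensitivity and specificity at
        each study's country-midyear; ``gamma`` is (n_studies,).
        """
        if _HAVE_NUMBA:
            out = np.empty(self.n_studies)
            _loglik_kernel(
                np.ascontiguousarray(eta_mid),
                np.ascontiguousarray(gamma),
                self.full_idx,
                self.F,
                self.F_coef,
                self.part_idx,
                self.P,
                self.P_coef,
                self.tt_idx,
                self.seg_starts,
                self.seg_len,
                self.Z,
                self.Z_coef,
                self.tt_dead,
                out,
            )
            return out
        return self._logliks_numpy(eta_mid, gamma)

    def _logliks_numpy(self, eta_mid: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        out = np.empty(self.n_studies)
        se = ndtr(eta_mid[:, 0])
        sp = ndtr(eta_mid[:, 1])
        if len(self.full_idx):
            idx = self.full_idx
            logg = self._cell_logprobs(se[idx], sp[idx], gamma[idx])
            out[idx] = self.F_coef + np.einsum("ij,ij->i", self.F, logg)
        if len(self.part_idx):
            idx = self.part_idx
            g = gamma[idx]
            gm = se[idx] * g + (1.0 - sp[idx]) * (1.0 - g)
            logm = np.log(
                np.clip(
                    np.stack(
                        [(1.0 - se[idx]) * g, sp[idx] * (1.0 - g), gm], axis=1
                    ),
                    1e-300,
                    None,
                )
            )
            out[idx] = self.P_coef + np.einsum("ij,ij->i", self.P, logm)
        if len(self.tt_idx):
            idx = self.tt_idx
            logg = self._cell_logprobs(se[idx], sp[idx], gamma[idx])
            rows = logg[self.row_study]
            s = self.Z_coef + np.einsum("ij,ij->i", self.Z, rows)
            m = np.maximum.reduceat(s, self.seg_starts)
            e = np.exp(s - m[self.row_study])
            ll = np.log(np.add.reduceat(e, self.seg_starts)) + m
            ll[self.tt_dead] = -np.inf
            out[idx] = ll
        return out


# ---------------------------------------------------------------------------
# Prior helper terms
# ---------------------------------------------------------------------------


def _bvn_sum(x, mu1, mu2, s1, s2, r):
    """Sum of bivariate-normal log-densities over rows of x (shape (m, 2))."""
    a = (x[:, 0] - mu1) / s1
    b = (x[:, 1] - mu2) / s2
    om = 1.0 - r * r
    quad = (a * a - 2.0 * r * a * b + b * b) / om
    m = x.shape[0]
    return -m * np.log(2.0 * np.pi * s1 * s2 * np.sqrt(om)) - 0.5 * quad.sum()


def _bvn_rows(x, mu1, mu2, s1, s2, r):
    a = (x[..., 0] - mu1) / s1
    b = (x[..., 1] - mu2) / s2
    om = 1.0 - r * r
    quad = (a * a - 2.0 * r * a * b + b * b) / om
    return -np.log(2.0 * np.pi * s1 * s2 * np.sqrt(om)) - 0.5 * quad


def _innov_sum(Sxx, Syy, Sxy, m, d1, d2, phi):
    om = 1.0 - phi * phi
    quad = (Sxx / d1**2 - 2.0 * phi * Sxy / (d1 * d2) + Syy / d2**2) / om
    return -m * np.log(2.0 * np.pi * d1 * d2 * np.sqrt(om)) - 0.5 * quad


# ---------------------------------------------------------------------------
# Chain state and single-chain driver
# ---------------------------------------------------------------------------


@dataclass
class _Steps:
    gamma: np.ndarray  # log step, (n_studies,)
    eta: np.ndarray  # log step, (C,)
    xi: np.ndarray  # log step, (C, T-1)
    hyper: np.ndarray  # log step, (8,)
    shift: np.ndarray  # log step, (2,) joint global-level/mean translation
    sscale: np.ndarray  # log step, (2,) joint sigma/mean-spread scaling
    dscale: np.ndarray  # log step, (2,) joint delta/innovation scaling


def _init_state(lik: LikelihoodData, rng: np.random.Generator):
    ds = lik.dataset
    C, T, n = lik.C, lik.T, lik.n_studies
    studies = ds.studies

    gamma = np.empty(n)
    for i, s in enumerate(studies):
        base = s.z_true if s.z_true is not None else max(s.z_mat, 1)
        gamma[i] = np.clip(base / s.z_crvs, 5 * GAMMA_LO, 0.5)
    gamma *= np.exp(rng.normal(0.0, 0.2, size=n))
    gamma = np.clip(gamma, 2 * GAMMA_LO, 0.9)

    # crude per-country sensitivity from the ratio of coded to confirmed totals
    se0 = np.full(C, 0.6)
    num = np.zeros(C)
    den = np.zeros(C)
    for i, s in enumerate(studies):
        if s.z_true is not None and s.z_true > 0:
            c = lik.c_idx[i]
            num[c] += min(s.z_mat, s.z_true)
            den[c] += s.z_true
    has = den > 0
    se0[has] = np.clip(num[has] / den[has], 0.1, 0.9)

    eta_mean = np.empty((C, 2))
    eta_mean[:, 0] = ndtri(se0) + rng.normal(0.0, 0.2, size=C)
    eta_mean[:, 1] = ndtri(0.995) + rng.normal(0.0, 0.2, size=C)
    xi = rng.normal(0.0, 0.02, size=(C, T - 1, 2))

    hyper = {
        "lam": np.array(
            [
                float(ndtr(ndtri(0.6) + rng.normal(0, 0.2))),
                float(ndtr(ndtri(0.995) + rng.normal(0, 0.2))),
            ]
        ),
        "rho": float(rng.uniform(-0.3, 0.3)),
        "sig": np.array([0.6, 0.3]) * np.exp(rng.normal(0, 0.2, 2)),
        "phi": float(rng.uniform(-0.3, 0.3)),
        "delta": np.array([0.12, 0.13]) * np.exp(rng.normal(0, 0.2, 2)),
    }
    return hyper, eta_mean, xi, gamma


def _run_chain(lik: LikelihoodData, config, rng: np.random.Generator):
    C, T, n = lik.C, lik.T, lik.n_studies
    D = build_rw_basis(T).D  # (T, T-1)
    hyper, eta_mean, xi, gamma = _init_state(lik, rng)
    loggamma = np.log(gamma) - np.log1p(-gamma)  # logit parameterization

    # cached probit (sens, spec) at each study's country-midyear
    def midyear_eta():
        series = eta_mean[:, None, :] + np.einsum("tk,ckj->ctj", D, xi)
        return series[lik.c_idx, lik.t_idx, :], series

    eta_mid, _ = midyear_eta()
    ll = lik.logliks(eta_mid, gamma)
    D_mid = D[lik.t_idx, :]  # (n_studies, T-1)

    steps = _Steps(
        gamma=np.full(n, np.log(0.4)),
        eta=np.full(C, np.log(0.2)),
        xi=np.full((C, T - 1), np.log(0.15)),
        hyper=np.full(8, np.log(0.15)),
        shift=np.full(2, np.log(0.1)),
        sscale=np.full(2, np.log(0.3)),
        dscale=np.full(2, np.log(0.3)),
    )
    acc = {
        "gamma": np.zeros(n),
        "eta": np.zeros(C),
        "xi": np.zeros((C, T - 1)),
        "hyper": np.zeros(8),
        "shift": np.zeros(2),
        "sscale": np.zeros(2),
        "dscale": np.zeros(2),
    }
    # fixed per-dimension proposal ratio: specificity moves on a tighter scale
    eta_dim = np.array([1.0, 0.6])

    n_keep = (config.n_iter - config.n_burnin) // config.thin
    out_hyper = np.empty((n_keep, 8))
    out_eta_mean = np.empty((n_keep, C, 2))
    out_series = np.empty((n_keep, C, T, 2))
    out_gamma = np.empty((n_keep, n))
    keep = 0

    for it in range(config.n_iter):
        # --- per-study true proportions (logit-scale random walk) ----------
        step = np.exp(steps.gamma)
        prop = loggamma + step * rng.standard_normal(n)
        g_prop = 1.0 / (1.0 + np.exp(-prop))
        valid = g_prop > GAMMA_LO
        ll_prop = lik.logliks(eta_mid, np.where(valid, g_prop, gamma))
        # uniform prior on gamma => logit-scale Jacobian log g(1-g)
        jac = np.log(g_prop) + np.log1p(-g_prop) - np.log(gamma) - np.log1p(-gamma)
        logr = np.where(valid, ll_prop - ll + jac, -np.inf)
        accept = np.log(rng.random(n)) < logr
        loggamma = np.where(accept, prop, loggamma)
        gamma = np.where(accept, g_prop, gamma)
        ll = np.where(accept, ll_prop, ll)
        acc["gamma"] += accept

        mu1, mu2 = ndtri(hyper["lam"][0]), ndtri(hyper["lam"][1])
        s1, s2, r = hyper["sig"][0], hyper["sig"][1], hyper["rho"]
        d1, d2, ph = hyper["delta"][0], hyper["delta"][1], hyper["phi"]

        # --- country mean levels (joint 2-d proposal per country) ----------
        delta = np.exp(steps.eta)[:, None] * eta_dim * rng.standard_normal((C, 2))
        em_prop = eta_mean + delta
        pr_old = _bvn_rows(eta_mean, mu1, mu2, s1, s2, r)
        pr_new = _bvn_rows(em_prop, mu1, mu2, s1, s2, r)
        mid_prop = eta_mid + delta[lik.c_idx]
        ll_prop = lik.logliks(mid_prop, gamma)
        dll = np.bincount(lik.c_idx, weights=ll_prop - ll, minlength=C)
        accept = np.log(rng.random(C)) < (pr_new - pr_old + dll)
        eta_mean = np.where(accept[:, None], em_prop, eta_mean)
        amask = accept[lik.c_idx]
        eta_mid = np.where(amask[:, None], mid_prop, eta_mid)
        ll = np.where(amask, ll_prop, ll)
        acc["eta"] += accept

        # --- innovations, one time slot at a time across all countries -----
        for k in range(T - 1):
            dxi = np.exp(steps.xi[:, k])[:, None] * eta_dim * rng.standard_normal((C, 2))
            xk = xi[:, k, :]
            xk_prop = xk + dxi
            pr_old = _bvn_rows(xk, 0.0, 0.0, d1, d2, ph)
            pr_new = _bvn_rows(xk_prop, 0.0, 0.0, d1, d2, ph)
            mid_prop = eta_mid + D_mid[:, k, None] * dxi[lik.c_idx]
            ll_prop = lik.logliks(mid_prop, gamma)
            dll = np.bincount(lik.c_idx, weights=ll_prop - ll, minlength=C)
            accept = np.log(rng.random(C)) < (pr_new - pr_old + dll)
            xi[:, k, :] = np.where(accept[:, None], xk_prop, xk)
            amask = accept[lik.c_idx]
            eta_mid = np.where(amask[:, None], mid_prop, eta_mid)
            ll = np.where(amask, ll_prop, ll)
            acc["xi"][:, k] += accept

        # --- hyperparameters (scalar Metropolis; prior terms only) ---------
        hstep = np.exp(steps.hyper)
        Sxx = float((xi[:, :, 0] ** 2).sum())
        Syy = float((xi[:, :, 1] ** 2).sum())
        Sxy = float((xi[:, :, 0] * xi[:, :, 1]).sum())
        m_xi = C * (T - 1)

        def level_lp(l1, l2, a1, a2, rr):
            return _bvn_sum(eta_mean, ndtri(l1), ndtri(l2), a1, a2, rr)

        # global levels: random walk on the probit scale with uniform(0,1)
        # prior on the probability => normal-density Jacobian
        for j in range(2):
            x = ndtri(hyper["lam"][j])
            x_new = x + hstep[j] * rng.standard_normal()
            lam_new = float(ndtr(x_new))
            if 0.0 < lam_new < 1.0:
                lams = hyper["lam"].copy()
                lams[j] = lam_new
                logr = (
                    level_lp(lams[0], lams[1], s1, s2, r)
                    - level_lp(hyper["lam"][0], hyper["lam"][1], s1, s2, r)
                    - 0.5 * (x_new**2 - x**2)
                )
                if np.log(rng.random()) < logr:
                    hyper["lam"] = lams
                    acc["hyper"][j] += 1

        # between-country correlation
        r_new = hyper["rho"] + hstep[2] * rng.standard_normal()
        if -1.0 < r_new < 1.0:
            logr = level_lp(*hyper["lam"], s1, s2, r_new) - level_lp(
                *hyper["lam"], s1, s2, hyper["rho"]
            )
            if np.log(rng.random()) < logr:
                hyper["rho"] = float(r_new)
                acc["hyper"][2] += 1
        r = hyper["rho"]

        # between-country SDs: log-scale walk, half-normal(1) prior
        for j in range(2):
            s_old = hyper["sig"][j]
            s_new = s_old * np.exp(hstep[3 + j] * rng.standard_normal())
            sigs = hyper["sig"].copy()
            sigs[j] = s_new
            logr = (
                level_lp(*hyper["lam"], sigs[0], sigs[1], r)
                - level_lp(*hyper["lam"], s1, s2, r)
                - 0.5 * (s_new**2 - s_old**2)
                + np.log(s_new / s_old)
            )
            if np.log(rng.random()) < logr:
                hyper["sig"] = sigs
                acc["hyper"][3 + j] += 1
            s1, s2 = hyper["sig"]

        # innovation correlation
        p_new = hyper["phi"] + hstep[5] * rng.standard_normal()
        if -1.0 < p_new < 1.0:
            logr = _innov_sum(Sxx, Syy, Sxy, m_xi, d1, d2, p_new) - _innov_sum(
                Sxx, Syy, Sxy, m_xi, d1, d2, hyper["phi"]
            )
            if np.log(rng.random()) < logr:
                hyper["phi"] = float(p_new)
                acc["hyper"][5] += 1
        ph = hyper["phi"]

        # innovation SDs
        for j in range(2):
            d_old = hyper["delta"][j]
            d_new = d_old * np.exp(hstep[6 + j] * rng.standard_normal())
            ds_ = hyper["delta"].copy()
            ds_[j] = d_new
            logr = (
                _innov_sum(Sxx, Syy, Sxy, m_xi, ds_[0], ds_[1], ph)
                - _innov_sum(Sxx, Syy, Sxy, m_xi, d1, d2, ph)
                - 0.5 * (d_new**2 - d_old**2)
                + np.log(d_new / d_old)
            )
            if np.log(rng.random()) < logr:
                hyper["delta"] = ds_
                acc["hyper"][6 + j] += 1
            d1, d2 = hyper["delta"]

        # --- interweaved joint moves (break hierarchical funnels) -----------
        # (a) translate a global level together with every country mean;
        # between-country prior terms are invariant, only the likelihood and
        # the uniform-prior Jacobian on the global probability change.
        for j in range(2):
            dshift = np.exp(steps.shift[j]) * rng.standard_normal()
            x = ndtri(hyper["lam"][j])
            x_new = x + dshift
            lam_new = float(ndtr(x_new))
            if not (0.0 < lam_new < 1.0):
                continue
            mid_prop = eta_mid.copy()
            mid_prop[:, j] += dshift
            ll_prop = lik.logliks(mid_prop, gamma)
            logr = (ll_prop - ll).sum() - 0.5 * (x_new**2 - x**2)
            if np.log(rng.random()) < logr:
                hyper["lam"][j] = lam_new
                eta_mean[:, j] += dshift
                eta_mid = mid_prop
                ll = ll_prop
                acc["shift"][j] += 1

        # (b) scale a between-country SD together with the spread of the
        # country means around the global level.  Standardized prior
        # quadratics are invariant; what remains is the likelihood change,
        # the half-normal prior and a net +log(a) from normalization vs the
        # transformation Jacobian.
        for j in range(2):
            a = float(np.exp(np.exp(steps.sscale[j]) * rng.standard_normal()))
            mu_j = ndtri(hyper["lam"][j])
            s_old = hyper["sig"][j]
            s_new = s_old * a
            mid_prop = eta_mid.copy()
            mid_prop[:, j] += (a - 1.0) * (eta_mean[lik.c_idx, j] - mu_j)
            ll_prop = lik.logliks(mid_prop, gamma)
            logr = (
                (ll_prop - ll).sum()
                + np.log(a)
                - 0.5 * (s_new**2 - s_old**2)
            )
            if np.log(rng.random()) < logr:
                hyper["sig"][j] = s_new
                eta_mean[:, j] = mu_j + a * (eta_mean[:, j] - mu_j)
                eta_mid = mid_prop
                ll = ll_prop
                acc["sscale"][j] += 1

        # (c) scale an innovation SD together with all innovations.
        for j in range(2):
            a = float(np.exp(np.exp(steps.dscale[j]) * rng.standard_normal()))
            d_old = hyper["delta"][j]
            d_new = d_old * a
            mid_prop = eta_mid.copy()
            mid_prop[:, j] += (a - 1.0) * (eta_mid[:, j] - eta_mean[lik.c_idx, j])
            ll_prop = lik.logliks(mid_prop, gamma)
            logr = (
                (ll_prop - ll).sum()
                + np.log(a)
                - 0.5 * (d_new**2 - d_old**2)
            )
            if np.log(rng.random()) < logr:
                hyper["delta"][j] = d_new
                xi[:, :, j] *= a
                eta_mid = mid_prop
                ll = ll_prop
                acc["dscale"][j] += 1

        # --- adaptation during burn-in --------------------------------------
        if it < config.n_burnin and (it + 1) % _ADAPT_EVERY == 0:
            b = (it + 1) // _ADAPT_EVERY
            gain = min(0.5, 1.0 / np.sqrt(b))
            steps.gamma += gain * (acc["gamma"] / _ADAPT_EVERY - _TARGET_SCALAR)
            steps.eta += gain * (acc["eta"] / _ADAPT_EVERY - _TARGET_BLOCK)
            steps.xi += gain * (acc["xi"] / _ADAPT_EVERY - _TARGET_BLOCK)
            steps.hyper += gain * (acc["hyper"] / _ADAPT_EVERY - _TARGET_SCALAR)
            steps.shift += gain * (acc["shift"] / _ADAPT_EVERY - _TARGET_SCALAR)
            steps.sscale += gain * (acc["sscale"] / _ADAPT_EVERY - _TARGET_SCALAR)
            steps.dscale += gain * (acc["dscale"] / _ADAPT_EVERY - _TARGET_SCALAR)
            for a in acc.values():
                a[...] = 0.0

        # --- retention ------------------------------------------------------
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            out_hyper[keep] = [
                hyper["lam"][0],
                hyper["lam"][1],
                hyper["rho"],
                hyper["sig"][0],
                hyper["sig"][1],
                hyper["phi"],
                hyper["delta"][0],
                hyper["delta"][1],
            ]
            out_eta_mean[keep] = eta_mean
            out_series[keep] = eta_mean[:, None, :] + np.einsum("tk,ckj->ctj", D, xi)
            out_gamma[keep] = gamma
            keep += 1

    return {
        "hyper": out_hyper,
        "eta_mean": out_eta_mean,
        "eta_series": out_series,
        "gamma": out_gamma,
    }


def run_mcmc(lik: LikelihoodData, config, seed: int | None = None):
    """Run ``config.n_chains`` independent chains; stack results per field."""
    seed = config.seed if seed is None else seed
    seqs = np.random.SeedSequence(seed).spawn(config.n_chains)
    chains = [_run_chain(lik, config, np.random.default_rng(s)) for s in seqs]
    return {k: np.stack([c[k] for c in chains]) for k in chains[0]}
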