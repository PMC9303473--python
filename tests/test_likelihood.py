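import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, multinomial

from bmis.data import StudyObservation
from bmis.likelihood import (
    CellProbabilities,
    LatentTable,
    MisclassParams,
    cell_probs,
    enumerate_tables,
    exclusion_indicator,
    exclusion_quantile,
    loglik_dispatch,
    loglik_true_total,
    multinomial_logpmf,
    reported_pm_prob,
)


def compositions(n):
    """All ordered 4-part compositions of n (brute-force table space)."""
    out = []
    for a in range(n + 1):
        for b in range(n + 1 - a):
            for c in range(n + 1 - a - b):
                out.append((a, b, c, n - a - b - c))
    return np.array(out)


def brute_force_pair_loglik(z_crvs, z_mat, z_true, p):
    """Oracle: sum multinomial pmf over all tables with the two marginals."""
    tables = compositions(z_crvs)
    mat = tables[:, 0] + tables[:, 1]
    true = tables[:, 0] + tables[:, 2]
    keep = (mat == z_mat) & (true == z_true)
    total = multinomial.pmf(tables[keep], n=z_crvs, p=p).sum()
    return math.log(total)


def random_probs(rng):
    se, sp = rng.uniform(0.2, 0.95), rng.uniform(0.8, 0.999)
    g = rng.uniform(0.02, 0.4)
    return cell_probs(MisclassParams(sens=se, spec=sp, gamma_true=g))


# ---------------------------------------------------------------------------
# cell probabilities
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "params, expected",
    [
        ((1 - 1e-12, 1 - 1e-12, 0.2), (0.2, 0.0, 0.0, 0.8)),
        ((0.5, 1 - 1e-12, 0.1), (0.05, 0.0, 0.05, 0.9)),
    ],
)
def test_cell_probs_examples(params, expected):
    got = cell_probs(MisclassParams(*params)).as_array()
    assert np.allclose(got, expected, atol=1e-9)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    se=st.floats(0.01, 0.99),
    sp=st.floats(0.01, 0.99),
    g=st.floats(0.001, 0.999),
)
def test_cell_probs_sum_to_one_and_recover_marginals(se, sp, g):
    probs = cell_probs(MisclassParams(se, sp, g))
    assert abs(probs.as_array().sum() - 1.0) < 1e-12
    assert math.isclose(probs.g_true, g, rel_tol=1e-9)
    assert math.isclose(
        reported_pm_prob(MisclassParams(se, sp, g)), probs.g_mat, rel_tol=1e-9
    )


def test_reported_pm_matches_cell_aggregation():
    params = MisclassParams(0.593, 0.9995, 0.01)
    probs = cell_probs(params)
    assert math.isclose(reported_pm_prob(params), probs.g_tpos + probs.g_fpos)
    assert math.isclose(reported_pm_prob(MisclassParams(0.5, 1 - 1e-15, 0.1)), 0.05)


# ---------------------------------------------------------------------------
# multinomial pmf
# ---------------------------------------------------------------------------


def test_multinomial_logpmf_closed_cases():
    assert math.isclose(
        multinomial_logpmf([1, 1, 1, 1], [0.25] * 4, total=4), math.log(24 / 256)
    )
    assert multinomial_logpmf([4, 0, 0, 0], [1.0, 0.0, 0.0, 0.0]) == 0.0
    with pytest.raises(ValueError):
        multinomial_logpmf([1, 2], [0.5, 0.25, 0.25])
    with pytest.raises(ValueError):
        multinomial_logpmf([-1, 2], [0.5, 0.5])


def test_multinomial_logpmf_matches_explicit_factorials(rng):
    for _ in range(20):
        counts = rng.integers(0, 6, size=4)
        p = rng.dirichlet(np.ones(4))
        n = counts.sum()
        expected = (
            math.factorial(n)
            / np.prod([math.factorial(int(c)) for c in counts])
            * np.prod(p**counts)
        )
        assert math.isclose(
            multinomial_logpmf(counts, p), math.log(expected), rel_tol=1e-10
        )


# ---------------------------------------------------------------------------
# latent-table enumeration
# ---------------------------------------------------------------------------


def test_enumerate_tables_against_brute_force():
    tables = enumerate_tables(10, 3, 4)
    assert len(tables) == 4
    assert sorted(t.tpos for t in tables) == [0, 1, 2, 3]
    raw = compositions(10)
    keep = (raw[:, 0] + raw[:, 1] == 3) & (raw[:, 0] + raw[:, 2] == 4)
    expected = {tuple(r) for r in raw[keep]}
    assert {(t.tpos, t.fpos, t.fneg, t.tneg) for t in tables} == expected


def test_enumerate_tables_edge_cases():
    (only,) = enumerate_tables(100, 0, 5)
    assert (only.tpos, only.fpos, only.fneg, only.tneg) == (0, 0, 5, 95)
    assert sorted(t.tpos for t in enumerate_tables(5, 3, 4)) == [2, 3]
    with pytest.raises(ValueError, match="infeasible"):
        enumerate_tables(10, 12, 3)  # coded-maternal marginal exceeds envelope


def test_table_counts_always_consistent():
    for t in enumerate_tables(17, 6, 9):
        assert t.total == 17
        assert t.tpos + t.fpos == 6
        assert t.tpos + t.fneg == 9


# ---------------------------------------------------------------------------
# exclusion rule
# ---------------------------------------------------------------------------


def test_exclusion_degenerate_envelope():
    # z_crvs == z_true: the binomial has no trials, the threshold is zero
    assert exclusion_quantile(5, 5) == 0.0
    assert exclusion_indicator(LatentTable(3, 0, 2, 2), 7, 5) == 1  # tneg above q
    assert exclusion_indicator(LatentTable(5, 0, 0, 0), 5, 5) == 0  # strict >


def test_exclusion_thresholds_at_large_n():
    q = exclusion_quantile(1000 + 12, 12)  # n = 1000
    assert q == binom.ppf(0.025, 1000, 0.97)
    keep = LatentTable(10, 12, 2, 990)
    drop = LatentTable(10, 502, 2, 500)
    assert exclusion_indicator(keep, 1014, 12) == 1
    assert exclusion_indicator(drop, 1024, 12) == 0


def test_exclusion_never_increases_likelihood(rng):
    for _ in range(20):
        z = int(rng.integers(10, 60))
        z_true = int(rng.integers(1, z // 2))
        z_mat = int(rng.integers(1, z // 2))
        probs = random_probs(rng)
        on = loglik_true_total(z, z_mat, z_true, probs, apply_exclusion=True)
        off = loglik_true_total(z, z_mat, z_true, probs, apply_exclusion=False)
        assert on <= off + 1e-12


def test_all_tables_excluded_warns_and_returns_neg_inf():
    # z_crvs == z_true forces tneg == 0, which the strict rule rejects
    probs = CellProbabilities(0.25, 0.25, 0.25, 0.25)
    with pytest.warns(RuntimeWarning, match="excluded"):
        out = loglik_true_total(4, 2, 4, probs, apply_exclusion=True)
    assert out == -np.inf


# ---------------------------------------------------------------------------
# exact likelihood for overlapping totals
# ---------------------------------------------------------------------------


def test_true_total_matches_brute_force(rng):
    for _ in range(10):
        z = int(rng.integers(4, 16))
        probs = random_probs(rng)
        p = probs.as_array()
        z_mat = int(rng.integers(0, z + 1))
        lo = max(0, z_mat - z)
        for z_true in range(lo, z + 1):
            if max(0, z_mat + z_true - z) > min(z_mat, z_true):
                continue
            got = loglik_true_total(z, z_mat, z_true, probs, apply_exclusion=False)
            assert got == pytest.approx(
                brute_force_pair_loglik(z, z_mat, z_true, p), abs=1e-10
            )


def test_true_total_single_table_reduces_to_multinomial():
    # z_mat covers the envelope minus the non-maternal remainder, so the
    # feasible T+ range collapses to a point: the unique table (3, 2, 0, 0)
    probs = random_probs(np.random.default_rng(0))
    (only,) = enumerate_tables(5, 5, 3)
    got = loglik_true_total(5, 5, 3, probs, apply_exclusion=False)
    assert got == pytest.approx(
        multinomial_logpmf(only.as_array(), probs.as_array()), abs=1e-12
    )


def test_true_total_normalizes_over_all_pairs(rng):
    z = 12
    probs = random_probs(rng)
    total = 0.0
    for z_mat in range(z + 1):
        for z_true in range(z + 1):
            if max(0, z_mat + z_true - z) > min(z_mat, z_true):
                continue
            total += math.exp(
                loglik_true_total(z, z_mat, z_true, probs, apply_exclusion=False)
            )
    assert total == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# dispatch across reporting patterns
# ---------------------------------------------------------------------------


def _obs(**kw):
    return StudyObservation(study_id="s", country="A", t1=2000, t2=2000, **kw)


def test_dispatch_full_breakdown_is_plain_multinomial():
    obs = _obs(z_crvs=100, z_tpos=8, z_fpos=2, z_fneg=4, z_tneg=86)
    probs = random_probs(np.random.default_rng(1))
    assert loglik_dispatch(obs, probs) == pytest.approx(
        multinomial_logpmf([8, 2, 4, 86], probs.as_array()), abs=1e-12
    )


def test_partial_equals_marginalized_full(rng):
    """Merging T+ and F+ in the multinomial equals summing the full pmf."""
    for _ in range(30):
        z = int(rng.integers(5, 25))
        table = rng.multinomial(z, rng.dirichlet(np.ones(4)))
        tpos, fpos, fneg, tneg = (int(v) for v in table)
        probs = random_probs(rng)
        partial = _obs(z_crvs=z, z_fneg=fneg, z_tneg=tneg, z_mat=tpos + fpos)
        got = loglik_dispatch(partial, probs)
        brute = sum(
            math.exp(
                multinomial_logpmf(
                    [k, tpos + fpos - k, fneg, tneg], probs.as_array()
                )
            )
            for k in range(tpos + fpos + 1)
        )
        assert got == pytest.approx(math.log(brute), abs=1e-10)


def test_dispatch_true_total_single_table_equals_full():
    probs = random_probs(np.random.default_rng(2))
    tt = _obs(z_crvs=100, z_mat=0, z_true=5)
    full = _obs(z_crvs=100, z_tpos=0, z_fpos=0, z_fneg=5, z_tneg=95)
    assert loglik_dispatch(tt, probs, apply_exclusion=False) == pytest.approx(
        loglik_dispatch(full, probs), abs=1e-12
    )


def test_vectorized_engine_matches_reference_likelihood(tiny_world, rng):
    """The sampler's flattened evaluation agrees with the per-study reference."""
    from bmis._mcmc import LikelihoodData
    from bmis.process import prob_to_probit

    ds = tiny_world.dataset
    lik = LikelihoodData(ds, apply_exclusion=True)
    n = lik.n_studies
    se = rng.uniform(0.3, 0.9, n)
    sp = rng.uniform(0.9, 0.999, n)
    g = rng.uniform(0.005, 0.1, n)
    eta = np.column_stack([prob_to_probit(se), prob_to_probit(sp)])
    got = lik.logliks(eta, g)
    for i, s in enumerate(ds.studies):
        probs = cell_probs(MisclassParams(se[i], sp[i], g[i]))
        want = loglik_dispatch(s, probs, apply_exclusion=True)
        assert got[i] == pytest.approx(want, rel=1e-9, abs=1e-9)
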