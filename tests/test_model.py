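import numpy as np
import pytest

from bmis.data import CRVSSeries, Dataset, StudyObservation
from bmis.model import BMisModel, BMisResults, FitConfig, split_rhat
from bmis.process import HYPERPARAMETER_NAMES


def _single_country_dataset(z_crvs=1_000_000, scale=1.0):
    cells = dict(
        z_tpos=int(6000 * scale),
        z_fpos=int(400 * scale),
        z_fneg=int(4000 * scale),
        z_tneg=int(z_crvs * scale) - int(6000 * scale) - int(400 * scale) - int(4000 * scale),
    )
    crvs = tuple(CRVSSeries("A", y, 100, 10_000) for y in range(2000, 2010))
    obs = StudyObservation(
        study_id="s1", country="A", t1=2004, t2=2004, z_crvs=int(z_crvs * scale), **cells
    )
    return Dataset(crvs=crvs, studies=(obs,), year_span=(2000, 2009))


FAST = FitConfig(n_chains=2, n_iter=1200, n_burnin=400, thin=2, seed=11)


def test_fit_config_contracts():
    with pytest.raises(ValueError):
        FitConfig(n_burnin=500, n_iter=400)
    with pytest.raises(ValueError):
        FitConfig(thin=0)
    with pytest.raises(ValueError):
        FitConfig(n_iter=1001, n_burnin=500, thin=2)
    assert FitConfig().n_retained == 15_000
    assert FitConfig.desk().n_retained == 2000


def test_split_rhat_degenerate_and_calibrated(rng):
    const = np.ones((4, 100))
    assert split_rhat(const) == 1.0
    x = rng.standard_normal((4, 2000))
    assert 0.99 <= split_rhat(x) <= 1.02


def test_fit_is_reproducible(tiny_world):
    m = BMisModel(tiny_world.dataset)
    cfg = FitConfig(n_chains=2, n_iter=300, n_burnin=100, thin=2, seed=5)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = m.fit(cfg)
        b = m.fit(cfg)
    assert np.array_equal(a.samples.hyper, b.samples.hyper)
    assert np.array_equal(a.samples.eta_series, b.samples.eta_series)
    assert a.samples.hyper.shape == (2, 100, 8)
    assert np.all((a.samples.gamma_true > 0) & (a.samples.gamma_true < 1))


def test_posterior_concentrates_on_empirical_rates():
    """A huge full-breakdown study pins sens/spec at its observed ratios."""
    ds = _single_country_dataset()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = BMisModel(ds).fit(FAST)
    se = res.sens("A", 2004)
    sp = res.spec("A", 2004)
    assert np.median(se) == pytest.approx(0.6, abs=0.02)
    assert np.median(sp) == pytest.approx(989600 / 990000, abs=5e-4)
    assert np.median(res.samples.gamma_true) == pytest.approx(0.01, abs=0.002)


def test_posterior_contracts_with_more_data():
    """A 100x larger study shrinks the posterior spread at its midyear."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        small = BMisModel(_single_country_dataset(scale=0.01)).fit(FAST)
        big = BMisModel(_single_country_dataset(scale=1.0)).fit(FAST)
    for accessor in ("sens", "spec"):
        lo_s, hi_s = np.quantile(getattr(small, accessor)("A", 2004), (0.25, 0.75))
        lo_b, hi_b = np.quantile(getattr(big, accessor)("A", 2004), (0.25, 0.75))
        assert (hi_b - lo_b) < (hi_s - lo_s)


def test_no_data_country_tracks_hierarchy(tiny_world):
    """A country without studies reverts to the hierarchy's prior predictive."""
    ds = tiny_world.dataset
    extra = ds.crvs + tuple(
        CRVSSeries("NEW", y, 1, 100) for y in range(*ds.year_span)
    ) + (CRVSSeries("NEW", ds.year_span[1], 1, 100),)
    ds2 = Dataset(crvs=extra, studies=ds.studies, year_span=ds.year_span)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = BMisModel(ds2).fit(FitConfig(n_chains=2, n_iter=1000, n_burnin=400, thin=2, seed=3))
    s = res.samples
    c_new = s.countries.index("NEW")
    got = s._flat(s.eta_mean)[:, c_new, :]
    # prior predictive of a country mean given each posterior hyper draw
    rng = np.random.default_rng(0)
    hyper = s._flat(s.hyper)
    from scipy.special import ndtri

    mu = ndtri(hyper[:, :2])
    z = rng.multivariate_normal(np.zeros(2), np.eye(2), size=len(hyper))
    sd_s, sd_p, rho = hyper[:, 3], hyper[:, 4], hyper[:, 2]
    pred_s = mu[:, 0] + sd_s * z[:, 0]
    pred_p = mu[:, 1] + sd_p * (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1])
    # the two distributions should agree in location and spread
    assert np.median(got[:, 0]) == pytest.approx(np.median(pred_s), abs=0.5)
    assert np.median(got[:, 1]) == pytest.approx(np.median(pred_p), abs=0.5)
    assert got[:, 0].std() == pytest.approx(pred_s.std(), rel=0.5)


def test_summary_and_diagnostics_structure(tiny_world):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = BMisModel(tiny_world.dataset).fit(
            FitConfig(n_chains=2, n_iter=300, n_burnin=100, thin=2, seed=1)
        )
    summary = res.summary()
    assert list(summary.index) == list(HYPERPARAMETER_NAMES)
    assert list(summary.columns) == ["q10", "q50", "q90"]
    assert (summary["q10"] <= summary["q50"]).all()
    assert (summary["q50"] <= summary["q90"]).all()
    diag = res.diagnostics()
    n_countries = len(tiny_world.dataset.countries)
    assert len(diag) == 8 + 2 * n_countries
    assert np.isfinite(diag["rhat"]).all()
    series = res.summary_series()
    assert set(series["parameter"]) == {"sens", "spec"}
    assert len(series) == 2 * n_countries * tiny_world.dataset.n_years


def test_single_chain_rhat_reported_as_undefined(tiny_world):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = BMisModel(tiny_world.dataset).fit(
            FitConfig(n_chains=1, n_iter=200, n_burnin=100, thin=1, seed=2)
        )
    assert res.diagnostics()["rhat"].isna().all()
    assert res.converged  # undefined R-hat is not flagged as divergence


def test_quantile_definition_is_linear_interpolation():
    draws = np.arange(1.0, 101.0)
    samples_like = {"x": draws}
    from bmis.model import _quantile_frame

    frame = _quantile_frame(samples_like)
    assert frame.loc["x", "q10"] == pytest.approx(np.quantile(draws, 0.1))
    assert frame.loc["x", "q50"] == pytest.approx(50.5)
    const = _quantile_frame({"c": np.full(10, 3.3)})
    assert (const.loc["c"] == 3.3).all()
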