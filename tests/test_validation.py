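import warnings

import numpy as np
import pandas as pd
import pytest

from bmis.data import CRVSSeries, Dataset, StudyObservation
from bmis.model import FitConfig
from bmis.validation import (
    METRIC_COLUMNS,
    predict_crvs_pm,
    run_validation,
    score,
    split_leave_last,
    split_random,
)


def _dataset(n_countries=2, studies_per_country=5):
    crvs, studies = [], []
    for c in range(n_countries):
        name = f"K{c}"
        for y in range(2000, 2012):
            crvs.append(CRVSSeries(name, y, 10, 1000))
        for j in range(studies_per_country):
            studies.append(
                StudyObservation(
                    study_id=f"{name}-{j}",
                    country=name,
                    t1=2000 + 2 * j,
                    t2=2000 + 2 * j,
                    z_crvs=1000,
                    z_mat=8 + j,
                    z_true=12,
                )
            )
    return Dataset(crvs=tuple(crvs), studies=tuple(studies), year_span=(2000, 2011))


def test_split_random_sizes_and_reproducibility():
    data = _dataset()  # 10 studies
    splits = split_random(data, fraction=0.2, n_repeats=4, seed=3)
    assert len(splits) == 4
    for train, test in splits:
        assert len(test) == 2
        ids = {s.study_id for s in train.studies} | {s.study_id for s in test}
        assert ids == {s.study_id for s in data.studies}
        assert not ({s.study_id for s in train.studies} & {s.study_id for s in test})
    again = split_random(data, fraction=0.2, n_repeats=4, seed=3)
    assert [{s.study_id for s in t} for _, t in splits] == [
        {s.study_id for s in t} for _, t in again
    ]


def test_split_leave_last_latest_per_country():
    data = _dataset()
    train, test = split_leave_last(data)
    assert [s.study_id for s in test] == ["K0-4", "K1-4"]
    assert len(train.studies) == len(data.studies) - 2
    # a single-study country contributes its only study to the test set
    single = StudyObservation(
        study_id="K0-solo",
        country="K0",
        t1=2011,
        t2=2011,
        z_crvs=500,
        z_mat=5,
        z_true=6,
    )
    data2 = _dataset(n_countries=1, studies_per_country=0).with_studies((single,))
    train2, test2 = split_leave_last(data2)
    assert len(train2.studies) == 0 and test2 == (single,)


def test_split_leave_last_tie_break_deterministic():
    base = _dataset(n_countries=1, studies_per_country=0)
    a = StudyObservation(
        study_id="a", country="K0", t1=2009, t2=2011, z_crvs=100, z_mat=5, z_true=5
    )
    b = StudyObservation(
        study_id="b", country="K0", t1=2010, t2=2010, z_crvs=100, z_mat=5, z_true=5
    )
    _, test = split_leave_last(base.with_studies((a, b)))
    # same midyear 2010: the longer-running (later t2) study wins
    assert test[0].study_id == "a"


def test_predict_degenerate_draws_recover_reported_pm():
    obs = StudyObservation(
        study_id="s", country="K", t1=2005, t2=2005, z_crvs=10**7, z_mat=40, z_true=50
    )
    ones = np.ones(500)
    exact = predict_crvs_pm(obs, ones, ones, include_binomial=False)
    assert np.allclose(exact, 50 / 10**7)
    # half sensitivity, perfect specificity, huge envelope
    approx = predict_crvs_pm(
        obs, 0.5 * ones, ones, rng=np.random.default_rng(1), include_binomial=True
    )
    assert np.median(approx) == pytest.approx(0.5 * 50 / 10**7, rel=0.05)
    missing = StudyObservation(
        study_id="m", country="K", t1=2005, t2=2005, z_crvs=100,
        z_fneg=5, z_tneg=85, z_mat=10,
    )
    with pytest.raises(ValueError, match="confirmed maternal total"):
        predict_crvs_pm(missing, ones, ones)


def _obs_frame(rows):
    return pd.DataFrame(
        rows, columns=["country", "observed", "predicted", "lower", "upper"]
    )


def test_score_perfect_predictions():
    df = _obs_frame([("A", 0.01, 0.01, 0.005, 0.02), ("B", 0.02, 0.02, 0.01, 0.03)])
    out = score(df, aggregation="per-observation")
    assert out.aggregates["ME"] == 0.0
    assert out.aggregates["MAE"] == 0.0
    assert out.aggregates["MRE"] == 0.0
    assert out.aggregates["MARE"] == 0.0
    assert out.aggregates["prop_below"] == 0.0
    assert out.aggregates["prop_above"] == 0.0


def test_score_coverage_flags_and_hand_case():
    df = _obs_frame(
        [
            ("A", 0.030, 0.020, 0.01, 0.025),  # above upper: error 0.01
            ("A", 0.010, 0.020, 0.015, 0.03),  # below lower: error -0.01
            ("B", 0.020, 0.016, 0.01, 0.03),  # inside: error 0.004
        ]
    )
    out = score(df, aggregation="per-observation")
    assert out.aggregates["n_left_out"] == 3
    assert out.aggregates["ME"] == pytest.approx(0.004)
    assert out.aggregates["MAE"] == pytest.approx(0.01)
    assert out.aggregates["MRE"] == pytest.approx(100 * 0.004 / 0.02)
    assert out.aggregates["prop_below"] == pytest.approx(1 / 3)
    assert out.aggregates["prop_above"] == pytest.approx(1 / 3)
    # within-country means first: A averages to error 0, so the median over
    # countries pairs A's 0 with B's 0.004
    within = score(df, aggregation="within-country-mean")
    assert within.aggregates["ME"] == pytest.approx(0.002)
    assert within.aggregates["prop_below"] == pytest.approx(0.25)


def test_score_permutation_invariant_and_zero_observed():
    rows = [("A", 0.02, 0.018, 0.01, 0.03), ("A", 0.03, 0.02, 0.01, 0.04),
            ("B", 0.01, 0.02, 0.005, 0.04)]
    a = score(_obs_frame(rows), aggregation="within-country-mean")
    b = score(_obs_frame(rows[::-1]), aggregation="within-country-mean")
    assert a.aggregates == b.aggregates
    with pytest.warns(RuntimeWarning, match="zero observed"):
        out = score(
            _obs_frame(rows + [("B", 0.0, 0.01, 0.0, 0.02)]),
            aggregation="per-observation",
        )
    assert np.isfinite(out.aggregates["MARE"])


def test_run_validation_shapes_and_shared_splits():
    from bmis.synthetic import WorldConfig, generate_world

    world = generate_world(
        WorldConfig(
            n_countries=3,
            year_span=(2000, 2007),
            envelope_range=(200, 800),
            pm_range=(0.01, 0.05),
            studies_per_country=3,
            max_period_length=2,
            seed=2,
        )
    )
    cfg = FitConfig(n_chains=2, n_iter=500, n_burnin=200, thin=3, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = run_validation(
            world.dataset,
            fit_config=cfg,
            exercise="random20",
            n_repeats=2,
            seed=4,
        )
    comparison = out["comparison"]
    assert list(comparison.columns) == METRIC_COLUMNS
    assert set(comparison["model"]) == {"BMis", "UNMMEIG2015"}
    assert out["bmis"].split_hash == out["unmmeig2015"].split_hash
    assert out["bmis"].aggregates["n_left_out"] >= 1
    assert np.isfinite(comparison["MARE"]).all()
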