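"""Out-of-sample validation: leave-out splits, predictions and error metrics.

Two exercises probe how well the model predicts the CRVS-*reported*
proportion maternal (PM) for left-out specialized studies:

* ``random20`` — repeatedly leave out 20% of study records at random;
* ``leavelast`` — leave out each country's most recent study.

For a left-out study the model is refit on the training records, and
posterior draws of sensitivity and specificity at the study's country and
midyear are combined with the study's confirmed PM,

    p_mat = se * p_true + (1 - sp) * (1 - p_true),    p_true = z_true / z_crvs,

optionally adding binomial count noise on the envelope so observation-level
intervals reflect stochastic uncertainty.  The 2015-style baseline makes
the analogous prediction by dividing the study PM by its interpolated
adjustment factor with log-normal uncertainty.  Errors are summarized as
medians of (absolute, relative) differences between observed and predicted
PM plus the share of observations falling outside 80% prediction intervals.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjustment import GLOBAL_ADJUSTMENT_2015, LOG_SD_2015, unmmeig2015_series
from .data import Dataset, StudyObservation
from .model import BMisModel, FitConfig

__all__ = [
    "ValidationResult",
    "split_random",
    "split_leave_last",
    "predict_crvs_pm",
    "score",
    "run_validation",
]

METRIC_COLUMNS = [
    "exercise",
    "model",
    "n_left_out",
    "ME",
    "MAE",
    "MRE",
    "MARE",
    "prop_below",
    "prop_above",
]


def split_random(
    data: Dataset, fraction: float = 0.2, n_repeats: int = 20, seed: int = 0
) -> list[tuple[Dataset, tuple[StudyObservation, ...]]]:
    """Repeatedly leave out ``round(fraction * n)`` studies at random."""
    n = len(data.studies)
    if n < 5:
        raise ValueError("need at least 5 studies to hold out a fraction")
    n_out = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        out = set(rng.choice(n, size=n_out, replace=False).tolist())
        train = tuple(s for i, s in enumerate(data.studies) if i not in out)
        test = tuple(s for i, s in enumerate(data.studies) if i in out)
        splits.append((data.with_studies(train), test))
    return splits


def split_leave_last(data: Dataset) -> tuple[Dataset, tuple[StudyObservation, ...]]:
    """Leave out each country's most recent study.

    Ties on midyear break by later end year, then by study id, so the
    split is deterministic.
    """
    latest: dict[str, StudyObservation] = {}
    for s in data.studies:
        cur = latest.get(s.country)
        if cur is None or (s.t_mid, s.t2, s.study_id) > (cur.t_mid, cur.t2, cur.study_id):
            latest[s.country] = s
    test_ids = {s.study_id for s in latest.values()}
    train = tuple(s for s in data.studies if s.study_id not in test_ids)
    test = tuple(latest[c] for c in sorted(latest))
    return data.with_studies(train), test


def predict_crvs_pm(
    test_obs: StudyObservation,
    sens_draws: np.ndarray,
    spec_draws: np.ndarray,
    rng: np.random.Generator | None = None,
    include_binomial: bool = True,
) -> np.ndarray:
    """Predictive draws of the CRVS-reported PM for a left-out study.

    ``sens_draws``/``spec_draws`` must be posterior draws at the study's
    country and midyear.  With ``include_binomial`` the reported count is
    redrawn from Binomial(z_crvs, p_mat) per draw, adding the stochastic
    uncertainty of a finite envelope.
    """
    if test_obs.z_true is None:
        raise ValueError(
            f"study {test_obs.study_id} has no confirmed maternal total; "
            "its study-based PM is unknown"
        )
    p_true = test_obs.z_true / test_obs.z_crvs
    p_mat = sens_draws * p_true + (1.0 - spec_draws) * (1.0 - p_true)
    if not include_binomial:
        return p_mat
    rng = rng or np.random.default_rng()
    counts = rng.binomial(test_obs.z_crvs, np.clip(p_mat, 0.0, 1.0))
    return counts / test_obs.z_crvs


@dataclass(frozen=True)
class ValidationResult:
    """Per-observation predictions and aggregate error/coverage metrics."""

    exercise: str
    method: str
    per_obs: pd.DataFrame
    aggregates: dict
    split_hash: str = ""

    def metrics_row(self) -> dict:
        return {
            "exercise": self.exercise,
            "model": self.method,
            "n_left_out": self.aggregates["n_left_out"],
            **{k: self.aggregates[k] for k in ("ME", "MAE", "MRE", "MARE")},
            "prop_below": self.aggregates["prop_below"],
            "prop_above": self.aggregates["prop_above"],
        }


def score(
    per_obs: pd.DataFrame,
    aggregation: str = "within-country-mean",
    exercise: str = "",
    method: str = "",
    split_hash: str = "",
) -> ValidationResult:
    """Aggregate per-observation prediction records into summary metrics.

    ``per_obs`` needs columns (country, observed, predicted, lower, upper).
    Error is observed minus predicted point estimate; relative error is in
    percent of the observed value (observations with zero observed PM are
    excluded from relative metrics with a warning).  With
    ``within-country-mean`` aggregation, errors and coverage flags are
    averaged within each country before taking medians/proportions across
    countries.
    """
    df = per_obs.copy()
    df["error"] = df["observed"] - df["predicted"]
    df["below"] = (df["observed"] < df["lower"]).astype(float)
    df["above"] = (df["observed"] > df["upper"]).astype(float)
    zero = df["observed"] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} observation(s) with zero observed PM "
            "excluded from relative-error metrics",
            RuntimeWarning,
            stacklevel=2,
        )
    df["rel_error"] = np.where(zero, np.nan, 100.0 * df["error"] / df["observed"])
    df["abs_error"] = df["error"].abs()
    df["abs_rel_error"] = df["rel_error"].abs()

    if aggregation == "within-country-mean":
        unit = df.groupby("country", sort=True)[
            ["error", "abs_error", "rel_error", "abs_rel_error", "below", "above"]
        ].mean()
    elif aggregation == "per-observation":
        unit = df[["error", "abs_error", "rel_error", "abs_rel_error", "below", "above"]]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    aggregates = {
        "n_left_out": int(len(df)),
        "ME": float(unit["error"].median()),
        "MAE": float(unit["abs_error"].median()),
        "MRE": float(np.nanmedian(unit["rel_error"])),
        "MARE": float(np.nanmedian(unit["abs_rel_error"])),
        "prop_below": float(unit["below"].mean()),
        "prop_above": float(unit["above"].mean()),
    }
    return ValidationResult(
        exercise=exercise,
        method=method,
        per_obs=df,
        aggregates=aggregates,
        split_hash=split_hash,
    )


def _hash_splits(splits) -> str:
    h = hashlib.sha256()
    for train, test in splits:
        h.update(",".join(sorted(s.study_id for s in test)).encode())
        h.update(b"|")
    return h.hexdigest()[:16]


def _predict_records(res, test, repeat, rng, include_binomial):
    """BMis per-observation prediction records for one split."""
    recs = []
    for obs in test:
        if obs.z_true is None:
            continue  # no study-based PM for partial-breakdown records
        se = res.sens(obs.country, obs.t_mid)
        sp = res.spec(obs.country, obs.t_mid)
        draws = predict_crvs_pm(obs, se, sp, rng=rng, include_binomial=include_binomial)
        q10, q50, q90 = np.quantile(draws, (0.1, 0.5, 0.9))
        recs.append(
            dict(
                repeat=repeat,
                study_id=obs.study_id,
                country=obs.country,
                observed=obs.z_mat / obs.z_crvs,
                predicted=q50,
                lower=q10,
                upper=q90,
            )
        )
    return recs


def _baseline_records(train, test, repeat, rng, n_draws, include_binomial):
    """2015-style baseline prediction records for one split."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        series = unmmeig2015_series(train)
    omega_lookup = {
        (r.country, r.year): r.omega for r in series.frame.itertuples()
    }
    recs = []
    for obs in test:
        if obs.z_true is None:
            continue
        omega_hat = omega_lookup.get((obs.country, obs.t_mid), GLOBAL_ADJUSTMENT_2015)
        omega = omega_hat * np.exp(rng.normal(0.0, LOG_SD_2015, size=n_draws))
        p_true = obs.z_true / obs.z_crvs
        p_mat = p_true / omega
        if include_binomial:
            counts = rng.binomial(obs.z_crvs, np.clip(p_mat, 0.0, 1.0))
            draws = counts / obs.z_crvs
        else:
            draws = p_mat
        q10, q50, q90 = np.quantile(draws, (0.1, 0.5, 0.9))
        recs.append(
            dict(
                repeat=repeat,
                study_id=obs.study_id,
                country=obs.country,
                observed=obs.z_mat / obs.z_crvs,
                predicted=q50,
                lower=q10,
                upper=q90,
            )
        )
    return recs


def run_validation(
    data: Dataset,
    fit_config: FitConfig | None = None,
    exercise: str = "random20",
    fraction: float = 0.2,
    n_repeats: int = 20,
    seed: int = 0,
    include_binomial: bool = True,
    aggregation: str | None = None,
) -> dict:
    """Run one validation exercise for both the model and the 2015 baseline.

    Both methods consume identical train/test splits.  Returns a dict with
    per-method :class:`ValidationResult` objects and a Table-style
    ``comparison`` frame.  The leave-20% exercise aggregates within-country
    means (the leave-last exercise has one observation per country, where
    the two aggregations coincide).
    """
    fit_config = fit_config or FitConfig.desk(seed=seed)
    if exercise == "random20":
        splits = split_random(data, fraction=fraction, n_repeats=n_repeats, seed=seed)
        if aggregation is None:
            aggregation = "within-country-mean"
    elif exercise == "leavelast":
        splits = [split_leave_last(data)]
        if aggregation is None:
            aggregation = "per-observation"
    else:
        raise ValueError(f"unknown exercise {exercise!r}")
    split_hash = _hash_splits(splits)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    bmis_recs, base_recs = [], []
    for rep, (train, test) in enumerate(splits):
        cfg = FitConfig(
            **{
                **fit_config.__dict__,
                "seed": (fit_config.seed + 1000 * rep) % (2**31 - 1),
            }
        )
        res = BMisModel(train, apply_exclusion=cfg.apply_exclusion).fit(cfg)
        bmis_recs += _predict_records(res, test, rep, rng, include_binomial)
        base_recs += _baseline_records(
            train, test, rep, rng, res.samples.n_draws, include_binomial
        )

    bmis = score(
        pd.DataFrame(bmis_recs),
        aggregation=aggregation,
        exercise=exercise,
        method="BMis",
        split_hash=split_hash,
    )
    base = score(
        pd.DataFrame(base_recs),
        aggregation=aggregation,
        exercise=exercise,
        method="UNMMEIG2015",
        split_hash=split_hash,
    )
    comparison = pd.DataFrame([bmis.metrics_row(), base.metrics_row()])[METRIC_COLUMNS]
    return {"bmis": bmis, "unmmeig2015": base, "comparison": comparison}
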