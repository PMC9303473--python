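"""CRVS adjustment factors from sensitivity/specificity, and the 2015-style
baseline.

The adjustment factor Omega is the ratio of the *true* proportion maternal
(PM) to the CRVS-*reported* PM; multiplying reported maternal deaths by
Omega corrects for misclassification.  Given sensitivity ``se``,
specificity ``sp`` and true PM ``g``,

    Omega = g / ( se * g + (1 - sp) * (1 - g) ).

When specificity is one this collapses to 1/se regardless of the true PM;
with specificity below one, Omega rises with the true PM because false
positives weigh more heavily when maternal deaths are rare.

The pre-2019 UN-MMEIG procedure instead anchored Omega at observed
study/CRVS PM ratios and carried them across years: linear interpolation
between observed midyears, constant forward extrapolation, and a backward
ramp reaching a global factor of 1.5 over five years.  Its uncertainty is
a fixed 0.25 SD on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AdjustmentSeries",
    "adjustment_factor",
    "adjustment_samples",
    "adjustment_curve",
    "unmmeig2015_series",
]

GLOBAL_ADJUSTMENT_2015 = 1.5
BACKWARD_RAMP_YEARS = 5
LOG_SD_2015 = 0.25


@dataclass(frozen=True)
class AdjustmentSeries:
    """Per-country-year adjustment factors with uncertainty.

    ``frame`` holds one row per country-year with columns
    (country, year, omega, omega_q10, omega_q90) where ``omega`` is the
    median (BMIS) or point estimate (UNMMEIG2015); for the 2015 method an
    extra ``log_sd`` column carries the fixed log-scale SD.  ``draws``,
    when present, is (n_draws, n_rows) aligned with the frame rows.
    """

    frame: pd.DataFrame
    method: str
    draws: np.ndarray | None = None


def adjustment_factor(sens, spec, true_pm):
    """Omega = true PM over reported PM; array-broadcasting, strictly positive."""
    sens = np.asarray(sens, dtype=float)
    spec = np.asarray(spec, dtype=float)
    g = np.asarray(true_pm, dtype=float)
    denom = sens * g + (1.0 - spec) * (1.0 - g)
    if np.any(denom <= 0.0):
        raise ZeroDivisionError(
            "reported PM is zero (sens*g + (1-spec)*(1-g) <= 0); "
            "adjustment factor undefined"
        )
    out = g / denom
    return float(out) if out.ndim == 0 else out


def adjustment_curve(sens: float, spec_values, pm_grid) -> pd.DataFrame:
    """Omega on a (specificity x true PM) grid, one column per specificity.

    Suitable for plotting the adjustment factor against true PM at a fixed
    sensitivity for several specificity values.
    """
    pm_grid = np.asarray(pm_grid, dtype=float)
    data = {"true_pm": pm_grid}
    for sp in spec_values:
        data[f"spec={sp:g}"] = adjustment_factor(sens, sp, pm_grid)
    return pd.DataFrame(data)


def adjustment_samples(results, true_pm: pd.DataFrame) -> AdjustmentSeries:
    """One Omega draw per posterior draw per requested country-year.

    ``true_pm`` must have columns (country, year, true_pm); the true PM is
    an external input (it is estimated elsewhere, not by this model).
    """
    samples = results.samples
    sens = samples.sens
    spec = samples.spec
    rows, draw_cols = [], []
    for rec in true_pm.itertuples():
        try:
            c = samples.country_index(rec.country)
            t = samples.year_index(int(rec.year))
        except (ValueError, KeyError) as err:
            raise KeyError(
                f"no posterior draws for country-year "
                f"({rec.country}, {rec.year})"
            ) from err
        omega = adjustment_factor(sens[:, c, t], spec[:, c, t], float(rec.true_pm))
        q10, q50, q90 = np.quantile(omega, (0.1, 0.5, 0.9))
        rows.append((rec.country, int(rec.year), q50, q10, q90))
        draw_cols.append(omega)
    frame = pd.DataFrame(
        rows, columns=["country", "year", "omega", "omega_q10", "omega_q90"]
    )
    return AdjustmentSeries(
        frame=frame, method="BMIS", draws=np.column_stack(draw_cols)
    )


def _baseline_points(dataset) -> dict[str, list[tuple[int, float]]]:
    """Observed adjustment ratios z_true/z_mat anchored at study midyears."""
    points: dict[str, dict[int, list[float]]] = {}
    for s in dataset.studies:
        if s.z_true is None:
            warnings.warn(
                f"study {s.study_id}: no confirmed maternal total; "
                "skipped in the 2015-style adjustment",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        if s.z_mat == 0:
            warnings.warn(
                f"study {s.study_id}: zero CRVS-coded maternal deaths; "
                "adjustment ratio undefined, record skipped",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        points.setdefault(s.country, {}).setdefault(s.t_mid, []).append(
            s.z_true / s.z_mat
        )
    # multiple studies sharing a midyear: average their ratios
    return {
        country: sorted((year, float(np.mean(vals))) for year, vals in by_year.items())
        for country, by_year in points.items()
    }


def unmmeig2015_series(
    dataset,
    global_factor: float = GLOBAL_ADJUSTMENT_2015,
    ramp_years: int = BACKWARD_RAMP_YEARS,
    log_sd: float = LOG_SD_2015,
) -> AdjustmentSeries:
    """2015-style adjustment series for every country with usable studies.

    Point estimates are the observed study-to-CRVS PM ratios at study
    midyears; years in between are linearly interpolated, later years are
    held at the most recent observed value, and earlier years ramp
    linearly to the global factor over ``ramp_years`` years and stay there.
    Quantile columns come from the fixed log-normal uncertainty.
    """
    years = dataset.years
    rows = []
    z10, z90 = -1.2815515655446004, 1.2815515655446004  # normal 10/90 quantiles
    for country, pts in _baseline_points(dataset).items():
        obs_years = np.array([p[0] for p in pts], dtype=float)
        obs_omega = np.array([p[1] for p in pts], dtype=float)
        omega = np.interp(years, obs_years, obs_omega)  # interior + flat ends
        first_year, first_omega = obs_years[0], obs_omega[0]
        before = years < first_year
        frac = np.clip((first_year - years[before]) / ramp_years, 0.0, 1.0)
        omega[before] = first_omega + frac * (global_factor - first_omega)
        for year, om in zip(years, omega):
            rows.append(
                (
                    country,
                    int(year),
                    float(om),
                    float(om * np.exp(z10 * log_sd)),
                    float(om * np.exp(z90 * log_sd)),
                    log_sd,
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=["country", "year", "omega", "omega_q10", "omega_q90", "log_sd"],
    )
    return AdjustmentSeries(frame=frame, method="UNMMEIG2015")
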