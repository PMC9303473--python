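"""Model and results objects for posterior inference.

``BMisModel`` wraps a validated :class:`~bmis.data.Dataset`; ``fit()``
samples the posterior of the hierarchical misclassification model and
returns a ``BMisResults`` carrying posterior draws, convergence
diagnostics and quantile summaries.

Typical use::

    model = BMisModel.from_csv("crvs.csv", "studies.csv")
    res = model.fit(FitConfig.desk(seed=1))
    print(res.summary())
    sens = res.sens("BRA")          # (n_draws, T) sensitivity draws

Summaries report the 10%, 50% and 90% quantiles (the bounds of 80%
credible intervals); quantiles use numpy's default linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._mcmc import LikelihoodData, run_mcmc
from .data import Dataset, read_dataset, DEFAULT_YEAR_SPAN
from .process import HYPERPARAMETER_NAMES, probit_to_prob

__all__ = ["FitConfig", "PosteriorSamples", "BMisModel", "BMisResults", "split_rhat"]


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings.

    The defaults reproduce the production schedule: 10 parallel chains of
    40 000 iterations, the first 10 000 discarded as burn-in, every 20th
    retained thereafter (15 000 retained draws).  Use :meth:`desk` for a
    schedule sized for interactive work and tests.
    """

    n_chains: int = 10
    n_iter: int = 40_000
    n_burnin: int = 10_000
    thin: int = 20
    seed: int = 0
    apply_exclusion: bool = True

    def __post_init__(self):
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.n_burnin) % self.thin:
            raise ValueError("n_iter - n_burnin must be divisible by thin")

    @classmethod
    def desk(cls, seed: int = 0, **kwargs) -> "FitConfig":
        """Light schedule for desk work: 4 chains x 5000, burn-in 2000, thin 6."""
        return cls(
            n_chains=4, n_iter=5_000, n_burnin=2_000, thin=6, seed=seed, **kwargs
        )

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iter - self.n_burnin) // self.thin


def split_rhat(x: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for an array of shape (chains, draws).

    Each chain is split in half; R-hat compares between- to within-half
    variance.  Degenerate zero-variance cases (identical chains of a
    constant) return exactly 1.0.
    """
    x = np.asarray(x, dtype=float)
    m, n = x.shape
    half = n // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    b = half * halves.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def _ess(x: np.ndarray) -> float:
    """Bulk effective sample size; total draw count for constant chains."""
    x = np.asarray(x, dtype=float)
    if x.var() == 0.0:
        return float(x.size)
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.ess(az.convert_to_dataset(x))["x"].values).item())


@dataclass(frozen=True)
class PosteriorSamples:
    """Posterior draws of every latent quantity, with chain provenance.

    Arrays are indexed ``[chain, draw, ...]``:

    * ``hyper`` — (chains, draws, 8) in the order of
      :data:`~bmis.process.HYPERPARAMETER_NAMES`;
    * ``eta_mean`` — (chains, draws, C, 2) country mean probit levels;
    * ``eta_series`` — (chains, draws, C, T, 2) probit series;
    * ``gamma_true`` — (chains, draws, n_studies).
    """

    hyper: np.ndarray
    eta_mean: np.ndarray
    eta_series: np.ndarray
    gamma_true: np.ndarray
    countries: tuple[str, ...]
    years: np.ndarray
    study_ids: tuple[str, ...]
    config: FitConfig

    @property
    def n_draws(self) -> int:
        """Total retained draws across chains."""
        return self.hyper.shape[0] * self.hyper.shape[1]

    def _flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(self.n_draws, *arr.shape[2:])

    def hyper_frame(self) -> pd.DataFrame:
        chains, draws, _ = self.hyper.shape
        df = pd.DataFrame(self._flat(self.hyper), columns=list(HYPERPARAMETER_NAMES))
        df.insert(0, "draw", np.tile(np.arange(draws), chains))
        df.insert(0, "chain", np.repeat(np.arange(chains), draws))
        return df

    @property
    def sens(self) -> np.ndarray:
        """Sensitivity draws, (n_draws, C, T), probability scale."""
        return probit_to_prob(self._flat(self.eta_series)[..., 0])

    @property
    def spec(self) -> np.ndarray:
        """Specificity draws, (n_draws, C, T), probability scale."""
        return probit_to_prob(self._flat(self.eta_series)[..., 1])

    def country_index(self, country: str) -> int:
        return self.countries.index(country)

    def year_index(self, year: int) -> int:
        idx = int(year - self.years[0])
        if not 0 <= idx < len(self.years):
            raise KeyError(f"year {year} outside estimation grid")
        return idx


QUANTILES = (0.1, 0.5, 0.9)


def _quantile_frame(named_draws: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = {
        name: np.quantile(d, QUANTILES) for name, d in named_draws.items()
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"q{int(q * 100)}" for q in QUANTILES]
    ).rename_axis("parameter")


class BMisModel:
    """Hierarchical misclassification model for CRVS maternal-death reporting.

    Parameters
    ----------
    dataset
        Validated CRVS series plus specialized-study records.
    apply_exclusion
        Prune negligible latent tables in the overlapping-totals likelihood
        (computational device; on by default for inference).
    """

    def __init__(self, dataset: Dataset, apply_exclusion: bool = True):
        if len(dataset.studies) == 0:
            raise ValueError("model requires at least one specialized study")
        self.dataset = dataset
        self.apply_exclusion = apply_exclusion
        self._lik = LikelihoodData(dataset, apply_exclusion=apply_exclusion)

    @classmethod
    def from_csv(
        cls,
        crvs_path,
        studies_path,
        year_span: tuple[int, int] = DEFAULT_YEAR_SPAN,
        apply_exclusion: bool = True,
    ) -> "BMisModel":
        return cls(
            read_dataset(crvs_path, studies_path, year_span=year_span),
            apply_exclusion=apply_exclusion,
        )

    def fit(self, config: FitConfig | None = None) -> "BMisResults":
        """Sample the posterior; warns (and flags the result) on non-convergence."""
        config = config or FitConfig()
        if config.apply_exclusion != self.apply_exclusion:
            config = replace(config, apply_exclusion=self.apply_exclusion)
        raw = run_mcmc(self._lik, config)
        samples = PosteriorSamples(
            hyper=raw["hyper"],
            eta_mean=raw["eta_mean"],
            eta_series=raw["eta_series"],
            gamma_true=raw["gamma"],
            countries=tuple(self._lik.countries),
            years=self.dataset.years.copy(),
            study_ids=tuple(s.study_id for s in self.dataset.studies),
            config=config,
        )
        res = BMisResults(model=self, samples=samples)
        if not res.converged:
            warnings.warn(
                f"MCMC convergence not reached: max split R-hat = "
                f"{res.max_rhat:.3f} > 1.1 on monitored parameters",
                RuntimeWarning,
                stacklevel=2,
            )
        return res


@dataclass
class BMisResults:
    """Posterior fit: draws, diagnostics, summaries and derived quantities."""

    model: BMisModel
    samples: PosteriorSamples
    _diag: pd.DataFrame | None = field(default=None, repr=False)

    # -- diagnostics --------------------------------------------------------

    def diagnostics(self) -> pd.DataFrame:
        """Split R-hat and effective sample size for monitored parameters.

        Monitored: the eight hyperparameters plus every country's mean
        probit sensitivity and specificity.  With a single chain R-hat is
        undefined and reported as NaN.
        """
        if self._diag is not None:
            return self._diag
        s = self.samples
        rows = {}
        single = s.hyper.shape[0] < 2
        for j, name in enumerate(HYPERPARAMETER_NAMES):
            x = s.hyper[:, :, j]
            rows[name] = (
                np.nan if single else split_rhat(x),
                _ess(x),
            )
        for c, country in enumerate(s.countries):
            for j, side in enumerate(("sens", "spec")):
                x = s.eta_mean[:, :, c, j]
                rows[f"eta_mean_{side}[{country}]"] = (
                    np.nan if single else split_rhat(x),
                    _ess(x),
                )
        self._diag = pd.DataFrame.from_dict(
            rows, orient="index", columns=["rhat", "ess"]
        ).rename_axis("parameter")
        return self._diag

    @property
    def max_rhat(self) -> float:
        r = self.diagnostics()["rhat"]
        return float(r.max()) if r.notna().any() else float("nan")

    @property
    def converged(self) -> bool:
        """True when every monitored split R-hat is at most 1.1."""
        r = self.max_rhat
        return bool(np.isnan(r) or r <= 1.1)

    # -- summaries ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """10%/50%/90% posterior quantiles of the hyperparameters."""
        s = self.samples
        flat = s._flat(s.hyper)
        return _quantile_frame(
            {name: flat[:, j] for j, name in enumerate(HYPERPARAMETER_NAMES)}
        )

    def summary_countries(self) -> pd.DataFrame:
        """Quantiles of each country's mean-level sensitivity and specificity."""
        s = self.samples
        flat = probit_to_prob(s._flat(s.eta_mean))
        rows = {}
        for c, country in enumerate(s.countries):
            rows[f"sens_mean[{country}]"] = flat[:, c, 0]
            rows[f"spec_mean[{country}]"] = flat[:, c, 1]
        return _quantile_frame(rows)

    def summary_series(self) -> pd.DataFrame:
        """Long table of country-year sensitivity/specificity quantiles."""
        s = self.samples
        recs = []
        for name, draws in (("sens", s.sens), ("spec", s.spec)):
            q = np.quantile(draws, QUANTILES, axis=0)  # (3, C, T)
            for c, country in enumerate(s.countries):
                for t, year in enumerate(s.years):
                    recs.append(
                        (country, int(year), name, q[0, c, t], q[1, c, t], q[2, c, t])
                    )
        return pd.DataFrame(
            recs, columns=["country", "year", "parameter", "q10", "q50", "q90"]
        )

    # -- draw accessors ------------------------------------------------------

    def sens(self, country: str, year: int | None = None) -> np.ndarray:
        """Sensitivity draws for a country: (n_draws, T) or (n_draws,) at a year."""
        c = self.samples.country_index(country)
        draws = self.samples.sens[:, c, :]
        return draws if year is None else draws[:, self.samples.year_index(year)]

    def spec(self, country: str, year: int | None = None) -> np.ndarray:
        c = self.samples.country_index(country)
        draws = self.samples.spec[:, c, :]
        return draws if year is None else draws[:, self.samples.year_index(year)]

    # -- derived quantities ---------------------------------------------------

    def adjustment_samples(self, true_pm: pd.DataFrame):
        """CRVS adjustment-factor draws; see :func:`bmis.adjustment.adjustment_samples`."""
        from .adjustment import adjustment_samples

        return adjustment_samples(self, true_pm)

    def plot_country(self, country: str, ax=None):
        """Plot posterior median and 80% band of sensitivity and specificity."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.2), sharex=True)
        years = self.samples.years
        for a, (name, draws) in zip(
            ax, (("sensitivity", self.sens(country)), ("specificity", self.spec(country)))
        ):
            q10, q50, q90 = np.quantile(draws, QUANTILES, axis=0)
            a.plot(years, q50, color="C0")
            a.fill_between(years, q10, q90, alpha=0.3, color="C0")
            a.set_title(f"{country} {name}")
            a.set_ylim(0, 1.02)
        return ax
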