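"""Synthetic worlds drawn from the model's own generative process.

A *world* is the complete truth — per-country-year sensitivity,
specificity, true maternal proportion and the four classification-cell
counts — together with the masked observable :class:`~bmis.data.Dataset`
a study database would actually contain.  Masking mirrors the empirical
mix of reporting detail: roughly 72% of study records carry only the
confirmed and CRVS-coded maternal totals, 19% add the false-negative
breakdown, and 9% report all four cells (shares 147/39/18 of 204 records).

Default magnitudes emulate national CRVS systems: envelopes of 10^3-10^5
deaths of women of reproductive age per year, true maternal proportions
of 0.3-2% with mild linear trends, and hyperparameters at the posterior
medians reported for the global CRVS study database (global sensitivity
0.593, global specificity 0.9995).  Multi-year study periods aggregate
yearly multinomial draws whose probabilities vary over the period, while
the likelihood evaluates probabilities at the midyear — a deliberate,
mild model misspecification that mirrors real study reporting;
``constant_probs=True`` removes it for exact-model tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, CRVSSeries, StudyObservation, ReportingPattern
from .process import Hyperparameters, sample_prior

__all__ = [
    "DEFAULT_HYPERPARAMETERS",
    "WorldConfig",
    "StudyDesign",
    "SyntheticWorld",
    "generate_world",
    "mask_world",
    "make_fixture",
]

#: Posterior-median hyperparameters for the global maternal-mortality
#: CRVS study database; used as generative truth by default.
DEFAULT_HYPERPARAMETERS = Hyperparameters(
    lambda_global_sens=0.593,
    lambda_global_spec=0.9995,
    sigma_sens=0.599,
    sigma_spec=0.157,
    rho=0.307,
    delta_sens=0.117,
    delta_spec=0.131,
    phi=-0.370,
)

#: Observed mix of reporting detail across study records.
DEFAULT_PATTERN_MIX = {
    ReportingPattern.TRUE_TOTAL_ONLY: 147 / 204,
    ReportingPattern.PARTIAL_FNEG: 39 / 204,
    ReportingPattern.FULL_BREAKDOWN: 18 / 204,
}


@dataclass(frozen=True)
class WorldConfig:
    """Generative settings for a synthetic world."""

    n_countries: int = 15
    year_span: tuple[int, int] = (1998, 2017)
    hyper: Hyperparameters = DEFAULT_HYPERPARAMETERS
    envelope_range: tuple[float, float] = (1e3, 1e5)
    pm_range: tuple[float, float] = (0.003, 0.02)
    pm_trend_range: tuple[float, float] = (-0.02, 0.02)
    studies_per_country: int = 4
    max_period_length: int = 3
    pattern_mix: dict = field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    constant_probs: bool = False
    seed: int = 0

    def __post_init__(self):
        total = sum(self.pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern mix sums to {total}, not 1")
        if self.envelope_range[0] <= 0 or self.envelope_range[0] > self.envelope_range[1]:
            raise ValueError(f"invalid envelope range {self.envelope_range}")
        lo, hi = self.pm_range
        if not (1e-4 < lo <= hi <= 0.05):
            raise ValueError("pm_range must lie within (0.0001, 0.05]")

    @property
    def T(self) -> int:
        return self.year_span[1] - self.year_span[0] + 1


@dataclass(frozen=True)
class StudyDesign:
    """Placement and reporting pattern of one synthetic study."""

    country: int  # index
    t1: int  # time index (inclusive)
    t2: int
    pattern: ReportingPattern


@dataclass(frozen=True)
class SyntheticWorld:
    """Truth arrays plus the masked observable dataset."""

    config: WorldConfig
    sens: np.ndarray  # (C, T)
    spec: np.ndarray  # (C, T)
    gamma_true: np.ndarray  # (C, T)
    y_crvs: np.ndarray  # (C, T) int
    cells: np.ndarray  # (C, T, 4) int, order (T+, F+, F-, T-)
    designs: tuple[StudyDesign, ...]
    dataset: Dataset

    @property
    def countries(self) -> list[str]:
        return self.dataset.countries

    def truth_frame(self) -> pd.DataFrame:
        first = self.config.year_span[0]
        recs = []
        for c, country in enumerate(self.countries):
            for t in range(self.config.T):
                recs.append(
                    (
                        country,
                        first + t,
                        self.sens[c, t],
                        self.spec[c, t],
                        self.gamma_true[c, t],
                        *self.cells[c, t],
                    )
                )
        return pd.DataFrame(
            recs,
            columns=[
                "country",
                "year",
                "sens",
                "spec",
                "gamma_true",
                "y_tpos",
                "y_fpos",
                "y_fneg",
                "y_tneg",
            ],
        )


def _design_studies(config: WorldConfig, rng: np.random.Generator) -> list[StudyDesign]:
    """Place non-overlapping study periods and assign reporting patterns."""
    patterns = list(config.pattern_mix.keys())
    probs = np.array([config.pattern_mix[p] for p in patterns])
    designs = []
    T = config.T
    for c in range(config.n_countries):
        taken = np.zeros(T, dtype=bool)
        placed = 0
        for _ in range(200):
            if placed >= config.studies_per_country:
                break
            length = int(rng.integers(1, config.max_period_length + 1))
            if length > T:
                length = T
            t1 = int(rng.integers(0, T - length + 1))
            if taken[t1 : t1 + length].any():
                continue
            taken[t1 : t1 + length] = True
            pattern = patterns[rng.choice(len(patterns), p=probs)]
            designs.append(StudyDesign(country=c, t1=t1, t2=t1 + length - 1, pattern=pattern))
            placed += 1
    return designs


def mask_world(
    cells: np.ndarray,
    designs,
    countries: list[str],
    first_year: int,
) -> list[StudyObservation]:
    """Aggregate truth cells over study periods and keep pattern-visible fields."""
    out = []
    counter: dict[int, int] = {}
    for d in designs:
        k = counter.get(d.country, 0) + 1
        counter[d.country] = k
        z = cells[d.country, d.t1 : d.t2 + 1].sum(axis=0)
        tpos, fpos, fneg, tneg = (int(v) for v in z)
        common = dict(
            study_id=f"{countries[d.country]}-{k:02d}",
            country=countries[d.country],
            t1=first_year + d.t1,
            t2=first_year + d.t2,
            z_crvs=int(z.sum()),
        )
        if d.pattern is ReportingPattern.FULL_BREAKDOWN:
            obs = StudyObservation(
                **common, z_tpos=tpos, z_fpos=fpos, z_fneg=fneg, z_tneg=tneg
            )
        elif d.pattern is ReportingPattern.PARTIAL_FNEG:
            obs = StudyObservation(
                **common, z_fneg=fneg, z_tneg=tneg, z_mat=tpos + fpos
            )
        else:
            obs = StudyObservation(
                **common, z_mat=tpos + fpos, z_true=tpos + fneg
            )
        out.append(obs)
    return out


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw a complete world from the hierarchical generative process."""
    rng = np.random.default_rng(config.seed)
    C, T = config.n_countries, config.T
    _, sens, spec = sample_prior(config.hyper, C, T, rng)

    lo, hi = config.envelope_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=C))
    y_crvs = np.maximum(rng.poisson(base[:, None], size=(C, T)), 1)

    pm_base = np.exp(rng.uniform(*np.log(config.pm_range), size=C))
    trend = rng.uniform(*config.pm_trend_range, size=C)
    t_rel = np.arange(T) - (T - 1) / 2.0
    gamma = np.clip(pm_base[:, None] * (1.0 + trend[:, None] * t_rel), 2e-4, 0.05)

    designs = _design_studies(config, rng)

    probs = np.empty((C, T, 4))
    probs[:, :, 0] = sens * gamma
    probs[:, :, 2] = gamma - probs[:, :, 0]
    probs[:, :, 3] = spec * (1.0 - gamma)
    probs[:, :, 1] = (1.0 - gamma) - probs[:, :, 3]
    if config.constant_probs:
        # freeze each study period at its midyear probabilities
        for d in designs:
            mid = (d.t1 + d.t2) // 2
            probs[d.country, d.t1 : d.t2 + 1, :] = probs[d.country, mid, :]

    cells = np.empty((C, T, 4), dtype=np.int64)
    for c in range(C):
        for t in range(T):
            cells[c, t] = rng.multinomial(y_crvs[c, t], probs[c, t])

    first_year = config.year_span[0]
    countries = [f"C{c + 1:02d}" for c in range(C)]
    crvs = [
        CRVSSeries(
            country=countries[c],
            year=first_year + t,
            y_mat=int(cells[c, t, 0] + cells[c, t, 1]),
            y_crvs=int(y_crvs[c, t]),
        )
        for c in range(C)
        for t in range(T)
    ]
    studies = mask_world(cells, designs, countries, first_year)
    dataset = Dataset(
        crvs=tuple(crvs), studies=tuple(studies), year_span=config.year_span
    )
    return SyntheticWorld(
        config=config,
        sens=sens,
        spec=spec,
        gamma_true=gamma,
        y_crvs=y_crvs,
        cells=cells,
        designs=tuple(designs),
        dataset=dataset,
    )


def make_fixture(size: str = "tiny", seed: int | None = None) -> SyntheticWorld:
    """Fixed-seed worlds for tests.

    ``tiny``: 2 countries x 5 years with envelopes of at most a few
    hundred deaths, keeping every latent-table enumeration small enough
    for brute-force oracles.  ``small``: 15 countries x 20 years with
    about 60 studies, the scale used for parameter-recovery checks.
    """
    if size == "tiny":
        config = WorldConfig(
            n_countries=2,
            year_span=(2000, 2004),
            envelope_range=(80, 200),
            pm_range=(0.01, 0.05),
            studies_per_country=2,
            max_period_length=2,
            seed=20210 if seed is None else seed,
        )
    elif size == "small":
        config = WorldConfig(seed=114 if seed is None else seed)
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    return generate_world(config)
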