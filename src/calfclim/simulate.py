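"""Synthetic stand-ins for the survey and climate inputs.

The generator emulates the statistical structure the models assume rather
than any particular historical record:

* monthly SOI and NINO 3.4 as a bivariate AR(1) pair with negative
  cross-correlation (the two ENSO indices move in opposition);
* sub-regional monthly rainfall with a November-April wet season and a
  positive SOI coupling (La Nina years are wet years on this coast);
* tropical-cyclone tracks generated season by season with a Poisson count
  whose rate is elevated in La Nina seasons (doubled by default), placed
  so that most but not all storms pass within the 5-degree exposure radius
  of a sub-region coastline;
* calf counts drawn from the Beta-Binomial trend model itself, with
  configurable true parameters and planted driver effects.

Named fixtures bundle data plus the ground-truth parameters for recovery
and selection tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .climate import (
    CovariateTable,
    CycloneTrack,
    LaggedDesign,
    MonthlySeries,
    build_covariate_table,
    build_lagged_design,
    cyclone_counts,
)
from .splines import SplineBasis, build_spline_basis
from .surveys import (
    SubregionRegistry,
    SurveyTable,
    default_registry,
    table1_survey_years,
)

__all__ = [
    "ScenarioConfig",
    "FixtureBundle",
    "FIXTURE_NAMES",
    "simulate_climate",
    "simulate_surveys",
    "make_fixture",
    "classify_enso_seasons",
]

WET_WEIGHT = {11: 0.6, 12: 1.0, 1: 1.0, 2: 1.0, 3: 0.7, 4: 0.4}


@dataclass
class ScenarioConfig:
    """True parameters and process settings for one synthetic scenario.

    ``term_effects`` maps ``(driver, lag, subregion)`` to the true
    standardized effect on the logit; everything absent is zero.
    """

    survey_design: dict[str, tuple[int, ...]] = field(default_factory=table1_survey_years)
    beta0: float = -2.1972245773362196        # logit(0.10)
    beta1: float = 0.15
    # the penalized thin-plate columns have sd well above 1, so modest
    # coefficients already move the trend visibly
    r: tuple[float, ...] = (0.05, -0.04, 0.03)
    gamma0: tuple[float, ...] = (0.2, -0.15, 0.1, -0.2)
    gamma1: tuple[float, ...] = (0.1, -0.1, 0.05, -0.05)
    s: tuple[float, ...] = (0.0,) * 12
    theta: float = 20.0
    term_effects: dict[tuple[str, int, str], float] = field(default_factory=dict)
    # counts per survey: rounded lognormal, median ~150 dugongs sighted
    count_median: float = 150.0
    count_log_sd: float = 0.6
    # ENSO process
    enso_ar: float = 0.8                  # monthly AR(1) coefficient
    enso_cross_corr: float = -0.7         # SOI vs NINO34 innovation correlation
    soi_sd: float = 7.0
    nino_sd: float = 0.9
    # rainfall process (mm / month)
    rain_wet_mean: float = 160.0
    rain_dry_mean: float = 40.0
    rain_noise_sd: float = 35.0
    rain_soi_coupling: float = 25.0       # mm per standardized SOI in peak wet months
    # cyclone process
    cyclone_base_rate: float = 2.5        # storms per season near the coast
    la_nina_multiplier: float = 2.0
    miss_probability: float = 0.15        # storms generated far offshore
    n_knots: int = 3

    def __post_init__(self):
        if not (0 < self.theta < 100 or self.theta >= 1e5):
            raise ValueError("theta must lie in (0, 100) (or be effectively infinite)")
        if self.cyclone_base_rate <= 0:
            raise ValueError("cyclone rate must be positive")
        if self.la_nina_multiplier < 1:
            raise ValueError("La Nina multiplier must be >= 1")


@dataclass
class FixtureBundle:
    """Everything a test needs: data, design matrices and the truth record."""

    name: str
    surveys: SurveyTable
    covariates: CovariateTable
    design: LaggedDesign
    basis: SplineBasis
    tracks: list[CycloneTrack]
    registry: SubregionRegistry
    truth: dict
    config: ScenarioConfig

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, sort_keys=True)


def _rng(seed, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stage])


def classify_enso_seasons(seasonal_soi: pd.Series, band: float = 0.5) -> pd.Series:
    """Label season-years La Nina / El Nino / neutral from seasonal SOI.

    Standardizes across the given years; |z| >= ``band`` picks the phases.
    """
    z = (seasonal_soi - seasonal_soi.mean()) / seasonal_soi.std(ddof=1)
    return pd.Series(
        np.where(z >= band, "la_nina", np.where(z <= -band, "el_nino", "neutral")),
        index=seasonal_soi.index, name="phase",
    )


def simulate_climate(
    config: ScenarioConfig,
    years,
    seed: int = 0,
    registry: SubregionRegistry | None = None,
    baseline_years: int = 30,
):
    """Generate monthly series, cyclone tracks and the covariate table.

    ``years`` are the covariate years required; monthly series extend
    ``baseline_years + 1`` years earlier so the rainfall anomaly baseline is
    covered.  Returns ``(rainfall, soi, nino34, tracks, covariates)`` where
    ``rainfall`` maps sub-region name to its MonthlySeries.
    """
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("no covariate years requested")
    registry = registry or default_registry()
    first, last = years[0], years[-1]
    month_start = first - baseline_years - 1
    months = [(y, m) for y in range(month_start, last + 1) for m in range(1, 13)]

    # -- bivariate AR(1) ENSO pair ----------------------------------------
    rng = _rng(seed, 1)
    phi = config.enso_ar
    rho = config.enso_cross_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    innov_sd = np.sqrt(1.0 - phi**2)   # unit stationary variance
    state = chol @ rng.standard_normal(2)
    soi_vals, nino_vals = {}, {}
    for key in months:
        state = phi * state + innov_sd * (chol @ rng.standard_normal(2))
        soi_vals[key] = config.soi_sd * state[0]
        nino_vals[key] = config.nino_sd * state[1]
    soi = MonthlySeries("SOI", soi_vals)
    nino34 = MonthlySeries("NINO34", nino_vals)

    # -- sub-regional rainfall with wet-season SOI coupling ----------------
    rng = _rng(seed, 2)
    rainfall = {}
    for entry in registry:
        vals = {}
        for (y, m) in months:
            wet = WET_WEIGHT.get(m, 0.0)
            mean = config.rain_dry_mean + wet * (config.rain_wet_mean - config.rain_dry_mean)
            coupling = wet * config.rain_soi_coupling * (soi_vals[(y, m)] / config.soi_sd)
            vals[(y, m)] = max(0.0, mean + coupling + config.rain_noise_sd * rng.standard_normal())
        rainfall[entry.name] = MonthlySeries("rainfall", vals, subregion=entry.name)

    # -- cyclone seasons ---------------------------------------------------
    rng = _rng(seed, 3)
    seasonal = pd.Series(
        {y: np.mean([soi_vals[(y - 1, 11)], soi_vals[(y - 1, 12)],
                     soi_vals[(y, 1)], soi_vals[(y, 2)]]) for y in years}
    )
    phase = classify_enso_seasons(seasonal)
    base = config.cyclone_base_rate
    mult = config.la_nina_multiplier
    rate_by_phase = {"la_nina": base * mult, "el_nino": base,
                     "neutral": base * 0.5 * (1 + mult)}
    entries = list(registry)
    tracks: list[CycloneTrack] = []
    storm_no = 0
    for year in years:
        count = rng.poisson(rate_by_phase[str(phase.loc[year])])
        for _ in range(count):
            storm_no += 1
            target = entries[rng.integers(len(entries))]
            verts = np.asarray(target.coastline)
            lat0, lon0 = verts[rng.integers(len(verts))]
            if rng.random() < config.miss_probability:
                lon_off = 6.5 + 4.0 * rng.random()      # well beyond the 5-deg radius
            else:
                lon_off = 0.5 + 3.0 * rng.random()      # coastal passage
            start = np.array([lat0 + rng.uniform(1.0, 3.0), lon0 + lon_off])
            heading = np.array([-rng.uniform(0.5, 1.5), -rng.uniform(0.0, 0.8)])
            day0 = pd.Timestamp(year=year, month=1, day=int(rng.integers(5, 25)))
            fixes = []
            pos = start.copy()
            for k in range(5):
                fixes.append((day0 + pd.Timedelta(hours=12 * k), float(pos[0]), float(pos[1])))
                pos = pos + heading + 0.3 * rng.standard_normal(2)
            tracks.append(
                CycloneTrack(f"SYN{storm_no:04d}", str(year), tuple(fixes))
            )

    tc = cyclone_counts(tracks, registry)
    covariates = build_covariate_table(rainfall, soi, nino34, tc, years,
                                       baseline_years=baseline_years)
    return rainfall, soi, nino34, tracks, covariates


def simulate_surveys(
    config: ScenarioConfig,
    covariates: CovariateTable,
    seed: int = 0,
    lags=(1, 2, 3, 4),
    drivers=None,
    registry: SubregionRegistry | None = None,
):
    """Draw calf counts from the trend model with planted driver effects.

    Returns ``(surveys, design, basis, truth)``: the survey table with
    simulated counts, the standardized lagged design actually used, the
    spline basis the true curve was built on, and the ground-truth record.
    """
    registry = registry or default_registry()
    rng = _rng(seed, 4)
    rows = []
    for name, yrs in config.survey_design.items():
        for year in yrs:
            n = max(1, int(round(config.count_median
                                 * np.exp(config.count_log_sd * rng.standard_normal()))))
            rows.append({"subregion": name, "year": int(year),
                         "season": "spring_summer", "total": n, "calves": 0})
    skeleton = SurveyTable(pd.DataFrame(rows))
    from .climate import DRIVERS
    design = build_lagged_design(covariates, skeleton, lags=lags,
                                 drivers=drivers or DRIVERS)
    basis = build_spline_basis(skeleton.time_values, n_knots=config.n_knots)

    levels_present = sorted(set(skeleton.subregions),
                            key=lambda nm: registry.index_of(nm))
    t = skeleton.time_values
    Z = basis.penalized
    r = np.asarray(config.r, dtype=float)[: config.n_knots]
    eta = config.beta0 + config.beta1 * t + Z @ r
    lvl = np.array(skeleton.subregions)
    for i, name in enumerate(levels_present[1:]):
        mask = lvl == name
        g0 = config.gamma0[i] if i < len(config.gamma0) else 0.0
        g1 = config.gamma1[i] if i < len(config.gamma1) else 0.0
        sl = np.asarray(config.s[i * config.n_knots:(i + 1) * config.n_knots])
        if len(sl) < config.n_knots:
            sl = np.zeros(config.n_knots)
        eta = eta + mask * (g0 + g1 * t + Z @ sl)
    for (driver, lag, name), coef in config.term_effects.items():
        col = f"{driver}_lag{lag}"
        if col not in design.frame.columns:
            raise KeyError(f"planted effect on unknown design column {col}")
        eta = eta + coef * (lvl == name) * design.frame[col].to_numpy()

    pi = expit(eta)
    n_arr = skeleton.totals
    if config.theta >= 1e5:       # effectively Binomial
        y = rng.binomial(n_arr, pi)
    else:
        p = rng.beta(config.theta * pi, config.theta * (1.0 - pi))
        y = rng.binomial(n_arr, p)
    frame = skeleton.frame[["subregion", "year", "season", "total"]].copy()
    frame["calves"] = y
    surveys = SurveyTable(frame[["subregion", "year", "season", "total", "calves"]])

    truth = {
        "beta0": config.beta0,
        "beta1": config.beta1,
        "r": list(r),
        "gamma0": list(config.gamma0[: len(levels_present) - 1]),
        "gamma1": list(config.gamma1[: len(levels_present) - 1]),
        "s": list(config.s[: (len(levels_present) - 1) * config.n_knots]),
        "theta": config.theta,
        "term_effects": {
            f"{name}:{driver}_lag{lag}": coef
            for (driver, lag, name), coef in config.term_effects.items()
        },
        "subregion_levels": levels_present,
        "seed": int(seed),
    }
    return surveys, design, basis, truth


FIXTURE_NAMES = ("null_effects", "single_strong_term", "table1_design_trend", "tiny_toy")

#: the planted term of the single_strong_term fixture
PLANTED_TERM = ("SOI", 2, "southern_gbr")


def make_fixture(name: str, seed: int = 0) -> FixtureBundle:
    """Build a named scenario bundle with its ground-truth record.

    ``table1_design_trend``
        The full 44-record five-sub-region design with a smooth trend,
        sub-regional deviations and no driver effects.
    ``single_strong_term``
        Same design with a flat trend and exactly one planted effect:
        SOI at lag 2 in the Southern GBR, standardized coefficient -1.
    ``null_effects``
        One sub-region (Southern GBR years), flat trend, 16 candidate
        terms, all true effects zero.
    ``tiny_toy``
        One sub-region, 12 records, 3 candidate rainfall-lag terms, trend
        fixed at a known intercept and precision so the posterior over
        (terms, indicators) is exactly enumerable.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    flat = dict(beta1=0.0, r=(0.0, 0.0, 0.0), gamma0=(0.0,) * 4,
                gamma1=(0.0,) * 4, s=(0.0,) * 12)
    drivers = None
    if name == "table1_design_trend":
        config = ScenarioConfig()
        lags = (1, 2, 3, 4)
    elif name == "single_strong_term":
        config = ScenarioConfig(term_effects={PLANTED_TERM: -1.0}, **flat)
        lags = (1, 2, 3, 4)
    elif name == "null_effects":
        config = ScenarioConfig(
            survey_design={"southern_gbr": table1_survey_years()["southern_gbr"]},
            **flat,
        )
        lags = (1, 2, 3, 4)
    else:  # tiny_toy
        config = ScenarioConfig(
            survey_design={"southern_gbr": table1_survey_years()["southern_gbr"]},
            term_effects={("rain_anom", 1, "southern_gbr"): -0.8},
            **flat,
        )
        lags = (1, 2, 3)
        drivers = ("rain_anom",)

    design_years = sorted({y for ys in config.survey_design.values() for y in ys})
    cov_years = range(design_years[0] - max(lags), design_years[-1] + 1)
    registry = default_registry()
    rainfall, soi, nino, tracks, covariates = simulate_climate(
        config, cov_years, seed=seed, registry=registry
    )
    surveys, design, basis, truth = simulate_surveys(
        config, covariates, seed=seed, lags=lags, drivers=drivers, registry=registry
    )
    truth["fixture"] = name
    if name == "tiny_toy":
        truth["fixed_intercept"] = config.beta0
        truth["fixed_theta"] = config.theta
    return FixtureBundle(
        name=name, surveys=surveys, covariates=covariates, design=design,
        basis=basis, tracks=tracks, registry=registry, truth=truth, config=config,
    )
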