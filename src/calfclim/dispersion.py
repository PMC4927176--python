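"""Exploratory screening: overdispersion and zero-inflation vs a null Binomial.

Survey calf counts routinely vary more than a Binomial with a common
proportion allows, which is what motivates the Beta-Binomial observation
model.  This module makes that screening reproducible: a Pearson
dispersion ratio compared against its parametric-bootstrap null
distribution (one-sided test at alpha = 0.05), and a zero-inflation check
comparing the observed fraction of zero-calf surveys with the fraction
expected under the fitted null Binomial.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .surveys import SurveyTable

__all__ = [
    "DispersionReport",
    "NoDataError",
    "fit_null_binomial",
    "pearson_dispersion_ratio",
    "overdispersion_statistic",
    "expected_zero_fraction",
    "zero_inflation_check",
    "check_dispersion",
]


class NoDataError(ValueError):
    """Not enough usable records (total_count > 0) for the check."""


@dataclass(frozen=True)
class DispersionReport:
    """Outcome of the exploratory screening on one survey table."""

    pooled_proportion: float
    pearson_ratio: float
    overdispersion_pvalue: float
    overdispersed: bool
    observed_zero_fraction: float
    expected_zero_fraction: float
    zero_inflation_threshold: float
    zero_inflated: bool
    n_records: int
    n_bootstrap: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _usable(surveys: SurveyTable) -> tuple[np.ndarray, np.ndarray]:
    y = surveys.calves
    n = surveys.totals
    keep = n > 0
    return y[keep], n[keep]


def fit_null_binomial(surveys: SurveyTable) -> float:
    """Intercept-only Binomial MLE of the calf proportion: sum(y) / sum(n)."""
    y, n = _usable(surveys)
    if len(n) < 2:
        raise NoDataError(
            f"need >= 2 records with positive totals, got {len(n)}"
        )
    return float(y.sum() / n.sum())


def pearson_dispersion_ratio(y: np.ndarray, n: np.ndarray, p0: float) -> float:
    """Pearson chi-square of y_i against Binomial(n_i, p0), divided by df = N-1."""
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"degenerate pooled proportion {p0}")
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    chi2 = np.sum((y - n * p0) ** 2 / (n * p0 * (1.0 - p0)))
    return float(chi2 / (len(y) - 1))


def overdispersion_statistic(
    surveys: SurveyTable,
    p0: float | None = None,
    n_bootstrap: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, bool]:
    """Pearson ratio, bootstrap p-value, and the overdispersion flag.

    The null distribution of the ratio is obtained by simulating
    ``n_bootstrap`` tables from Binomial(n_i, p0) and recomputing the ratio
    at each table's own pooled estimate; the flag fires when the observed
    ratio exceeds the upper ``alpha`` tail.
    """
    y, n = _usable(surveys)
    if len(n) < 2:
        raise NoDataError("need >= 2 usable records")
    if p0 is None:
        p0 = fit_null_binomial(surveys)
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"degenerate pooled proportion {p0}")
    ratio = pearson_dispersion_ratio(y, n, p0)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ysim = rng.binomial(n[None, :], p0, size=(n_bootstrap, len(n)))
    psim = ysim.sum(axis=1) / n.sum()
    psim = np.clip(psim, 1e-12, 1 - 1e-12)
    chi2 = ((ysim - n[None, :] * psim[:, None]) ** 2
            / (n[None, :] * psim[:, None] * (1 - psim[:, None]))).sum(axis=1)
    null_ratio = chi2 / (len(n) - 1)
    pvalue = float((1 + np.sum(null_ratio >= ratio)) / (1 + n_bootstrap))
    return ratio, pvalue, bool(pvalue < alpha)


def expected_zero_fraction(n: np.ndarray, p0: float) -> float:
    """Mean over records of P(y = 0 | Binomial(n_i, p0)) = (1 - p0)^n_i."""
    n = np.asarray(n, dtype=float)
    return float(np.mean((1.0 - p0) ** n))


def zero_inflation_check(
    surveys: SurveyTable,
    p0: float | None = None,
    n_bootstrap: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float, bool]:
    """Observed vs expected zero fractions and the zero-inflation flag.

    Returns (observed, expected, threshold, flagged): the flag fires when
    the observed zero fraction exceeds the upper (1 - alpha) bootstrap
    quantile of zero fractions simulated under the null Binomial.
    """
    y, n = _usable(surveys)
    if len(n) < 2:
        raise NoDataError("need >= 2 usable records")
    if p0 is None:
        p0 = fit_null_binomial(surveys)
    observed = float(np.mean(y == 0))
    expected = expected_zero_fraction(n, p0)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ysim = rng.binomial(n[None, :], p0, size=(n_bootstrap, len(n)))
    null_zero = np.mean(ysim == 0, axis=1)
    threshold = float(np.quantile(null_zero, 1.0 - alpha))
    return observed, expected, threshold, bool(observed > threshold)


def check_dispersion(
    surveys: SurveyTable,
    n_bootstrap: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> DispersionReport:
    """Run both screenings and bundle the outcome."""
    rng = np.random.default_rng(seed)
    p0 = fit_null_binomial(surveys)
    ratio, pvalue, over = overdispersion_statistic(
        surveys, p0, n_bootstrap=n_bootstrap, alpha=alpha, seed=rng
    )
    observed, expected, threshold, inflated = zero_inflation_check(
        surveys, p0, n_bootstrap=n_bootstrap, alpha=alpha, seed=rng
    )
    y, n = _usable(surveys)
    return DispersionReport(
        pooled_proportion=p0,
        pearson_ratio=ratio,
        overdispersion_pvalue=pvalue,
        overdispersed=over,
        observed_zero_fraction=observed,
        expected_zero_fraction=expected,
        zero_inflation_threshold=threshold,
        zero_inflated=inflated,
        n_records=len(n),
        n_bootstrap=n_bootstrap,
    )
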