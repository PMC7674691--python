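"""Monte Carlo propagation of parameter uncertainty into retention curves.

``propagate`` draws Latin-hypercube parameter sets once and solves one full
retention curve per set (coherent trajectories), so per-time distributions,
percentile bands and the time-dependent geometric standard deviation GSD(t)
all come from the same ensemble.  Scattering factors summarize GSD(t) as a
single early value (mean over hours 1-10) and a plateau value (mean over
48 h to the grid horizon), the form in which they enter maximum-likelihood
bioassay fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .biokinetics import (
    IntakeScenario,
    RadionuclideSpec,
    Route,
    _as_scenario,
    build_system,
    iodine_131,
    reference_parameters,
    sampled_parameters,
)
from .distributions import fit_lognormal
from .errors import InsufficientGridError, InvalidParameterError
from .solver import RetentionCurve, default_time_grid_h, thyroid_retention

__all__ = [
    "RetentionEnsemble",
    "RetentionSummary",
    "ScatteringFactors",
    "ScatteringFactorTable",
    "propagate",
    "summarize_ensemble",
    "extract_scattering_factors",
    "percentile_of_value",
    "convergence_check",
    "mean_relative_standard_error",
    "scattering_factor_table",
    "reference_retention",
    "DEFAULT_SAMPLES",
    "MIN_SAMPLES",
]

logger = logging.getLogger(__name__)

#: Monte Carlo sample count at which the mean standard error of the ensemble
#: mean falls below 2%.
DEFAULT_SAMPLES = 1000
#: Minimum ensemble size accepted for summarization.
MIN_SAMPLES = 100


@dataclass(frozen=True)
class RetentionEnsemble:
    """Monte Carlo ensemble of retention curves (n samples x time points)."""

    scenario: IntakeScenario
    times_h: np.ndarray
    values: np.ndarray
    seed: int | None
    n: int

    def at(self, t_h: float) -> np.ndarray:
        """Sample values at one time, interpolated between grid points."""
        t = float(t_h)
        if t < self.times_h[0] or t > self.times_h[-1]:
            raise InvalidParameterError("time outside the ensemble grid")
        hi = int(np.searchsorted(self.times_h, t, side="left"))
        if self.times_h[hi] == t:
            return self.values[:, hi]
        lo = hi - 1
        f = (t - self.times_h[lo]) / (self.times_h[hi] - self.times_h[lo])
        return (1 - f) * self.values[:, lo] + f * self.values[:, hi]


@dataclass(frozen=True)
class RetentionSummary:
    """Per-time log-normal fits and empirical percentile bands."""

    scenario: IntakeScenario
    times_h: np.ndarray
    gm: np.ndarray
    gsd: np.ndarray
    r_squared: np.ndarray
    p05: np.ndarray
    p50: np.ndarray
    p95: np.ndarray
    _values: np.ndarray | None = None

    def percentile(self, q: float) -> np.ndarray:
        """Arbitrary empirical percentile band (linear order-statistic
        interpolation), from the ensemble this summary was built from."""
        if self._values is None:
            raise InvalidParameterError("summary does not carry its ensemble")
        return np.percentile(self._values, q, axis=0)


@dataclass(frozen=True)
class ScatteringFactors:
    """Suggested scattering factors for one intake scenario.

    ``sf_before_24h`` is the mean GSD over hours 1-10 (thyroid measurements
    after an incident are typically attempted as early as possible);
    ``sf_after_24h`` is the plateau GSD once uptake is complete.
    """

    sf_before_24h: float
    sf_after_24h: float

    def rounded(self, step: float = 0.05) -> "ScatteringFactors":
        return ScatteringFactors(
            sf_before_24h=round(self.sf_before_24h / step) * step,
            sf_after_24h=round(self.sf_after_24h / step) * step,
        )


#: Scenario -> ScatteringFactors mapping (one row per intake route).
ScatteringFactorTable = Mapping[str, ScatteringFactors]


def propagate(
    scenario: IntakeScenario | Route | str,
    n: int = DEFAULT_SAMPLES,
    seed: int | None = 42,
    times_h=None,
    nuclide: RadionuclideSpec | None = None,
    config: dict | None = None,
) -> RetentionEnsemble:
    """Propagate the parameter distributions into an ensemble of curves.

    Draws ``n`` Latin-hypercube parameter sets, builds one compartment
    system per set and solves the full retention curve for each.
    """
    if n < MIN_SAMPLES:
        raise InvalidParameterError(
            f"ensemble size must be >= {MIN_SAMPLES} for summarization, got {n}"
        )
    scenario = _as_scenario(scenario)
    times_h = default_time_grid_h() if times_h is None else np.asarray(times_h, dtype=float)
    nuclide = nuclide or iodine_131()
    triples = sampled_parameters(scenario, n, seed=seed, config=config)
    values = np.empty((n, times_h.size))
    for i, triple in enumerate(triples):
        system = build_system(scenario, triple, nuclide)
        values[i] = thyroid_retention(system, times_h).values
    logger.info("propagated %s: n=%d, seed=%s, %d time points",
                scenario.route.value, n, seed, times_h.size)
    return RetentionEnsemble(
        scenario=scenario, times_h=times_h, values=values,
        seed=seed if isinstance(seed, int) else None, n=n,
    )


def summarize_ensemble(ensemble: RetentionEnsemble) -> RetentionSummary:
    """Per-time log-normal fit plus empirical 5/50/95 percentile bands.

    Time points with non-positive samples are summarized on the positive
    subset (with a logged warning); the percentiles always use all samples.
    """
    if ensemble.n < MIN_SAMPLES:
        raise InvalidParameterError(f"need at least {MIN_SAMPLES} samples, got {ensemble.n}")
    T = ensemble.times_h.size
    gm = np.empty(T)
    gsd = np.empty(T)
    r2 = np.empty(T)
    for k in range(T):
        col = ensemble.values[:, k]
        positive = col[col > 0]
        if positive.size < col.size:
            logger.warning(
                "t=%.1f h: %d non-positive samples excluded from log-normal fit",
                ensemble.times_h[k], col.size - positive.size,
            )
        fit = fit_lognormal(positive)
        gm[k], gsd[k], r2[k] = fit.gm, fit.gsd, fit.r_squared
    p05, p50, p95 = np.percentile(ensemble.values, [5, 50, 95], axis=0)
    return RetentionSummary(
        scenario=ensemble.scenario, times_h=ensemble.times_h.copy(),
        gm=gm, gsd=gsd, r_squared=r2, p05=p05, p50=p50, p95=p95,
        _values=ensemble.values,
    )


def extract_scattering_factors(
    summary: RetentionSummary,
    early_window_h: tuple[float, float] = (1.0, 10.0),
    plateau_window_h: tuple[float, float] = (48.0, 720.0),
) -> ScatteringFactors:
    """Scattering factors from the time-dependent GSD curve.

    The early value averages GSD(t) over ``early_window_h`` (default hours
    1-10 inclusive); the plateau value averages over ``plateau_window_h``
    (default 48 h to 30 d), the region where GSD(t) has reached its minimum
    and no longer changes.
    """
    t = summary.times_h
    early = (t >= early_window_h[0]) & (t <= early_window_h[1])
    plateau = (t >= plateau_window_h[0]) & (t <= plateau_window_h[1])
    if not np.any(early) or t[0] > early_window_h[0]:
        raise InsufficientGridError(
            f"grid does not cover the early window {early_window_h} h"
        )
    if not np.any(plateau):
        raise InsufficientGridError(
            f"grid does not cover the plateau window {plateau_window_h} h"
        )
    return ScatteringFactors(
        sf_before_24h=float(summary.gsd[early].mean()),
        sf_after_24h=float(summary.gsd[plateau].mean()),
    )


def percentile_of_value(ensemble: RetentionEnsemble, t_h: float, value: float) -> float:
    """Empirical percentile rank of ``value`` within the ensemble at ``t_h``.

    Off-grid times use linearly interpolated sample trajectories.
    """
    if value <= 0:
        raise InvalidParameterError("value must be > 0")
    samples = ensemble.at(t_h)
    return float(np.mean(samples <= value) * 100.0)


def mean_relative_standard_error(ensemble: RetentionEnsemble) -> float:
    """Mean over time of sd/(mean * sqrt(n)), in percent.

    The Monte Carlo standard error of the ensemble mean, expressed relative
    to that mean, averaged over all time points.
    """
    mean = ensemble.values.mean(axis=0)
    sd = ensemble.values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rse = np.where(mean > 0, sd / (mean * np.sqrt(ensemble.n)), 0.0)
    return float(rse.mean() * 100.0)


def convergence_check(
    scenario: IntakeScenario | Route | str,
    n: int = DEFAULT_SAMPLES,
    seed: int | None = 42,
    times_h=None,
    config: dict | None = None,
) -> float:
    """Mean relative standard error (%) of a freshly propagated ensemble."""
    ensemble = propagate(scenario, n=n, seed=seed, times_h=times_h, config=config)
    return mean_relative_standard_error(ensemble)


def scattering_factor_table(
    routes=None,
    n: int = DEFAULT_SAMPLES,
    seed: int | None = 42,
    config: dict | None = None,
) -> dict[str, ScatteringFactors]:
    """Scattering factors for several routes (defaults to all five)."""
    routes = list(Route) if routes is None else [Route(r) for r in routes]
    table: dict[str, ScatteringFactors] = {}
    for route in routes:
        ensemble = propagate(route, n=n, seed=seed, config=config)
        table[route.value] = extract_scattering_factors(summarize_ensemble(ensemble))
    return table


def reference_retention(
    scenario: IntakeScenario | Route | str,
    times_h=None,
    nuclide: RadionuclideSpec | None = None,
    config: dict | None = None,
) -> RetentionCurve:
    """Retention curve at the deterministic reference parameter set."""
    scenario = _as_scenario(scenario)
    params = reference_parameters(scenario, config=config)
    system = build_system(scenario, params, nuclide or iodine_131())
    return thyroid_retention(system, times_h)
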