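"""Parameter uncertainty distributions and Latin hypercube sampling.

Biokinetic parameter uncertainties are described by normal, log-normal or
triangular distributions (or fixed point values).  Log-normal spreads are
expressed as geometric standard deviations (GSD); literature "uncertainty
factors" (UF), which give the multiplicative half-width of a one-sided 95%
confidence interval around the geometric mean, are converted to GSDs via
``gsd = exp(ln(UF) / z_0.95)``.

Monte Carlo samples are drawn by Latin hypercube sampling (LHS): for each
parameter the unit interval is split into ``n`` equal-probability strata,
one draw is taken per stratum at a uniformly random position within it, and
the strata are independently permuted across parameters so the pairing
between parameters is random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidDataError, InvalidParameterError

__all__ = [
    "DistributionSpec",
    "UncertaintyFactor",
    "LognormalFit",
    "uf_to_gsd",
    "gsd_to_uf",
    "quantile",
    "sample_lhs",
    "fit_lognormal",
    "ONE_SIDED_95_Z",
]

#: Standard-normal quantile for a one-sided 95% confidence limit.  Literature
#: uncertainty factors span GM x/ UF at this confidence level; using 1.645
#: reproduces the conventional UF 2 -> GSD 1.52 and UF 1.5 -> GSD 1.28
#: conversions.
ONE_SIDED_95_Z = 1.645


@dataclass(frozen=True)
class DistributionSpec:
    """One parameter's uncertainty model.

    Use the class-method constructors (:meth:`normal`, :meth:`lognormal`,
    :meth:`triangular`, :meth:`fixed`) rather than the raw constructor; they
    validate the defining constants.

    Attributes
    ----------
    kind:
        One of ``"normal"``, ``"lognormal"``, ``"triangular"``, ``"fixed"``.
    a, b, c:
        Family constants: (mean, sd) for normal; (gm, gsd) for log-normal;
        (min, mode, max) for triangular; (value,) for fixed.
    """

    kind: str
    a: float
    b: float = float("nan")
    c: float = float("nan")

    @classmethod
    def normal(cls, mean: float, sd: float) -> "DistributionSpec":
        if sd <= 0:
            raise InvalidParameterError(f"normal sd must be > 0, got {sd}")
        return cls("normal", float(mean), float(sd))

    @classmethod
    def lognormal(cls, gm: float, gsd: float) -> "DistributionSpec":
        if gm <= 0:
            raise InvalidParameterError(f"lognormal gm must be > 0, got {gm}")
        if gsd < 1:
            raise InvalidParameterError(f"lognormal gsd must be >= 1, got {gsd}")
        return cls("lognormal", float(gm), float(gsd))

    @classmethod
    def triangular(cls, lo: float, mode: float, hi: float) -> "DistributionSpec":
        if not (lo <= mode <= hi):
            raise InvalidParameterError(
                f"triangular requires min <= mode <= max, got ({lo}, {mode}, {hi})"
            )
        return cls("triangular", float(lo), float(mode), float(hi))

    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls("fixed", float(value))

    # -- convenience accessors ------------------------------------------------
    @property
    def gm(self) -> float:
        if self.kind != "lognormal":
            raise AttributeError("gm is defined for lognormal specs only")
        return self.a

    @property
    def gsd(self) -> float:
        if self.kind != "lognormal":
            raise AttributeError("gsd is defined for lognormal specs only")
        return self.b

    def central(self) -> float:
        """Deterministic central value (mean / GM / mode / value)."""
        if self.kind == "triangular":
            return self.b
        return self.a

    def ppf(self, p):
        """Inverse CDF; see :func:`quantile`."""
        return quantile(self, p)


@dataclass(frozen=True)
class UncertaintyFactor:
    """Multiplicative uncertainty factor around a geometric mean.

    ``uf`` spans the one-sided 95% confidence limit: the GM is multiplied or
    divided by ``uf`` to reach the 95% bound.
    """

    uf: float

    def __post_init__(self) -> None:
        if self.uf < 1:
            raise InvalidParameterError(f"uncertainty factor must be >= 1, got {self.uf}")


@dataclass(frozen=True)
class LognormalFit:
    """Log-normal summary of a positive sample.

    ``r_squared`` is the squared Pearson correlation of the probability plot
    (sorted log samples against matching standard-normal quantiles), i.e. how
    well a straight line — a log-normal — describes the sample.
    """

    gm: float
    gsd: float
    r_squared: float

    def quantile(self, p: float) -> float:
        return self.gm * self.gsd ** stats.norm.ppf(p)


def uf_to_gsd(uf: UncertaintyFactor | float) -> float:
    """Convert an uncertainty factor to a geometric standard deviation.

    ``gsd = exp(ln(uf) / 1.645)``: the UF spans the one-sided 95% limit, the
    GSD spans one geometric standard deviation.

    >>> round(uf_to_gsd(2.0), 2)
    1.52
    """
    value = uf.uf if isinstance(uf, UncertaintyFactor) else float(uf)
    if value < 1:
        raise InvalidParameterError(f"uncertainty factor must be >= 1, got {value}")
    return math.exp(math.log(value) / ONE_SIDED_95_Z)


def gsd_to_uf(gsd: float) -> float:
    """Inverse of :func:`uf_to_gsd`."""
    if gsd < 1:
        raise InvalidParameterError(f"gsd must be >= 1, got {gsd}")
    return math.exp(math.log(gsd) * ONE_SIDED_95_Z)


def _frozen(spec: DistributionSpec):
    """scipy frozen distribution for a (non-fixed) spec."""
    if spec.kind == "normal":
        return stats.norm(loc=spec.a, scale=spec.b)
    if spec.kind == "lognormal":
        return stats.lognorm(s=math.log(spec.b), scale=spec.a)
    if spec.kind == "triangular":
        lo, mode, hi = spec.a, spec.b, spec.c
        if hi == lo:
            return None  # degenerate point mass
        return stats.triang(c=(mode - lo) / (hi - lo), loc=lo, scale=hi - lo)
    raise InvalidParameterError(f"unknown distribution kind {spec.kind!r}")


def quantile(spec: DistributionSpec, p):
    """Exact inverse CDF of ``spec`` at probability ``p`` (scalar or array).

    For a log-normal this is ``gm * gsd ** z(p)`` with ``z`` the standard
    normal quantile.
    """
    parr = np.asarray(p, dtype=float)
    if np.any((parr <= 0) | (parr >= 1)):
        raise InvalidParameterError("probability must lie strictly in (0, 1)")
    if spec.kind == "fixed":
        out = np.full_like(parr, spec.a)
        return float(out) if np.isscalar(p) else out
    frozen = _frozen(spec)
    if frozen is None:  # degenerate triangular
        out = np.full_like(parr, spec.a)
        return float(out) if np.isscalar(p) else out
    out = frozen.ppf(parr)
    # lognorm.ppf with gsd == 1 collapses to the GM
    if spec.kind == "lognormal" and spec.b == 1.0:
        out = np.full_like(parr, spec.a)
    return float(out) if np.isscalar(p) else out


def sample_lhs(
    specs: Sequence[DistributionSpec],
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` Latin-hypercube samples of the given parameters.

    Returns an ``(n, len(specs))`` array.  For each parameter exactly one
    sample falls in each of the ``n`` equal-probability strata of its marginal
    CDF; the stratum order is permuted independently per parameter, and the
    position within each stratum is uniformly random (not the midpoint), so
    distribution tails are represented.

    ``seed`` may be an integer or a ``numpy.random.Generator`` (which is
    advanced in place, allowing several LHS blocks to share one stream).
    """
    if n < 1:
        raise InvalidParameterError(f"sample count must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(specs)
    out = np.empty((n, k), dtype=float)
    for j, spec in enumerate(specs):
        strata = rng.permutation(n)
        u = (strata + rng.uniform(size=n)) / n
        out[:, j] = quantile(spec, u)
    return out


def fit_lognormal(samples: Iterable[float]) -> LognormalFit:
    """Fit a log-normal summary (GM, GSD, probability-plot R^2) to a sample.

    GM and GSD are the moment estimates on the log scale; R^2 comes from the
    Q-Q (probability-plot) regression of sorted log samples against matching
    standard-normal plotting positions.  A degenerate (constant) sample has
    GSD 1 and, by convention, R^2 = 1.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 10:
        raise InsufficientDataError(f"need at least 10 samples, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise InvalidDataError("log-normal fit requires finite positive samples")
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    sd = float(logs.std(ddof=1))
    if sd <= 1e-14 * max(1.0, abs(float(logs.mean()))):
        # constant sample: point mass, perfectly "log-normal" by convention
        return LognormalFit(gm=gm, gsd=1.0, r_squared=1.0)
    (osm, osr), (_, _, r) = stats.probplot(logs, dist="norm", fit=True)
    return LognormalFit(gm=gm, gsd=float(np.exp(sd)), r_squared=float(r**2))
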