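"""ICRP biokinetic models for iodine and compartment-system assembly.

Three model blocks are combined depending on the intake route:

* the ICRP 66 human respiratory tract model (HRTM) for inhalation —
  regional deposition (ET1, ET2, BB, bb, AI), mechanical particle transport,
  and fast (F-type) dissolution to blood;
* the ICRP 100 human alimentary tract model (HATM) for ingested and
  swallowed material — oral cavity, oesophagus (fast/slow), stomach, small
  intestine (where the fraction ``f1`` is absorbed to blood), and colon;
* the ICRP 67 three-compartment systemic model — blood, thyroid and
  rest-of-body, with urinary and faecal loss and recycling to blood.

Everything is expressed as a first-order transfer-rate matrix ``A`` (d^-1)
with physical decay on the diagonal, so the activity vector evolves as
``q(t) = expm(A t) q(0)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import load_config, parse_distribution
from .distributions import DistributionSpec, sample_lhs
from .errors import InvalidParameterError, InvalidScenarioError

__all__ = [
    "Route",
    "IntakeScenario",
    "HRTMParameters",
    "HATMParameters",
    "SystemicParameters",
    "RadionuclideSpec",
    "CompartmentSystem",
    "ParameterSet",
    "reference_parameters",
    "sampled_parameters",
    "build_system",
    "iodine_131",
    "ROUTES",
]

LN2 = math.log(2.0)


class Route(str, enum.Enum):
    """Intake routes covered by the uncertainty analysis."""

    AEROSOL_5UM = "aerosol-5um"
    AEROSOL_1UM = "aerosol-1um"
    VAPOR_ELEMENTAL = "vapor-elemental"
    VAPOR_ORGANIC = "vapor-organic"
    INGESTION = "ingestion"


ROUTES = tuple(Route)

_AEROSOL_ROUTES = (Route.AEROSOL_5UM, Route.AEROSOL_1UM)
_INHALATION_ROUTES = _AEROSOL_ROUTES + (Route.VAPOR_ELEMENTAL, Route.VAPOR_ORGANIC)

#: config key per route for the deposition table
_DEPOSITION_KEY = {
    Route.AEROSOL_5UM: "aerosol_5um",
    Route.AEROSOL_1UM: "aerosol_1um",
    Route.VAPOR_ELEMENTAL: "vapor_elemental",
    Route.VAPOR_ORGANIC: "vapor_organic",
}

_DEFAULT_INFO = {
    Route.AEROSOL_5UM: "5 um AMAD aerosol, F-type absorption",
    Route.AEROSOL_1UM: "1 um AMAD aerosol, F-type absorption",
    Route.VAPOR_ELEMENTAL: "SR-1 elemental/inorganic vapor, F-type, 100% deposition",
    Route.VAPOR_ORGANIC: "SR-1 organic vapor, V-type, 70% deposition",
    Route.INGESTION: "total-diet iodine, f1 = 1",
}


@dataclass(frozen=True)
class IntakeScenario:
    """An intake route with its default absorption behaviour.

    Aerosols and elemental vapor clear to blood with fast (F-type)
    dissolution; organic vapor (V-type) transfers its deposited fraction to
    blood effectively instantaneously; ingestion has no respiratory phase.
    """

    route: Route
    absorption_type: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        route = Route(self.route)
        object.__setattr__(self, "route", route)
        expected = None if route is Route.INGESTION else (
            "V" if route is Route.VAPOR_ORGANIC else "F"
        )
        atype = self.absorption_type or expected
        if atype != expected:
            raise InvalidScenarioError(
                f"route {route.value} requires absorption type {expected!r}, got {atype!r}"
            )
        object.__setattr__(self, "absorption_type", expected)
        if not self.description:
            object.__setattr__(self, "description", _DEFAULT_INFO[route])

    @classmethod
    def from_route(cls, route: "Route | str") -> "IntakeScenario":
        try:
            return cls(route=Route(route))
        except ValueError as exc:
            raise InvalidScenarioError(f"unknown intake route {route!r}") from exc

    @property
    def is_inhalation(self) -> bool:
        return self.route in _INHALATION_ROUTES


@dataclass(frozen=True)
class RadionuclideSpec:
    """A radionuclide and its physical half-life in days."""

    name: str
    half_life_d: float

    def __post_init__(self) -> None:
        if self.half_life_d <= 0:
            raise InvalidParameterError("physical half-life must be > 0")

    @property
    def decay_const_per_d(self) -> float:
        return LN2 / self.half_life_d


def iodine_131() -> RadionuclideSpec:
    return RadionuclideSpec(name="I-131", half_life_d=8.0252)


@dataclass(frozen=True)
class HRTMParameters:
    """Respiratory-tract deposition and clearance parameters.

    ``deposition`` maps region (ET1, ET2, BB, bb, AI) to the deposited
    fraction of intake.  For vapors the regional fractions are already
    renormalized (see :func:`reference_parameters` / :func:`sampled_parameters`)
    and AI is zero.  ``total_deposition`` is the deposited fraction of intake
    for vapors (1.0 for elemental, sampled around 0.70 for organic).
    """

    deposition: Mapping[str, float] = field(default_factory=dict)
    total_deposition: float = 1.0
    transport_rates_per_d: Mapping[str, float] = field(default_factory=dict)
    s_p_per_d: float = 100.0
    seq_fraction: float = 0.007
    et2_seq_fraction: float = 0.0005
    slow_fraction: float = 0.5
    ai_split: tuple[float, float, float] = (0.3, 0.6, 0.1)

    def validate(self, aerosol: bool) -> None:
        for region, frac in self.deposition.items():
            if not 0.0 <= frac <= 1.0:
                raise InvalidParameterError(f"deposition {region} = {frac} outside [0, 1]")
        total = sum(self.deposition.values())
        if aerosol and total > 1.0 + 1e-12:
            raise InvalidParameterError(f"aerosol deposition sums to {total} > 1")
        if not 0.0 <= self.total_deposition <= 1.0:
            raise InvalidParameterError("total_deposition outside [0, 1]")
        for name, rate in self.transport_rates_per_d.items():
            if rate < 0 or not np.isfinite(rate):
                raise InvalidParameterError(f"transport rate {name} = {rate} invalid")
        for name in ("seq_fraction", "et2_seq_fraction", "slow_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} = {v} outside [0, 1]")
        if abs(sum(self.ai_split) - 1.0) > 1e-9:
            raise InvalidParameterError("ai_split must sum to 1")


@dataclass(frozen=True)
class HATMParameters:
    """Alimentary-tract transfer rates (d^-1) and fractional absorption f1."""

    rates_per_d: Mapping[str, float]
    f1: float = 1.0

    def validate(self) -> None:
        for name, rate in self.rates_per_d.items():
            if rate <= 0 or not np.isfinite(rate):
                raise InvalidParameterError(f"HATM rate {name} = {rate} must be > 0")
        if not 0.0 <= self.f1 <= 1.0:
            raise InvalidParameterError(f"f1 = {self.f1} outside [0, 1]")


@dataclass(frozen=True)
class SystemicParameters:
    """Three-compartment systemic model parameters.

    ``f_blt`` is the thyroid uptake fraction of iodide leaving blood,
    ``f_bbl`` the fraction of rest-of-body loss recycled to blood, and the
    ``k_*`` values are biological half-times in days (blood, thyroid,
    rest of body).  Transfer rate = fraction x ln2 / half-time.
    """

    f_blt: float
    f_bbl: float
    k_t_d: float
    k_b_d: float
    k_bl_d: float

    def validate(self) -> None:
        if not 0.0 <= self.f_blt < 1.0:
            raise InvalidParameterError(f"f_blt = {self.f_blt} outside [0, 1)")
        if not 0.0 < self.f_bbl <= 1.0:
            raise InvalidParameterError(f"f_bbl = {self.f_bbl} outside (0, 1]")
        for name in ("k_t_d", "k_b_d", "k_bl_d"):
            v = getattr(self, name)
            if v <= 0 or not np.isfinite(v):
                raise InvalidParameterError(f"{name} = {v} must be > 0")


#: (HRTM, HATM, systemic) parameter triple for one model evaluation.
ParameterSet = tuple[HRTMParameters, HATMParameters, SystemicParameters]


# ---------------------------------------------------------------------------
# parameter assembly
# ---------------------------------------------------------------------------

_HATM_RATE_KEYS = (
    "oral_to_oesophagus_fast",
    "oral_to_oesophagus_slow",
    "oesophagus_fast_to_stomach",
    "oesophagus_slow_to_stomach",
    "stomach_to_si",
    "si_to_rc",
    "rc_to_lc",
    "lc_to_rs",
    "rs_to_faeces",
)

_SYSTEMIC_KEYS = ("f_blt", "f_bbl", "k_t_d", "k_b_d", "k_bl_d")


def _hrtm_fixed(config: dict) -> dict:
    """Central values of the HRTM clearance slots."""
    hrtm = config["hrtm"]
    return {
        "transport_rates_per_d": {
            k: parse_distribution(v).central() for k, v in hrtm["transport_rates_per_d"].items()
        },
        "s_p_per_d": parse_distribution(hrtm["s_p_per_d"]).central(),
        "seq_fraction": parse_distribution(hrtm["seq_fraction"]).central(),
        "et2_seq_fraction": parse_distribution(hrtm["et2_seq_fraction"]).central(),
        "slow_fraction": parse_distribution(hrtm["slow_fraction"]).central(),
        "ai_split": tuple(hrtm["ai_split"]),
    }


def _vapor_regional(dep: dict[str, float], total: float) -> dict[str, float]:
    """Renormalize vapor regional fractions to sum to ``total``; AI is zero."""
    s = sum(v for k, v in dep.items() if k != "AI")
    scaled = {region: frac * total / s for region, frac in dep.items() if region != "AI"}
    scaled["AI"] = 0.0
    return scaled


def _assemble_hrtm(
    scenario: IntakeScenario, dep: dict[str, float], total_dep: float, config: dict
) -> HRTMParameters:
    route = scenario.route
    if route in _AEROSOL_ROUTES:
        deposition = dict(dep)
        total = sum(deposition.values())
    elif route in (Route.VAPOR_ELEMENTAL, Route.VAPOR_ORGANIC):
        # regional fractions renormalized to sum to the (sampled) total
        # deposited fraction; AI uptake is negligible for vapors
        total = total_dep
        deposition = _vapor_regional(dep, total) if dep else {}
    else:  # ingestion: no respiratory phase
        deposition, total = {}, 0.0
    params = HRTMParameters(
        deposition=deposition, total_deposition=total, **_hrtm_fixed(config)
    )
    params.validate(aerosol=route in _AEROSOL_ROUTES)
    return params


def reference_parameters(
    scenario: IntakeScenario | Route | str, config: dict | None = None
) -> ParameterSet:
    """Deterministic reference parameter set for a scenario.

    Deposition and alimentary transit use the central values of the
    uncertainty tables; the systemic block uses the ICRP 67 reference values
    (uptake fraction 0.3, blood half-time 0.25 d, thyroid half-time 80 d,
    rest-of-body half-time 12 d, recycled fraction 0.8), which is the curve
    the published retention functions are based on.
    """
    scenario = _as_scenario(scenario)
    config = config or load_config()
    route = scenario.route
    if route is Route.INGESTION:
        dep: dict[str, float] = {}
    else:
        dep = {
            region: parse_distribution(entry).central()
            for region, entry in config["deposition"][_DEPOSITION_KEY[route]].items()
        }
    total_dep = 0.0
    if route in (Route.VAPOR_ELEMENTAL, Route.VAPOR_ORGANIC):
        total_dep = parse_distribution(config["total_deposition"][_DEPOSITION_KEY[route]]).central()
    hrtm = _assemble_hrtm(scenario, dep, total_dep, config)

    rates = {
        key: parse_distribution(config["hatm"]["rates"][key]).central()
        for key in _HATM_RATE_KEYS
    }
    hatm = HATMParameters(rates_per_d=rates, f1=float(config["hatm"]["f1_reference"]))
    hatm.validate()

    systemic = SystemicParameters(**{k: float(config["systemic"]["reference"][k]) for k in _SYSTEMIC_KEYS})
    systemic.validate()
    return hrtm, hatm, systemic


def sampled_parameters(
    scenario: IntakeScenario | Route | str,
    n: int,
    seed: int | np.random.Generator | None = None,
    config: dict | None = None,
) -> list[ParameterSet]:
    """Draw ``n`` Latin-hypercube parameter sets for a scenario.

    Samples the blocks that matter for the route: regional deposition for
    inhalation (total deposition for organic vapor), alimentary-tract rates
    and ``f1`` whenever material is ingested or swallowed, and the systemic
    parameters always.  Aerosol deposition vectors whose regional fractions
    are non-physical (negative, or summing above 1) are rejected and redrawn
    from the same marginals.
    """
    if n < 1:
        raise InvalidParameterError(f"sample count must be >= 1, got {n}")
    scenario = _as_scenario(scenario)
    config = config or load_config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    route = scenario.route

    spec_names: list[str] = []
    specs: list[DistributionSpec] = []

    dep_regions: list[str] = []
    if route in _AEROSOL_ROUTES or route is Route.VAPOR_ELEMENTAL:
        table = config["deposition"][_DEPOSITION_KEY[route]]
        for region, entry in table.items():
            dep_regions.append(region)
            spec_names.append(f"dep_{region}")
            specs.append(parse_distribution(entry))
    if route in (Route.VAPOR_ELEMENTAL, Route.VAPOR_ORGANIC):
        spec_names.append("total_deposition")
        specs.append(parse_distribution(config["total_deposition"][_DEPOSITION_KEY[route]]))

    uses_hatm = route is Route.INGESTION or (
        scenario.is_inhalation and route is not Route.VAPOR_ORGANIC
    )
    if uses_hatm:
        for key in _HATM_RATE_KEYS:
            spec_names.append(f"hatm_{key}")
            specs.append(parse_distribution(config["hatm"]["rates"][key]))
        spec_names.append("f1")
        specs.append(parse_distribution(config["hatm"]["f1"]))

    for key in _SYSTEMIC_KEYS:
        spec_names.append(key)
        specs.append(parse_distribution(config["systemic"]["distributions"][key]))

    matrix = sample_lhs(specs, n, rng)
    cols = {name: matrix[:, j] for j, name in enumerate(spec_names)}

    # Rejection steps: physically impossible draws are redrawn from the same
    # marginal.  The thyroid uptake fraction is a fraction, but its log-normal
    # has a small tail above 1 (~3e-4 probability mass).
    fblt_idx = spec_names.index("f_blt")
    fblt_spec = specs[fblt_idx]
    for row in range(n):
        while matrix[row, fblt_idx] >= 1.0:
            matrix[row, fblt_idx] = quantile_draw(fblt_spec, rng)

    # Rejection step for aerosol deposition vectors (whole vector redrawn).
    if dep_regions and route in _AEROSOL_ROUTES:
        dep_idx = [spec_names.index(f"dep_{r}") for r in dep_regions]
        dep_specs = [specs[i] for i in dep_idx]
        for row in range(n):
            vec = matrix[row, dep_idx]
            while np.any(vec < 0) or vec.sum() > 1.0:
                vec = np.array([quantile_draw(s, rng) for s in dep_specs])
            matrix[row, dep_idx] = vec

    out: list[ParameterSet] = []
    ref_hatm_rates = {
        key: parse_distribution(config["hatm"]["rates"][key]).central()
        for key in _HATM_RATE_KEYS
    }
    for row in range(n):
        dep = {region: float(cols[f"dep_{region}"][row]) for region in dep_regions}
        total_dep = float(cols["total_deposition"][row]) if "total_deposition" in cols else 0.0
        total_dep = min(total_dep, 1.0)
        hrtm = _assemble_hrtm(scenario, dep, total_dep, config)
        if uses_hatm:
            rates = {key: float(cols[f"hatm_{key}"][row]) for key in _HATM_RATE_KEYS}
            hatm = HATMParameters(rates_per_d=rates, f1=float(cols["f1"][row]))
        else:
            hatm = HATMParameters(rates_per_d=ref_hatm_rates, f1=float(config["hatm"]["f1_reference"]))
        hatm.validate()
        systemic = SystemicParameters(**{k: float(cols[k][row]) for k in _SYSTEMIC_KEYS})
        systemic.validate()
        out.append((hrtm, hatm, systemic))
    return out


def quantile_draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One plain Monte Carlo draw from a spec (used for rejection redraws)."""
    return float(spec.ppf(rng.uniform(low=np.nextafter(0.0, 1.0), high=np.nextafter(1.0, 0.0))))


def _as_scenario(scenario: IntakeScenario | Route | str) -> IntakeScenario:
    if isinstance(scenario, IntakeScenario):
        return scenario
    return IntakeScenario.from_route(scenario)


# ---------------------------------------------------------------------------
# compartment system
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompartmentSystem:
    """A first-order compartment system with physical decay.

    ``matrix`` is the full rate matrix ``A`` (d^-1) including decay: entry
    ``A[i, j]`` for ``i != j`` is the transfer rate from compartment ``j`` to
    ``i``; each diagonal entry is minus the sum of that column's outflows
    minus the decay constant.  Sink compartments (urine, faeces, environment,
    exhaled) are retained in the state so that total activity, corrected for
    decay, is conserved.
    """

    names: tuple[str, ...]
    matrix: np.ndarray
    initial: np.ndarray
    decay_const_per_d: float
    scenario: IntakeScenario | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.matrix.shape != (n, n) or self.initial.shape != (n,):
            raise InvalidParameterError("system dimensions are inconsistent")
        if abs(float(self.initial.sum()) - 1.0) > 1e-9:
            raise InvalidParameterError("initial condition must sum to 1")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError as exc:
            raise InvalidParameterError(f"no compartment named {name!r}") from exc

    @property
    def thyroid_index(self) -> int:
        return self.index("thyroid")


class _SystemBuilder:
    def __init__(self) -> None:
        self.names: list[str] = []
        self._idx: dict[str, int] = {}
        self._transfers: list[tuple[str, str, float]] = []
        self._initial: dict[str, float] = {}

    def compartment(self, name: str) -> None:
        if name not in self._idx:
            self._idx[name] = len(self.names)
            self.names.append(name)

    def transfer(self, src: str, dst: str, rate: float) -> None:
        if rate < 0:
            raise InvalidParameterError(f"negative transfer rate {src}->{dst}: {rate}")
        if rate == 0:
            return
        self.compartment(src)
        self.compartment(dst)
        self._transfers.append((src, dst, float(rate)))

    def deposit(self, name: str, fraction: float) -> None:
        if fraction < 0:
            raise InvalidParameterError(f"negative deposit in {name}: {fraction}")
        if fraction == 0:
            return
        self.compartment(name)
        self._initial[name] = self._initial.get(name, 0.0) + float(fraction)

    def build(
        self, decay_const_per_d: float, scenario: IntakeScenario | None
    ) -> CompartmentSystem:
        n = len(self.names)
        A = np.zeros((n, n))
        for src, dst, rate in self._transfers:
            i, j = self._idx[dst], self._idx[src]
            A[i, j] += rate
            A[j, j] -= rate
        A -= decay_const_per_d * np.eye(n)
        q0 = np.zeros(n)
        for name, frac in self._initial.items():
            q0[self._idx[name]] = frac
        return CompartmentSystem(
            names=tuple(self.names),
            matrix=A,
            initial=q0,
            decay_const_per_d=decay_const_per_d,
            scenario=scenario,
        )


def _add_systemic(b: _SystemBuilder, sp: SystemicParameters) -> None:
    blood_rate = LN2 / sp.k_bl_d
    b.transfer("blood", "thyroid", sp.f_blt * blood_rate)
    b.transfer("blood", "urine", (1.0 - sp.f_blt) * blood_rate)
    b.transfer("thyroid", "rest_of_body", LN2 / sp.k_t_d)
    body_rate = LN2 / sp.k_b_d
    b.transfer("rest_of_body", "blood", sp.f_bbl * body_rate)
    b.transfer("rest_of_body", "faeces", (1.0 - sp.f_bbl) * body_rate)
    for name in ("blood", "thyroid", "rest_of_body", "urine", "faeces"):
        b.compartment(name)


def _add_hatm(b: _SystemBuilder, hp: HATMParameters, include_oral: bool) -> None:
    r = hp.rates_per_d
    if include_oral:
        b.transfer("oral_cavity", "oesophagus_fast", r["oral_to_oesophagus_fast"])
        b.transfer("oral_cavity", "oesophagus_slow", r["oral_to_oesophagus_slow"])
    b.transfer("oesophagus_fast", "stomach", r["oesophagus_fast_to_stomach"])
    b.transfer("oesophagus_slow", "stomach", r["oesophagus_slow_to_stomach"])
    b.transfer("stomach", "SI", r["stomach_to_si"])
    lam_si = r["si_to_rc"]
    if hp.f1 >= 1.0:
        # 100% absorption: keep the SI residence time, drop the colon path
        b.transfer("SI", "blood", lam_si)
    else:
        b.transfer("SI", "RC", lam_si)
        if hp.f1 > 0.0:
            b.transfer("SI", "blood", hp.f1 * lam_si / (1.0 - hp.f1))
    b.transfer("RC", "LC", r["rc_to_lc"])
    b.transfer("LC", "RS", r["lc_to_rs"])
    b.transfer("RS", "faeces", r["rs_to_faeces"])


def _add_hrtm(b: _SystemBuilder, hp: HRTMParameters, hatm: HATMParameters) -> None:
    dep = hp.deposition
    tr = hp.transport_rates_per_d

    # initial deposition, with the BB/bb fast/slow/sequestered split and the
    # AI1/AI2/AI3 sub-split
    b.deposit("ET1", dep.get("ET1", 0.0))
    d_et2 = dep.get("ET2", 0.0)
    b.deposit("ET_seq", d_et2 * hp.et2_seq_fraction)
    b.deposit("ET2", d_et2 * (1.0 - hp.et2_seq_fraction))
    for region, fast, slow, seq in (
        ("BB", "BB1", "BB2", "BB_seq"),
        ("bb", "bb1", "bb2", "bb_seq"),
    ):
        d = dep.get(region, 0.0)
        b.deposit(seq, d * hp.seq_fraction)
        rest = d * (1.0 - hp.seq_fraction)
        b.deposit(slow, rest * hp.slow_fraction)
        b.deposit(fast, rest * (1.0 - hp.slow_fraction))
    d_ai = dep.get("AI", 0.0)
    for sub, frac in zip(("AI1", "AI2", "AI3"), hp.ai_split):
        b.deposit(sub, d_ai * frac)
    remainder = 1.0 - sum(dep.values())
    if remainder > 1e-12:
        b.deposit("exhaled", remainder)

    # mechanical particle transport (ICRP 66 reference rates)
    b.transfer("AI1", "bb1", tr["ai1_to_bb1"])
    b.transfer("AI2", "bb1", tr["ai2_to_bb1"])
    b.transfer("AI3", "bb1", tr["ai3_to_bb1"])
    b.transfer("AI3", "LN_th", tr["ai3_to_ln_th"])
    b.transfer("bb1", "BB1", tr["bb1_to_big_bb1"])
    b.transfer("bb2", "BB1", tr["bb2_to_big_bb1"])
    b.transfer("bb_seq", "LN_th", tr["bb_seq_to_ln_th"])
    b.transfer("BB1", "ET2", tr["big_bb1_to_et2"])
    b.transfer("BB2", "ET2", tr["big_bb2_to_et2"])
    b.transfer("BB_seq", "LN_th", tr["big_bb_seq_to_ln_th"])
    b.transfer("ET_seq", "LN_et", tr["et_seq_to_ln_et"])
    b.transfer("ET1", "environment", tr["et1_to_environment"])

    # ET2 clears by swallowing into the oesophagus; split fast/slow in the
    # same proportion as the oral-cavity outflow
    swallow = tr["et2_to_oesophagus"]
    r_f = hatm.rates_per_d["oral_to_oesophagus_fast"]
    r_s = hatm.rates_per_d["oral_to_oesophagus_slow"]
    frac_fast = r_f / (r_f + r_s)
    b.transfer("ET2", "oesophagus_fast", swallow * frac_fast)
    b.transfer("ET2", "oesophagus_slow", swallow * (1.0 - frac_fast))

    # F-type dissolution to blood from every particle-bearing compartment
    # except ET1 (anterior nose clears only to the environment)
    for comp in (
        "ET2", "ET_seq", "BB1", "BB2", "BB_seq",
        "bb1", "bb2", "bb_seq", "AI1", "AI2", "AI3", "LN_th", "LN_et",
    ):
        b.transfer(comp, "blood", hp.s_p_per_d)


def build_system(
    scenario: IntakeScenario | Route | str,
    params: ParameterSet,
    nuclide: RadionuclideSpec | None = None,
) -> CompartmentSystem:
    """Assemble the full compartment system for one acute 1 Bq intake.

    Ingestion places the intake in the oral cavity; aerosol and elemental
    vapor inhalation deposit the regional fractions in the respiratory tract
    (non-deposited remainder exhaled); organic vapor (V-type) places its
    deposited fraction directly in blood.
    """
    scenario = _as_scenario(scenario)
    nuclide = nuclide or iodine_131()
    hrtm, hatm, systemic = params
    hrtm.validate(aerosol=scenario.route in _AEROSOL_ROUTES)
    hatm.validate()
    systemic.validate()

    b = _SystemBuilder()
    route = scenario.route
    if route is Route.INGESTION:
        b.deposit("oral_cavity", 1.0)
        _add_hatm(b, hatm, include_oral=True)
    elif route is Route.VAPOR_ORGANIC:
        b.deposit("blood", hrtm.total_deposition)
        if hrtm.total_deposition < 1.0 - 1e-12:
            b.deposit("exhaled", 1.0 - hrtm.total_deposition)
    else:
        _add_hrtm(b, hrtm, hatm)
        _add_hatm(b, hatm, include_oral=False)
    _add_systemic(b, systemic)
    return b.build(nuclide.decay_const_per_d, scenario)
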