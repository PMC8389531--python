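"""Synthetic stand-in for an ensemble MD binding-affinity simulator.

The real quantity of interest — an ensemble-averaged ligand-protein binding
free energy computed by an MD engine — costs CPU-hours per evaluation.  This
module provides a millisecond surrogate with the same statistical anatomy so
the whole uncertainty pipeline can be exercised and tested end to end:

- a 14-parameter input space of uniform distributions at +/-15% about their
  nominal values, with the thermostat temperature restricted to [280, 320] K;
- a mock simulator with a smooth low-effective-dimension parametric trend
  (temperature dominant), plus a right-skewed aleatoric draw indexed by the
  random seed alone, so the same seed shifts every configuration coherently
  — per-seed cdfs are then near-translates of each other, as replica
  ensembles with shared seeds behave;
- classic analytic benchmarks (Sobol g-function, Ishigami) with closed-form
  variance decompositions for validating the sensitivity pipeline.

Nominal values other than the temperature are placeholder constants — they
are NOT physically calibrated; they only define the affine map between the
unit cube and the physical box and never affect the unit-cube mathematics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "InputParameter",
    "InputSpace",
    "default_input_space",
    "MockConfig",
    "mock_esmacs",
    "make_mock_model",
    "g_function",
    "g_function_sobol",
    "ishigami",
    "ishigami_sobol",
    "DEFAULT_SEEDS",
]

#: The fixed replica seed list reused for every parametric configuration.
DEFAULT_SEEDS: Tuple[int, ...] = tuple(range(1, 26))


@dataclass(frozen=True)
class InputParameter:
    """One uncertain simulator input with uniform bounds."""

    name: str
    nominal: float
    lo: float
    hi: float
    group: str = "solver"  # "physical" | "solver"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: bounds must satisfy lo < hi")
        if not self.lo <= self.nominal <= self.hi:
            raise ValueError(f"{self.name}: nominal outside [lo, hi]")

    @classmethod
    def pm15(cls, name: str, nominal: float, group: str = "solver") -> "InputParameter":
        """Uniform bounds at +/-15% of a positive nominal value."""
        return cls(name=name, nominal=nominal, lo=0.85 * nominal,
                   hi=1.15 * nominal, group=group)


@dataclass(frozen=True)
class InputSpace:
    """Ordered collection of independent uniform inputs."""

    parameters: Tuple[InputParameter, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    @property
    def dimension(self) -> int:
        return len(self.parameters)

    @property
    def names(self) -> List[str]:
        return [p.name for p in self.parameters]

    def __getitem__(self, name: str) -> InputParameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def to_physical(self, unit_point: Sequence[float]) -> np.ndarray:
        """Affine map from the unit cube to the physical box."""
        u = np.asarray(unit_point, dtype=float)
        if u.shape != (self.dimension,):
            raise ValueError("unit point has wrong dimension")
        lo = np.array([p.lo for p in self.parameters])
        hi = np.array([p.hi for p in self.parameters])
        return lo + u * (hi - lo)

    def to_unit(self, physical_point: Sequence[float]) -> np.ndarray:
        """Inverse affine map; raises if the point leaves the box."""
        x = np.asarray(physical_point, dtype=float)
        lo = np.array([p.lo for p in self.parameters])
        hi = np.array([p.hi for p in self.parameters])
        if np.any(x < lo - 1e-12 * (hi - lo)) or np.any(x > hi + 1e-12 * (hi - lo)):
            raise ValueError("physical point outside the input box")
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "parameters": [
                {"name": p.name, "nominal": p.nominal, "lo": p.lo, "hi": p.hi,
                 "group": p.group}
                for p in self.parameters
            ]
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "InputSpace":
        return cls(tuple(InputParameter(**p) for p in payload["parameters"]))


def default_input_space() -> InputSpace:
    """The 14-input study space.

    Thirteen inputs carry uniform bounds at +/-15% of placeholder nominal
    values; the thermostat set temperature is varied on the physically
    motivated reduced range [280 K, 320 K] about a 300 K nominal.
    """
    pm15 = InputParameter.pm15
    return InputSpace(
        parameters=(
            InputParameter("setTemperature", 300.0, 280.0, 320.0, group="physical"),
            pm15("BerendsenPressureTarget", 1.01325, group="physical"),
            pm15("time_eq1", 2.0, group="physical"),
            pm15("time_sim1", 4.0, group="physical"),
            pm15("BerendsenPressureRelaxationTime", 100.0),
            pm15("initTemperature_eq1", 300.0),
            pm15("timestep", 2.0),
            pm15("cutoff", 12.0),
            pm15("switchdist", 10.0),
            pm15("pairlistdist", 13.5),
            pm15("box_pad", 14.0),
            pm15("langevinDamping", 5.0),
            pm15("PMEGridSpacing", 1.0),
            pm15("margin", 0.48),
        )
    )


@dataclass(frozen=True)
class MockConfig:
    """Parameters of the mock binding-energy simulator.

    The energy surface is ``base_energy`` plus a linear/quadratic trend in the
    unit-cube coordinates of the active inputs, plus an aleatoric draw from a
    standardized skew-normal family scaled by ``seed_noise_scale``.  Defaults
    emulate an ensemble campaign with a pooled mean near -34.5 kcal/mol,
    pooled spread near 1.6 kcal/mol, mild positive ensemble skewness and a
    low effective input dimension led by the temperature.
    """

    base_energy: float = -34.5
    linear_coeffs: Tuple[Tuple[str, float], ...] = (
        ("setTemperature", 1.4),
        ("box_pad", 0.5),
        ("cutoff", 0.25),
    )
    quad_coeffs: Tuple[Tuple[str, float], ...] = (("setTemperature", 0.3),)
    seed_noise_scale: float = 1.5
    seed_noise_skew: float = 3.0
    skew_mean_coupling: float = 0.0
    noise_mixing: float = 0.0
    seeds: Tuple[int, ...] = DEFAULT_SEEDS
    input_space: InputSpace = field(default_factory=default_input_space)

    @property
    def active_inputs(self) -> List[str]:
        names = [n for n, c in self.linear_coeffs if c != 0.0]
        names += [n for n, c in self.quad_coeffs if c != 0.0 and n not in names]
        return names

    def trend(self, unit_point: Sequence[float]) -> float:
        """Noise-free parametric trend evaluated at a unit-cube point."""
        u = np.asarray(unit_point, dtype=float)
        idx = {n: i for i, n in enumerate(self.input_space.names)}
        e = self.base_energy
        for name, c in self.linear_coeffs:
            e += c * (u[idx[name]] - 0.5)
        for name, c in self.quad_coeffs:
            e += c * (u[idx[name]] - 0.5) ** 2
        return float(e)


@lru_cache(maxsize=100_000)
def _standardized_skewnorm_ppf(p: float, alpha: float) -> float:
    """Quantile of the skew-normal(alpha) shifted/scaled to mean 0, sd 1."""
    if alpha == 0.0:
        return float(stats.norm.ppf(p))
    delta = alpha / math.sqrt(1.0 + alpha * alpha)
    mean = delta * math.sqrt(2.0 / math.pi)
    sd = math.sqrt(1.0 - 2.0 * delta * delta / math.pi)
    return float((stats.skewnorm.ppf(p, alpha) - mean) / sd)


def _seed_draw(seed: int) -> float:
    """Uniform variate attached to a replica seed — a function of the seed only.

    The base-2 radical inverse (van der Corput sequence) of ``seed + 1``:
    deterministic, never 0 or 1, and low-discrepancy, so that any modest
    contiguous seed list covers the noise distribution representatively — a
    replica ensemble of 25 seeds then carries spread and skewness close to
    the noise family's population values, emulating an ensemble size chosen
    to give stable statistics.
    """
    n = int(seed) + 1
    if n < 1:
        n = -n + 1  # negative seeds fold onto the positive branch
    u = 0.0
    denom = 2.0
    while n:
        u += (n & 1) / denom
        denom *= 2.0
        n >>= 1
    return u


def _pair_draw(unit_point: np.ndarray, seed: int) -> float:
    """Uniform variate hashed from a (configuration, seed) pair."""
    import hashlib

    h = hashlib.blake2b(
        np.asarray(unit_point, dtype=np.float64).tobytes() + seed.to_bytes(8, "little", signed=True),
        digest_size=8,
    ).digest()
    return (int.from_bytes(h, "little") + 0.5) / 2.0**64


def mock_esmacs(cfg: MockConfig, xi: Sequence[float], seed: int) -> float:
    """Mock ensemble-MD binding energy for one (configuration, seed) pair.

    ``xi`` is a point in the physical input box.  The result is a
    deterministic function of ``(xi, seed)``: the smooth parametric trend at
    ``xi`` plus a skew-normal aleatoric term whose underlying variate depends
    on the seed alone, so a given seed perturbs all configurations coherently
    (per-seed cdfs over configurations are then near-translates, a coherent
    probability box).  Two knobs, both off by default, plant
    configuration-seed interaction: ``skew_mean_coupling`` makes the noise
    family's skewness drift with the local trend, and ``noise_mixing`` in
    [0, 1] blends in a second variate hashed from the (configuration, seed)
    pair — at 1 the aleatoric term is independent across configurations, so
    ensemble averaging visibly shrinks the output spread.
    """
    u = cfg.input_space.to_unit(xi)  # raises for out-of-box points
    mu = cfg.trend(u)
    p = _seed_draw(int(seed))
    alpha = cfg.seed_noise_skew + cfg.skew_mean_coupling * (mu - cfg.base_energy)
    z = _standardized_skewnorm_ppf(p, alpha)
    if cfg.noise_mixing > 0.0:
        z_pair = _standardized_skewnorm_ppf(_pair_draw(u, int(seed)), alpha)
        m = cfg.noise_mixing
        z = math.sqrt(1.0 - m * m) * z + m * z_pair
    return mu + cfg.seed_noise_scale * z


def make_mock_model(cfg: Optional[MockConfig] = None):
    """Bind a MockConfig into the ``model(config, seed) -> energy`` signature."""
    cfg = cfg or MockConfig()
    return lambda xi, seed: mock_esmacs(cfg, xi, seed)


# ---------------------------------------------------------------------------
# analytic benchmarks with closed-form Sobol decompositions
# ---------------------------------------------------------------------------

def g_function(u: Sequence[float], a: Sequence[float]) -> float:
    """Sobol g-function on the unit cube: prod (|4u_i - 2| + a_i) / (1 + a_i)."""
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("g-function coefficients must be >= 0")
    if u.shape != a.shape:
        raise ValueError("point and coefficient vectors must match")
    return float(np.prod((np.abs(4.0 * u - 2.0) + a) / (1.0 + a)))


def g_function_sobol(a: Sequence[float]) -> Dict[frozenset, float]:
    """Closed-form Sobol indices of the g-function for every input subset.

    D_i = (1/3) / (1 + a_i)^2; D_u = prod_{i in u} D_i; D = prod (1 + D_i) - 1.
    """
    a = np.asarray(a, dtype=float)
    Di = (1.0 / 3.0) / (1.0 + a) ** 2
    D = float(np.prod(1.0 + Di) - 1.0)
    out: Dict[frozenset, float] = {}
    d = a.size
    import itertools

    for r in range(1, d + 1):
        for u in itertools.combinations(range(d), r):
            out[frozenset(u)] = float(np.prod(Di[list(u)]) / D)
    return out


def ishigami(u: Sequence[float], a: float = 7.0, b: float = 0.1) -> float:
    """Ishigami function; the unit cube is mapped affinely to [-pi, pi]^3."""
    u = np.asarray(u, dtype=float)
    if u.shape != (3,):
        raise ValueError("Ishigami is a 3-input function")
    x = -math.pi + 2.0 * math.pi * u
    return float(
        math.sin(x[0]) + a * math.sin(x[1]) ** 2 + b * x[2] ** 4 * math.sin(x[0])
    )


def ishigami_sobol(a: float = 7.0, b: float = 0.1) -> Dict[frozenset, float]:
    """Closed-form Sobol indices of the Ishigami function.

    V1 = (1 + b pi^4 / 5)^2 / 2; V2 = a^2 / 8; V13 = 8 b^2 pi^8 / 225;
    the third input contributes only through its interaction with the first.
    """
    pi = math.pi
    V1 = 0.5 * (1.0 + b * pi**4 / 5.0) ** 2
    V2 = a**2 / 8.0
    V13 = 8.0 * b**2 * pi**8 / 225.0
    V = V1 + V2 + V13
    return {
        frozenset({0}): V1 / V,
        frozenset({1}): V2 / V,
        frozenset({2}): 0.0,
        frozenset({0, 2}): V13 / V,
    }
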