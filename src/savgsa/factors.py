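"""Uncertain factors for the GSA/UA: input and function multipliers.

Every uncertain quantity is represented as a dimensionless multiplier with a
uniform distribution, by default U(0.8, 1.2) — a +/-20% band around the
baseline.  Input multipliers scale the five environmental drivers (salinity,
temperature, depth, light attenuation k, surface PAR); function multipliers
scale the output of each suitability curve, truncated to [0, 1] since an SI
cannot leave that range.  One sampled multiplier applies uniformly to every
grid cell within a model run, so each quasi-Monte-Carlo iteration produces a
whole perturbed map.

The proportional form means low baseline SI values receive absolutely
narrower perturbation bands than high ones — uncertainty is smallest where
conditions are thought to be clearly unsuitable.

A factor count of k = 5 inputs + (number of curves) function multipliers
gives 8 factors for a single-ADBL-curve species and 9 for a dual-curve one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .hsi import CellEnvironment, SpeciesModel

__all__ = [
    "FactorSpec",
    "FactorSpace",
    "INPUT_FACTOR_NAMES",
    "default_factor_space",
    "sample_to_multipliers",
    "apply_input_factors",
    "apply_function_multiplier",
    "function_multipliers_from_sample",
]

#: Canonical order of the five environmental input factors.
INPUT_FACTOR_NAMES = ("sal", "temp", "depth", "k", "par")

#: Function-multiplier factor name for each curve slot, in canonical curve order.
FUNCTION_FACTOR_NAMES = ("f.sal", "f.temp", "f.adbl", "f.adbl2")

DEFAULT_LOW = 0.8
DEFAULT_HIGH = 1.2


@dataclass(frozen=True)
class FactorSpec:
    """One uncertain factor.

    kind is ``"input"`` (multiplier on an environmental driver),
    ``"function"`` (multiplier on a curve's SI output) or ``"discrete"``
    (auxiliary factor with equiprobable labeled levels, e.g. alternative
    curve sets representing structural uncertainty).
    """

    name: str
    kind: str
    low: float = DEFAULT_LOW
    high: float = DEFAULT_HIGH
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("input", "function", "discrete"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if self.kind == "discrete":
            if len(self.levels) < 2:
                raise ValueError("discrete factor needs at least 2 levels")
        elif not (self.low < self.high):
            raise ValueError("factor bounds must satisfy low < high")

    def value_at(self, u: float):
        """Map a unit-interval coordinate to this factor's value.

        Continuous factors: inverse-CDF of U(low, high).  Discrete factors:
        the label of the equiprobable level containing u.
        """
        if not (0.0 <= u <= 1.0):
            raise ValueError("sample coordinate outside [0, 1]")
        if self.kind == "discrete":
            idx = min(int(u * len(self.levels)), len(self.levels) - 1)
            return self.levels[idx]
        return self.low + u * (self.high - self.low)


@dataclass(frozen=True)
class FactorSpace:
    """Ordered collection of the k uncertain factors of one analysis."""

    factors: tuple[FactorSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_factor_space(
    model: SpeciesModel, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> FactorSpace:
    """The standard factor space for a species model.

    Five input multipliers (sal, temp, depth, k, par) followed by one
    function multiplier per curve — 8 factors for a single-ADBL species,
    9 for a dual-ADBL species.  All share the same uniform bounds.
    """
    factors = [FactorSpec(n, "input", low, high) for n in INPUT_FACTOR_NAMES]
    factors += [
        FactorSpec(FUNCTION_FACTOR_NAMES[i], "function", low, high)
        for i in range(model.n_curves)
    ]
    return FactorSpace(tuple(factors))


def sample_to_multipliers(sample: Sequence[float], space: FactorSpace) -> dict:
    """Map one unit-hypercube point to named factor values."""
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (space.k,):
        raise ValueError(f"sample has shape {sample.shape}, expected ({space.k},)")
    return {f.name: f.value_at(u) for f, u in zip(space.factors, sample)}


def apply_input_factors(
    env: CellEnvironment, sample: Sequence[float], space: FactorSpace
) -> CellEnvironment:
    """Scale a baseline environment by the sampled input multipliers.

    Each input multiplier m = low + u*(high - low) scales its baseline
    field; factors absent from the space leave their field untouched.
    """
    mult = sample_to_multipliers(sample, space)
    return CellEnvironment(
        salinity=env.salinity * mult.get("sal", 1.0),
        temperature=env.temperature * mult.get("temp", 1.0),
        depth=env.depth * mult.get("depth", 1.0),
        par=env.par * mult.get("par", 1.0),
        k_light=env.k_light * mult.get("k", 1.0),
    )


def apply_function_multiplier(si, m):
    """Perturb an SI by a function multiplier, truncating to [0, 1].

    Works on scalars and arrays.  Equals m*si whenever that product lies in
    [0, 1]; since si is at most 1, the attainable band over m in [0.8, 1.2]
    is proportionally narrower for smaller baseline si.
    """
    out = np.clip(np.multiply(m, si), 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def function_multipliers_from_sample(
    sample: Sequence[float], space: FactorSpace, model: SpeciesModel
) -> tuple[float, ...]:
    """Extract per-curve function multipliers (canonical curve order).

    Curves whose factor is absent from the space get multiplier 1.
    """
    mult = sample_to_multipliers(sample, space)
    return tuple(
        float(mult.get(FUNCTION_FACTOR_NAMES[i], 1.0)) for i in range(model.n_curves)
    )
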