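"""Habitat suitability index (HSI) model core.

An HSI model scores habitat quality for a species on [0, 1] from a small set
of environmental variables.  Each variable is mapped to a partial suitability
index (SI) through a piecewise-linear look-up curve, and the total HSI is the
geometric mean of the three equally weighted partial indices

    HSI = (SI_sal * SI_temp * SI_ADBL) ** (1/3)

so that any single unsuitable variable acts as a limiting factor and drives
the total score to zero.

Light availability is expressed as average daily bottom light (ADBL): surface
photosynthetically active radiation (PAR) attenuated exponentially with depth
following the Beer–Lambert law, after a fixed fraction of incident light
passes the water surface.  Tape grass (*Vallisneria americana*) uses two
alternative ADBL curves — light-use efficiency differs between low- and
high-salinity conditions — selected by a salinity threshold; shoal grass
(*Halodule wrightii*) uses a single ADBL curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SuitabilityCurve",
    "SpeciesModel",
    "CellEnvironment",
    "interpolate_si",
    "compute_adbl",
    "select_adbl_curve",
    "total_hsi",
    "evaluate_cell",
]

#: Fraction of incident light passing the water surface (dimensionless).
DEFAULT_SURFACE_TRANSMISSION = 0.9


@dataclass(frozen=True)
class SuitabilityCurve:
    """Piecewise-linear map from an environmental variable to an SI in [0, 1].

    Parameters
    ----------
    variable_name
        Which variable the curve responds to: ``"salinity"``,
        ``"temperature"`` or ``"adbl"``.
    breakpoints
        Ordered ``(x, si)`` pairs; x strictly increasing, si in [0, 1].
        Outside the breakpoint range the curve is flat at the nearest
        endpoint's si (perturbed inputs may leave the plotted domain).
    """

    variable_name: str
    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        bps = tuple((float(x), float(s)) for x, s in self.breakpoints)
        object.__setattr__(self, "breakpoints", bps)
        if len(bps) < 2:
            raise ValueError("curve needs at least 2 breakpoints")
        xs = np.array([x for x, _ in bps])
        sis = np.array([s for _, s in bps])
        if not np.all(np.isfinite(xs)) or not np.all(np.isfinite(sis)):
            raise ValueError("breakpoints must be finite")
        if not np.all(np.diff(xs) > 0):
            raise ValueError("breakpoint x-values must be strictly increasing")
        if np.any(sis < 0) or np.any(sis > 1):
            raise ValueError("si values must lie in [0, 1]")

    @property
    def x(self) -> np.ndarray:
        return np.array([x for x, _ in self.breakpoints])

    @property
    def si(self) -> np.ndarray:
        return np.array([s for _, s in self.breakpoints])


@dataclass(frozen=True)
class SpeciesModel:
    """A species' HSI model: three look-up curves plus the ADBL-curve rule.

    ``adbl_curves`` holds one curve for single-curve species, or two
    (low-salinity first, then high-salinity) with ``adbl_salinity_threshold``
    giving the PSU value at and above which the high-salinity curve applies.
    """

    name: str
    salinity_curve: SuitabilityCurve
    temperature_curve: SuitabilityCurve
    adbl_curves: tuple[SuitabilityCurve, ...]
    adbl_salinity_threshold: float | None = None
    surface_transmission: float = DEFAULT_SURFACE_TRANSMISSION

    def __post_init__(self) -> None:
        object.__setattr__(self, "adbl_curves", tuple(self.adbl_curves))
        if len(self.adbl_curves) not in (1, 2):
            raise ValueError("exactly 1 or 2 ADBL curves required")
        if (len(self.adbl_curves) == 2) != (self.adbl_salinity_threshold is not None):
            raise ValueError(
                "adbl_salinity_threshold required iff two ADBL curves are present"
            )
        if not (0.0 < self.surface_transmission <= 1.0):
            raise ValueError("surface_transmission must be in (0, 1]")

    @property
    def curves(self) -> tuple[SuitabilityCurve, ...]:
        """All curves in canonical factor order: salinity, temperature, ADBL(s)."""
        return (self.salinity_curve, self.temperature_curve) + self.adbl_curves

    @property
    def n_curves(self) -> int:
        return 2 + len(self.adbl_curves)


@dataclass(frozen=True)
class CellEnvironment:
    """Monthly environmental state of one grid cell.

    salinity in PSU, temperature in degC, depth in m (positive down),
    par in umol m^-2 s^-1 at the surface, k_light in m^-1.
    """

    salinity: float
    temperature: float
    depth: float
    par: float
    k_light: float

    def __post_init__(self) -> None:
        vals = (self.salinity, self.temperature, self.depth, self.par, self.k_light)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("environment fields must be finite")
        if self.salinity < 0 or self.depth < 0 or self.par < 0 or self.k_light < 0:
            raise ValueError("salinity, depth, par and k_light must be >= 0")


def interpolate_si(curve: SuitabilityCurve, x) -> float | np.ndarray:
    """Evaluate a suitability curve at ``x`` by linear interpolation.

    Values below the first breakpoint clamp to the first si; above the last,
    to the last si.  Accepts scalars or arrays; non-finite x raises.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    out = np.interp(arr, curve.x, curve.si)
    return float(out) if np.ndim(x) == 0 else out


def compute_adbl(env: CellEnvironment, transmission: float = DEFAULT_SURFACE_TRANSMISSION):
    """Average daily bottom light via the Beer–Lambert law.

    ADBL = transmission * PAR * exp(-k_light * depth), in the same units as
    PAR (umol m^-2 s^-1).
    """
    return transmission * env.par * math.exp(-env.k_light * env.depth)


def select_adbl_curve(model: SpeciesModel, salinity: float) -> SuitabilityCurve:
    """Pick the ADBL curve in effect at a given salinity.

    Single-curve species always use their only curve.  For two-curve species
    the low-salinity curve applies on [0, threshold) and the high-salinity
    curve at and above the threshold.
    """
    if len(model.adbl_curves) == 1:
        return model.adbl_curves[0]
    if salinity < model.adbl_salinity_threshold:
        return model.adbl_curves[0]
    return model.adbl_curves[1]


def total_hsi(si_sal: float, si_temp: float, si_adbl: float) -> float:
    """Geometric mean of the three partial indices.

    Zero whenever any partial SI is zero (limiting-factor behaviour); inputs
    outside [0, 1] raise.
    """
    parts = (si_sal, si_temp, si_adbl)
    for p in parts:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"partial SI {p!r} outside [0, 1]")
    prod = si_sal * si_temp * si_adbl
    if prod == 0.0:
        return 0.0
    return prod ** (1.0 / 3.0)


def evaluate_cell(
    model: SpeciesModel,
    env: CellEnvironment,
    function_multipliers: Sequence[float] | None = None,
) -> tuple[float, float, float, float]:
    """Evaluate the full HSI model at one cell.

    ``function_multipliers`` scales each curve's output in canonical curve
    order (salinity, temperature, ADBL low, [ADBL high]); the perturbed SI is
    truncated to [0, 1].  ``None`` means all multipliers are 1 (the
    deterministic baseline run).

    Returns ``(hsi, si_sal, si_temp, si_adbl)``.
    """
    if function_multipliers is None:
        function_multipliers = (1.0,) * model.n_curves
    if len(function_multipliers) != model.n_curves:
        raise ValueError(
            f"expected {model.n_curves} function multipliers, "
            f"got {len(function_multipliers)}"
        )

    adbl = compute_adbl(env, model.surface_transmission)
    adbl_curve = select_adbl_curve(model, env.salinity)
    adbl_idx = 2 + model.adbl_curves.index(adbl_curve)

    si_sal = _perturbed_si(model.salinity_curve, env.salinity, function_multipliers[0])
    si_temp = _perturbed_si(model.temperature_curve, env.temperature, function_multipliers[1])
    si_adbl = _perturbed_si(adbl_curve, adbl, function_multipliers[adbl_idx])
    return total_hsi(si_sal, si_temp, si_adbl), si_sal, si_temp, si_adbl


def _perturbed_si(curve: SuitabilityCurve, x: float, m: float) -> float:
    si = interpolate_si(curve, x)
    return float(np.clip(m * si, 0.0, 1.0))
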