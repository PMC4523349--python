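"""Synthetic estuarine hydrology: gridded monthly drivers for the HSI model.

Stands in for hydrodynamic-model output so the full GSA/UA pipeline runs
self-contained.  The generator reproduces the qualitative structure the
analysis assumes, per 500 x 500 m cell and month:

* **salinity** — a logistic inland-to-marine gradient along the column axis
  (~0 PSU fresh inland, ~35 PSU marine), with a dry-season inland excursion
  of the salt front and seeded Gaussian noise; under a sea-level-rise (SLR)
  scenario the front migrates steadily inland, so domain-mean salinity rises
  through the simulation;
* **temperature** — a subtropical seasonal sinusoid (default 18–32 degC,
  warmest mid-summer) plus noise, spatially uniform before noise;
* **depth** — a fixed spatial field deepening toward the marine side, plus a
  linearly ramped SLR increment reaching ``slr_total`` in the final month;
* **surface PAR** — a 12-value monthly climatology (sinusoid peaking in
  June), shared by all cells;
* **k_light** — a single baseline light-attenuation coefficient
  (default 0.85 m^-1).

No spatial correlation of the noise is modelled: each cell is treated as
independent, matching the per-cell independence assumption of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HydroGrid",
    "ScenarioConfig",
    "month_range",
    "generate_hydrology",
    "write_hydrology",
    "read_hydrology",
]

BASELINE_K_LIGHT = 0.85  # m^-1
DEFAULT_CELLSIZE = 500.0  # m


def month_range(start: tuple[int, int], end: tuple[int, int]) -> tuple[tuple[int, int], ...]:
    """Contiguous (year, month) pairs from start to end inclusive."""
    y, m = start
    out = []
    while (y, m) <= tuple(end):
        out.append((y, m))
        m += 1
        if m > 12:
            y, m = y + 1, 1
    if not out:
        raise ValueError(f"empty month range {start}..{end}")
    return tuple(out)


@dataclass(frozen=True)
class HydroGrid:
    """Per-cell, per-month baseline environmental fields.

    ``salinity`` (PSU), ``temperature`` (degC) and ``depth`` (m) have shape
    (n_months, nrows, ncols); ``par_climatology`` holds 12 monthly surface
    PAR values (umol m^-2 s^-1) indexed by calendar month - 1.
    """

    nrows: int
    ncols: int
    cellsize: float
    months: tuple[tuple[int, int], ...]
    salinity: np.ndarray
    temperature: np.ndarray
    depth: np.ndarray
    par_climatology: np.ndarray
    k_light: float = BASELINE_K_LIGHT

    def __post_init__(self) -> None:
        object.__setattr__(self, "months", tuple(tuple(m) for m in self.months))
        object.__setattr__(self, "par_climatology", np.asarray(self.par_climatology, dtype=float))
        shape = (len(self.months), self.nrows, self.ncols)
        for name in ("salinity", "temperature", "depth"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.salinity < 0):
            raise ValueError("salinity must be >= 0")
        if np.any(self.depth <= 0):
            raise ValueError("depth must be > 0")
        if self.par_climatology.shape != (12,) or np.any(self.par_climatology < 0):
            raise ValueError("par_climatology must be 12 non-negative values")
        if self.k_light < 0 or self.cellsize <= 0:
            raise ValueError("k_light must be >= 0 and cellsize > 0")
        if self.months != month_range(self.months[0], self.months[-1]):
            raise ValueError("months must be contiguous")

    @property
    def n_months(self) -> int:
        return len(self.months)

    def par_for_month(self, month_idx: int) -> float:
        """Surface PAR for the month at position ``month_idx`` of the record."""
        return float(self.par_climatology[self.months[month_idx][1] - 1])


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic hydrology scenario.

    ``slr_total`` is the sea-level rise (m) reached by the final month: 0
    for current conditions, 0.30 for the future scenario.  The gradient
    parameters are in units of the normalised cross-shore coordinate
    (0 = inland edge, 1 = marine edge).
    """

    nrows: int = 20
    ncols: int = 20
    cellsize: float = DEFAULT_CELLSIZE
    start: tuple[int, int] = (1999, 1)
    end: tuple[int, int] = (2047, 12)
    slr_total: float = 0.0
    rng_seed: int = 0
    # salinity gradient
    marine_salinity: float = 35.0
    front_position: float = 0.55  # normalised location of the salt front
    front_width: float = 0.12
    dry_season_shift: float = 0.08  # inland front excursion at dry-season peak
    slr_front_shift: float = 0.5  # front migration (gradient units) per m SLR
    salinity_noise_sd: float = 1.0  # PSU
    # temperature cycle
    temp_mean: float = 25.0
    temp_amplitude: float = 7.0  # gives the default 18-32 degC annual range
    temp_noise_sd: float = 0.5
    # bathymetry
    depth_inshore: float = 0.3
    depth_offshore: float = 3.0
    # light
    par_mean: float = 700.0
    par_amplitude: float = 300.0
    k_light: float = BASELINE_K_LIGHT

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.slr_total < 0:
            raise ValueError("slr_total must be >= 0")
        if self.depth_inshore <= 0 or self.depth_offshore < self.depth_inshore:
            raise ValueError("depths must satisfy 0 < inshore <= offshore")


def _seasonal_dryness(month: int) -> float:
    """+1 at the March dry-season peak, -1 at the September wet peak."""
    return float(np.cos(2.0 * np.pi * (month - 3) / 12.0))


def generate_hydrology(config: ScenarioConfig) -> HydroGrid:
    """Generate a seeded synthetic hydrology record.

    Deterministic given ``config.rng_seed``.  Columns run inland (col 0) to
    marine (last col).
    """
    rng = np.random.default_rng(config.rng_seed)
    months = month_range(config.start, config.end)
    T = len(months)
    shape = (T, config.nrows, config.ncols)

    # normalised cross-shore coordinate per column, broadcast over rows
    x = np.linspace(0.0, 1.0, config.ncols)[np.newaxis, :]
    x = np.broadcast_to(x, (config.nrows, config.ncols))

    sal = np.empty(shape)
    temp = np.empty(shape)
    depth = np.empty(shape)
    # fixed bathymetry: deepening toward the marine edge
    bathy = config.depth_inshore + (config.depth_offshore - config.depth_inshore) * x**1.5

    for t, (_, month) in enumerate(months):
        slr_frac = t / (T - 1) if T > 1 else 0.0
        front = (
            config.front_position
            - config.dry_season_shift * _seasonal_dryness(month)
            - config.slr_front_shift * config.slr_total * slr_frac
        )
        sal[t] = config.marine_salinity / (1.0 + np.exp(-(x - front) / config.front_width))
        temp[t] = config.temp_mean + config.temp_amplitude * np.cos(
            2.0 * np.pi * (month - 7.5) / 12.0
        )
        depth[t] = bathy + config.slr_total * slr_frac

    sal += rng.normal(0.0, config.salinity_noise_sd, size=shape)
    temp += rng.normal(0.0, config.temp_noise_sd, size=shape)
    np.clip(sal, 0.0, None, out=sal)

    par = config.par_mean + config.par_amplitude * np.cos(
        2.0 * np.pi * (np.arange(1, 13) - 6) / 12.0
    )
    return HydroGrid(
        nrows=config.nrows,
        ncols=config.ncols,
        cellsize=config.cellsize,
        months=months,
        salinity=sal,
        temperature=temp,
        depth=depth,
        par_climatology=par,
        k_light=config.k_light,
    )


# ---------------------------------------------------------------------------
# plain-text persistence: long-format CSV + YAML metadata sidecar
# ---------------------------------------------------------------------------

_COLUMNS = ["cell_row", "cell_col", "year", "month", "salinity", "temperature", "depth"]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_hydrology(grid: HydroGrid, path) -> None:
    """Write a grid as ``<path>`` (long-format CSV) + ``<path>.meta.yaml``.

    Floats are serialised at full precision so write -> read round-trips
    exactly.
    """
    path = Path(path)
    T = grid.n_months
    rr, cc = np.meshgrid(np.arange(grid.nrows), np.arange(grid.ncols), indexing="ij")
    frames = []
    for t, (year, month) in enumerate(grid.months):
        frames.append(
            pd.DataFrame(
                {
                    "cell_row": rr.ravel(),
                    "cell_col": cc.ravel(),
                    "year": year,
                    "month": month,
                    "salinity": grid.salinity[t].ravel(),
                    "temperature": grid.temperature[t].ravel(),
                    "depth": grid.depth[t].ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "nrows": int(grid.nrows),
        "ncols": int(grid.ncols),
        "cellsize": float(grid.cellsize),
        "start": [int(v) for v in grid.months[0]],
        "end": [int(v) for v in grid.months[-1]],
        "k_light": float(grid.k_light),
        "par_climatology": [float(v) for v in grid.par_climatology],
    }
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_hydrology(path) -> HydroGrid:
    """Read a grid written by :func:`write_hydrology`, validating as it goes."""
    path = Path(path)
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_file}")
    meta = yaml.safe_load(meta_file.read_text())
    for key in ("nrows", "ncols", "cellsize", "start", "end", "k_light", "par_climatology"):
        if key not in meta:
            raise ValueError(f"metadata missing field {key!r}")
    nrows, ncols = int(meta["nrows"]), int(meta["ncols"])
    months = month_range(tuple(meta["start"]), tuple(meta["end"]))

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"data file missing columns {missing}")
    expected = len(months) * nrows * ncols
    if len(df) != expected:
        raise ValueError(
            f"data file has {len(df)} records, expected {expected} "
            f"({len(months)} months x {nrows} x {ncols} cells)"
        )
    if df[_COLUMNS].isna().any().any():
        bad = int(df[_COLUMNS].isna().any(axis=1).idxmax())
        raise ValueError(f"malformed record at data row {bad}")

    month_index = {ym: t for t, ym in enumerate(months)}
    shape = (len(months), nrows, ncols)
    sal = np.full(shape, np.nan)
    temp = np.full(shape, np.nan)
    depth = np.full(shape, np.nan)
    t_idx = np.array([month_index.get((y, m), -1) for y, m in zip(df.year, df.month)])
    if np.any(t_idx < 0):
        bad = int(np.flatnonzero(t_idx < 0)[0])
        raise ValueError(f"record {bad} has (year, month) outside the declared range")
    r = df.cell_row.to_numpy()
    c = df.cell_col.to_numpy()
    if r.min() < 0 or r.max() >= nrows or c.min() < 0 or c.max() >= ncols:
        raise ValueError("cell indices outside the declared grid (cellsize/shape mismatch)")
    sal[t_idx, r, c] = df.salinity
    temp[t_idx, r, c] = df.temperature
    depth[t_idx, r, c] = df.depth
    if np.any(np.isnan(sal)):
        t, rr, cc = (int(v[0]) for v in np.nonzero(np.isnan(sal)))
        raise ValueError(f"missing record for month {months[t]}, cell ({rr}, {cc})")

    return HydroGrid(
        nrows=nrows,
        ncols=ncols,
        cellsize=float(meta["cellsize"]),
        months=months,
        salinity=sal,
        temperature=temp,
        depth=depth,
        par_climatology=np.asarray(meta["par_climatology"], dtype=float),
        k_light=float(meta["k_light"]),
    )
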