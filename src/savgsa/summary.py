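"""Uncertainty-analysis products from an ensemble of HSI maps.

Each of the M quasi-Monte-Carlo runs yields one HSI map per month; this
module collapses those ensembles into per-cell mean and standard-deviation
maps and, at selected benchmark cells, empirical PDF/CDF summaries and
threshold-exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HsiEnsemble",
    "CellSummary",
    "summarize_maps",
    "empirical_distribution",
    "exceedance_probability",
]

DEFAULT_PDF_BINS = 25


@dataclass(frozen=True)
class HsiEnsemble:
    """M total-HSI maps aligned to the rows of a Saltelli design.

    ``values`` has shape (M, n_months, nrows, ncols), all entries in [0, 1].
    """

    values: np.ndarray
    months: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 4:
            raise ValueError("ensemble must have shape (M, n_months, nrows, ncols)")
        if v.shape[0] == 0:
            raise ValueError("ensemble is empty")
        if v.shape[1] != len(self.months):
            raise ValueError("months do not match ensemble axis 1")
        if np.any(v < 0) or np.any(v > 1) or not np.all(np.isfinite(v)):
            raise ValueError("HSI values must be finite and in [0, 1]")

    @property
    def M(self) -> int:
        return self.values.shape[0]

    def cell_values(self, month_idx: int, row: int, col: int) -> np.ndarray:
        """The M-vector of HSI values at one cell and month."""
        return self.values[:, month_idx, row, col]


@dataclass(frozen=True)
class CellSummary:
    """Per-month mean and SD maps over the M ensemble members."""

    mean: np.ndarray  # (n_months, nrows, ncols)
    sd: np.ndarray
    n: int


def summarize_maps(ensemble: HsiEnsemble) -> CellSummary:
    """Per-cell sample mean and sample SD (M-1 denominator) over all M runs."""
    v = ensemble.values
    return CellSummary(
        mean=v.mean(axis=0),
        sd=v.std(axis=0, ddof=1) if v.shape[0] > 1 else np.zeros_like(v[0]),
        n=ensemble.M,
    )


def empirical_distribution(values, bins: int = DEFAULT_PDF_BINS):
    """Empirical PDF (histogram) and CDF of a sample of HSI scores.

    The PDF is a density-normalised histogram over [0, 1] with ``bins``
    equal-width bins (fixed edges so different sites and dates are directly
    comparable).  The CDF is the step function evaluated at the sorted
    sample points: CDF(x) = fraction of values <= x, so CDF at the largest
    sample point is 1.

    Returns ``(bin_edges, density), (sorted_values, cdf)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("HSI values must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    density, _ = np.histogram(v, bins=edges, density=True)
    xs = np.sort(v)
    cdf = np.arange(1, xs.size + 1) / xs.size
    return (edges, density), (xs, cdf)


def exceedance_probability(values, threshold: float) -> float:
    """Fraction of sample values strictly greater than ``threshold``.

    The complement of the empirical CDF; useful for management questions of
    the form "how likely is suitability above 0.5 at this site?".
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    v = np.asarray(values, dtype=float)
    return float(np.mean(v > threshold))
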