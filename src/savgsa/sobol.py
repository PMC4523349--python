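"""Variance-based global sensitivity analysis: Sobol indices.

The method of Sobol decomposes the variance V(Y) of a model output into
contributions from each of the k uncertain factors and their interactions:

    V(Y) = sum_i V_i + sum_{i<j} V_ij + ... + V_{1..k}

The first-order index S_i = V_i / V measures a factor's direct contribution;
the total-order index S_Ti adds all interaction terms involving that factor.
Both are estimated here by the Saltelli quasi-Monte-Carlo scheme: two base
matrices A and B of N points each in the k-dimensional unit hypercube, plus
for each factor i the column-swapped matrices A_B^(i) (A with column i from
B) and B_A^(i) (B with column i from A), giving M = (2k + 2) N model runs in
total.  First-order indices use the Saltelli (2002) correlation estimator on
the pairs sharing only column i; total-order indices use the complementary
set, the pairs sharing every column except i.

A brute-force full-enumeration decomposition over discrete factor grids is
provided as an exact oracle for small tabulated functions; it computes every
partial variance and conserves V(Y) to floating tolerance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = [
    "SobolDesign",
    "SensitivityResult",
    "BruteForceDecomposition",
    "sobol_sequence",
    "saltelli_design",
    "estimate_indices",
    "brute_force_indices",
]

#: A cell whose output variance falls below RELATIVE_VARIANCE_TOL * mean^2
#: (or below an absolute floor) is flagged degenerate rather than reported.
RELATIVE_VARIANCE_TOL = 1e-12
ABSOLUTE_VARIANCE_FLOOR = 1e-30


def sobol_sequence(n: int, d: int, skip: int = 1) -> np.ndarray:
    """First ``n`` points of the d-dimensional Sobol low-discrepancy sequence.

    Unscrambled, with Joe–Kuo direction numbers; ``skip`` leading points are
    dropped (default 1, discarding the all-zeros origin, which would map to
    degenerate lower-bound multipliers).  Deterministic: identical arguments
    give bitwise-identical output.
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    if skip < 0:
        raise ValueError("skip must be >= 0")
    try:
        eng = qmc.Sobol(d, scramble=False)
    except ValueError as exc:  # dimension beyond tabulated direction numbers
        raise ValueError(f"dimension {d} not supported: {exc}") from exc
    if skip:
        eng.fast_forward(skip)
    with warnings.catch_warnings():
        # n need not be a power of two for the Saltelli estimators used here
        warnings.simplefilter("ignore", UserWarning)
        return eng.random(n)


@dataclass(frozen=True)
class SobolDesign:
    """A Saltelli experimental design of M = (2k+2)N unit-hypercube points.

    ``rows`` stacks the blocks in order A, B, A_B^(1..k), B_A^(1..k); the
    companion arrays ``matrix_id`` (e.g. ``"A"``, ``"AB3"``) and
    ``base_index`` (0..N-1) identify each row's block and base sample.
    """

    N: int
    k: int
    rows: np.ndarray
    matrix_id: np.ndarray
    base_index: np.ndarray

    def __post_init__(self) -> None:
        if self.rows.shape != (self.M, self.k):
            raise ValueError("design rows have wrong shape")

    @property
    def M(self) -> int:
        return (2 * self.k + 2) * self.N

    def block(self, name: str) -> np.ndarray:
        """Row indices of one block (``"A"``, ``"B"``, ``"AB<i>"``, ``"BA<i>"``).

        Ordered by base-sample id, so outputs from different blocks pair up
        correctly even if the design rows have been stored or processed out
        of order.
        """
        idx = np.flatnonzero(self.matrix_id == name)
        return idx[np.argsort(self.base_index[idx], kind="stable")]


def saltelli_design(N: int, k: int, skip: int = 1) -> SobolDesign:
    """Build the (2k+2)N Saltelli design from a 2k-dimensional Sobol sequence.

    The first k columns of each quasi-random point form matrix A, the last k
    form B; the 2k swapped matrices follow.  With the N = 512 base sample
    this yields the familiar 9216 runs for k = 8 and 10240 for k = 9.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if k < 1:
        raise ValueError("k must be >= 1")
    base = sobol_sequence(N, 2 * k, skip=skip)
    A = base[:, :k]
    B = base[:, k:]
    blocks = [A, B]
    ids = [np.full(N, "A", dtype=object), np.full(N, "B", dtype=object)]
    for i in range(k):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
        ids.append(np.full(N, f"AB{i}", dtype=object))
    for i in range(k):
        BA = B.copy()
        BA[:, i] = A[:, i]
        blocks.append(BA)
        ids.append(np.full(N, f"BA{i}", dtype=object))
    rows = np.vstack(blocks)
    matrix_id = np.concatenate(ids)
    base_index = np.tile(np.arange(N), 2 * k + 2)
    return SobolDesign(N=N, k=k, rows=rows, matrix_id=matrix_id, base_index=base_index)


@dataclass(frozen=True)
class SensitivityResult:
    """Estimated Sobol indices for one model output.

    ``Si``/``STi`` are the raw Monte-Carlo estimates (they may stray slightly
    outside [0, 1]); ``Si_clamped``/``STi_clamped`` are clipped companions
    satisfying 0 <= Si <= STi <= 1 up to estimator error.  ``valid`` is False
    for degenerate (near-zero-variance) outputs, for which the indices are
    undefined (NaN).
    """

    Si: np.ndarray
    STi: np.ndarray
    V: float
    mean: float
    valid: bool

    @property
    def Si_clamped(self) -> np.ndarray:
        return np.clip(self.Si, 0.0, 1.0)

    @property
    def STi_clamped(self) -> np.ndarray:
        return np.clip(self.STi, 0.0, 1.0)


def estimate_indices(
    design: SobolDesign,
    y: Sequence[float],
    rel_var_tol: float = RELATIVE_VARIANCE_TOL,
) -> SensitivityResult:
    """Estimate first- and total-order Sobol indices from aligned outputs.

    ``y`` must hold one finite model output per design row, in design-row
    order.  S_i averages the Saltelli (2002) estimator over the two
    available pairings, (A, B_A^(i)) and (B, A_B^(i)), which share only
    column i; S_Ti uses the complementary pairings (A, A_B^(i)) and
    (B, B_A^(i)), which share all columns but i.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (design.M,):
        raise ValueError(f"y has shape {y.shape}, expected ({design.M},)")
    if not np.all(np.isfinite(y)):
        raise ValueError("model outputs must be finite")

    N, k = design.N, design.k
    yA = y[design.block("A")]
    yB = y[design.block("B")]
    yAB = np.stack([y[design.block(f"AB{i}")] for i in range(k)])
    yBA = np.stack([y[design.block(f"BA{i}")] for i in range(k)])

    both = np.concatenate([yA, yB])
    mean = float(both.mean())
    V = float(both.var(ddof=1))
    f0sq = mean * mean

    if V <= max(rel_var_tol * f0sq, ABSOLUTE_VARIANCE_FLOOR):
        nan = np.full(k, np.nan)
        return SensitivityResult(Si=nan, STi=nan.copy(), V=V, mean=mean, valid=False)

    # V_i  ~ <y_A y_BA_i> - f0^2   (shared column i only)
    Vi = 0.5 * ((yA * yBA).mean(axis=1) + (yB * yAB).mean(axis=1)) - f0sq
    # V_~i ~ <y_A y_AB_i> - f0^2   (all columns shared except i)
    Vmi = 0.5 * ((yA * yAB).mean(axis=1) + (yB * yBA).mean(axis=1)) - f0sq
    Si = Vi / V
    STi = 1.0 - Vmi / V
    return SensitivityResult(Si=Si, STi=STi, V=V, mean=mean, valid=True)


@dataclass(frozen=True)
class BruteForceDecomposition:
    """Exact variance decomposition of a function of discrete factors.

    ``partial_variances`` maps each non-empty factor subset (a sorted tuple
    of indices) to its partial variance V_u; their sum equals ``V`` exactly
    (conservation).  ``Si``/``STi`` are the exact indices.
    """

    V: float
    mean: float
    partial_variances: Mapping[tuple[int, ...], float]
    Si: np.ndarray
    STi: np.ndarray

    @property
    def k(self) -> int:
        return len(self.Si)


def brute_force_indices(
    func: Callable[..., float],
    levels: Sequence[Sequence[float]],
    max_points: int = 10**6,
) -> BruteForceDecomposition:
    """Exact Sobol decomposition by complete enumeration of a discrete grid.

    Each factor takes equiprobable values from its grid in ``levels``; the
    function is evaluated at every combination.  Partial variances come from
    conditional means by Moebius inversion over factor subsets:

        V_u = Var(E[Y | X_u]) - sum over proper non-empty subsets v of V_v

    Serves as the independent oracle for :func:`estimate_indices`.
    """
    grids = [np.asarray(g, dtype=float) for g in levels]
    k = len(grids)
    sizes = [g.size for g in grids]
    total = int(np.prod(sizes))
    if total > max_points:
        raise ValueError(f"grid of {total} points exceeds limit {max_points}")

    Y = np.empty(sizes)
    for idx in itertools.product(*(range(s) for s in sizes)):
        Y[idx] = func(*(g[i] for g, i in zip(grids, idx)))

    mean = float(Y.mean())
    V = float(Y.var())  # population variance: exact over the discrete measure

    # Var(E[Y | X_u]) for every non-empty subset u
    cond_var: dict[tuple[int, ...], float] = {}
    axes = tuple(range(k))
    for r in range(1, k + 1):
        for u in itertools.combinations(axes, r):
            other = tuple(a for a in axes if a not in u)
            cond_mean = Y.mean(axis=other) if other else Y
            cond_var[u] = float(np.mean((cond_mean - mean) ** 2))

    partial: dict[tuple[int, ...], float] = {}
    for r in range(1, k + 1):
        for u in itertools.combinations(axes, r):
            lower = sum(
                partial[v]
                for rr in range(1, r)
                for v in itertools.combinations(u, rr)
            )
            partial[u] = cond_var[u] - lower

    if V > 0:
        Si = np.array([partial[(i,)] / V for i in range(k)])
        STi = np.array(
            [sum(pv for u, pv in partial.items() if i in u) / V for i in range(k)]
        )
    else:
        Si = np.zeros(k)
        STi = np.zeros(k)
    return BruteForceDecomposition(
        V=V, mean=mean, partial_variances=partial, Si=Si, STi=STi
    )
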