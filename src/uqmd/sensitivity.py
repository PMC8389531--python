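"""Variance-based sensitivity analysis of the collocation surrogate.

The combination-technique surrogate is converted to a tensor-Legendre
polynomial chaos expansion, orthonormal under the uniform measure on the unit
hypercube.  Each tensor-product Lagrange interpolant of the plan is a
polynomial of per-dimension degree ``m_i - 1``, so its projection onto the
first ``m_i`` orthonormal Legendre polynomials per dimension is exact; the
signed combination coefficients then assemble the global expansion.

With orthonormal modes, Parseval's identity turns variance bookkeeping into
sums of squared coefficients: the total variance is the sum over all nonzero
degree tuples, and the partial variance of an input subset ``u`` collects the
tuples whose support (dimensions with nonzero degree) is exactly ``u``.
Normalizing gives the Sobol indices S_u = D_u / D, which sum to one over the
power set of inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Tuple

import numpy as np
from numpy.polynomial import legendre as npleg

from .quadrature import MultiIndex, Point, SparseGridPlan

__all__ = ["SobolReport", "to_orthogonal_expansion", "sobol_indices"]

DegreeTuple = Tuple[int, ...]
Subset = FrozenSet[int]

# aggregate all-order indices only up to this dimension; beyond it the power
# set explodes and only order <= 2 subsets are reported
_MAX_FULL_DIMENSION = 6


def _orthonormal_legendre_matrix(rule) -> np.ndarray:
    """Projection matrix A[k, j] = <P_k, L_j> on [0, 1].

    P_k is the orthonormal shifted Legendre polynomial of degree k and L_j the
    j-th cardinal polynomial of the quadrature rule.  Computed with a
    Gauss-Legendre rule exact for the integrand degree 2(m-1).
    """
    m = rule.size
    gx, gw = np.polynomial.legendre.leggauss(m)
    x = 0.5 * (gx + 1.0)  # unit interval
    w = 0.5 * gw
    # orthonormal shifted Legendre values, shape (m degrees, m quad points)
    P = np.stack(
        [
            np.sqrt(2 * k + 1) * npleg.legval(2.0 * x - 1.0, [0] * k + [1])
            for k in range(m)
        ]
    )
    # cardinal polynomial values, shape (m nodes, m quad points)
    from .quadrature import _basis_row

    L = np.stack([_basis_row(rule, xi) for xi in x], axis=1)
    return (P * w) @ L.T


def to_orthogonal_expansion(
    plan: SparseGridPlan, values: Mapping[Point, float]
) -> Dict[DegreeTuple, float]:
    """Coefficients of the surrogate in the orthonormal tensor-Legendre basis.

    Returns a map from multivariate polynomial degree tuples to coefficients;
    evaluating the expansion reproduces the surrogate everywhere (both are the
    same polynomial, re-expressed).
    """
    coeffs: Dict[DegreeTuple, float] = {}
    for l, c, grid in plan.active_grids():
        fvals = np.array([values[p] for p in grid.points]).reshape(grid.shape)
        block = fvals
        for axis, rule in enumerate(grid.rules):
            A = _orthonormal_legendre_matrix(rule)
            block = np.tensordot(A, block, axes=([1], [axis]))
            block = np.moveaxis(block, 0, axis)
        for deg in np.ndindex(block.shape):
            val = c * float(block[deg])
            if val != 0.0:
                coeffs[deg] = coeffs.get(deg, 0.0) + val
    return {k: v for k, v in coeffs.items() if abs(v) > 0.0}


def evaluate_expansion(coeffs: Mapping[DegreeTuple, float], x) -> float:
    """Evaluate a tensor-Legendre expansion at a unit-cube point (test helper)."""
    x = np.asarray(x, dtype=float)
    total = 0.0
    for deg, c in coeffs.items():
        term = c
        for k, xi in zip(deg, x):
            term *= np.sqrt(2 * k + 1) * npleg.legval(2.0 * xi - 1.0, [0] * k + [1])
        total += term
    return float(total)


@dataclass
class SobolReport:
    """Variance decomposition of the surrogate.

    ``indices`` maps input subsets (frozensets of 0-based dimension indices)
    to Sobol indices; ``first_order`` is the per-input vector S_i.  When the
    surrogate is constant the total variance is zero and the indices are
    undefined: ``defined`` is False and the maps are empty.
    """

    total_variance: float
    partial_variances: Dict[Subset, float] = field(default_factory=dict)
    indices: Dict[Subset, float] = field(default_factory=dict)
    first_order: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dimension: int = 0
    defined: bool = True
    max_order: int | None = None

    def to_dict(self) -> dict:
        return {
            "total_variance": self.total_variance,
            "defined": self.defined,
            "max_order": self.max_order,
            "first_order": list(map(float, self.first_order)),
            "indices": {
                ",".join(map(str, sorted(u))): float(s)
                for u, s in sorted(self.indices.items(), key=lambda kv: -kv[1])
            },
        }

    def to_frame(self):
        """Two-column DataFrame (subset, index), sorted by index descending."""
        import pandas as pd

        rows = [
            {"subset": "+".join(str(i) for i in sorted(u)), "index": s}
            for u, s in self.indices.items()
        ]
        return pd.DataFrame(rows).sort_values("index", ascending=False, ignore_index=True)


def sobol_indices(expansion: Mapping[DegreeTuple, float]) -> SobolReport:
    """Sobol indices from an orthonormal expansion via Parseval's identity."""
    if not expansion:
        raise ValueError("empty expansion")
    (d,) = {len(k) for k in expansion}
    max_order = None if d <= _MAX_FULL_DIMENSION else 2

    partial: Dict[Subset, float] = {}
    total = 0.0
    for deg, c in expansion.items():
        support = frozenset(i for i, k in enumerate(deg) if k > 0)
        if not support:
            continue
        total += c * c
        if max_order is None or len(support) <= max_order:
            partial[support] = partial.get(support, 0.0) + c * c

    if total <= 0.0:
        return SobolReport(
            total_variance=0.0,
            dimension=d,
            defined=False,
            first_order=np.zeros(d),
            max_order=max_order,
        )

    indices = {u: dv / total for u, dv in partial.items()}
    first = np.array([indices.get(frozenset({i}), 0.0) for i in range(d)])
    return SobolReport(
        total_variance=total,
        partial_variances=partial,
        indices=indices,
        first_order=first,
        dimension=d,
        defined=True,
        max_order=max_order,
    )
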