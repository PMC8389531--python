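"""Nested Clenshaw-Curtis rules, tensor grids and the sparse-grid combination technique.

Everything here lives on the unit hypercube ``[0, 1]^d`` with the uniform
probability measure: quadrature weights sum to one, and moments computed by
:func:`grid_moments` are moments with respect to independent uniform inputs.
Affine maps to physical parameter ranges are the responsibility of the input
space (see :mod:`uqmd.synthetic`).

A sparse sampling plan is represented by a downward-closed set of quadrature
*multi-indices* (one quadrature order per input dimension).  The surrogate is
the signed sum of tensor-product Lagrange interpolants

    I(x) = sum_{l in Lambda} c_l * I_l(x),

where the integer combination coefficients ``c_l`` telescope the hierarchy so
that nested full boxes collapse to a single tensor grid.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "Rule1D",
    "TensorGrid",
    "SparseGridPlan",
    "clenshaw_curtis_rule",
    "lagrange_basis",
    "tensor_grid",
    "combination_coefficients",
    "interpolate",
    "grid_moments",
    "rule_size",
]

MultiIndex = Tuple[int, ...]
Point = Tuple[float, ...]


def rule_size(level: int) -> int:
    """Number of points of the nested Clenshaw-Curtis rule at ``level``.

    The growth is 1, 3, 5, 9, 17, ...: a single midpoint at level 0 and
    ``2**level + 1`` points afterwards, which makes consecutive levels nested.
    """
    if level < 0:
        raise ValueError(f"quadrature level must be >= 0, got {level}")
    return 1 if level == 0 else 2**level + 1


@dataclass(frozen=True)
class Rule1D:
    """A one-dimensional quadrature rule on [0, 1].

    Attributes
    ----------
    level : int
        Hierarchical level ``l`` of the rule.
    points : ndarray
        Strictly increasing abscissae in [0, 1], symmetric about 0.5.
    weights : ndarray
        Quadrature weights for the uniform probability measure; sum to 1.
    """

    level: int
    points: np.ndarray
    weights: np.ndarray

    @property
    def size(self) -> int:
        return self.points.size

    def __post_init__(self) -> None:
        if self.points.size != self.weights.size:
            raise ValueError("points and weights must have equal length")


def _cc_weights_reference(n: int) -> np.ndarray:
    """Clenshaw-Curtis weights on [-1, 1] for ``n + 1`` cosine-spaced points.

    Classical cosine-sum formula; O(n^2) which is ample for the modest levels
    used in sparse grids.
    """
    if n == 0:
        return np.array([2.0])
    w = np.empty(n + 1)
    ks = np.arange(1, n // 2 + 1)
    factors = np.where(2 * ks == n, 0.5, 1.0)
    for j in range(n + 1):
        s = np.sum(factors * np.cos(2.0 * np.pi * ks * j / n) / (4.0 * ks**2 - 1.0))
        w[j] = (2.0 / n) * (1.0 - 2.0 * s)
    w[0] *= 0.5
    w[n] *= 0.5
    return w


def clenshaw_curtis_rule(level: int) -> Rule1D:
    """Nested Clenshaw-Curtis rule of the given level on the unit interval.

    Level 0 is the single midpoint with weight 1; level ``l >= 1`` has
    ``2**l + 1`` cosine-spaced points including both endpoints.  An ``m``-point
    rule integrates polynomials of degree ``<= m - 1`` exactly.  Point sets are
    nested across levels, bitwise: the level-``l`` points reappear unchanged in
    every finer rule.
    """
    m = rule_size(level)
    if m == 1:
        return Rule1D(level=0, points=np.array([0.5]), weights=np.array([1.0]))
    n = m - 1
    j = np.arange(m)
    pts = 0.5 * (1.0 - np.cos(np.pi * j / n))
    # enforce exact symmetry so that deduplication across levels is exact
    half = n // 2
    pts[half] = 0.5
    pts[n - np.arange(half)] = 1.0 - pts[np.arange(half)]
    w = 0.5 * _cc_weights_reference(n)  # renormalize [-1,1] length-2 measure to 1
    w = 0.5 * (w + w[::-1])  # symmetrize away rounding noise
    return Rule1D(level=level, points=pts, weights=w)


def lagrange_basis(rule: Rule1D, j: int, x: float) -> float:
    """Value at ``x`` of the ``j``-th cardinal (Lagrange) polynomial of ``rule``.

    Equals 1 at collocation point ``j`` and 0 at every other point of the rule.
    """
    if not 0 <= j < rule.size:
        raise ValueError(f"basis index {j} out of range for a {rule.size}-point rule")
    pts = rule.points
    num = 1.0
    for k in range(rule.size):
        if k != j:
            num *= (x - pts[k]) / (pts[j] - pts[k])
    return num


def _basis_row(rule: Rule1D, x: float) -> np.ndarray:
    """All cardinal polynomial values of ``rule`` at ``x`` as a vector."""
    pts = rule.points
    m = pts.size
    if m == 1:
        return np.array([1.0])
    diffs = x - pts
    hit = np.flatnonzero(diffs == 0.0)
    if hit.size:
        row = np.zeros(m)
        row[hit[0]] = 1.0
        return row
    # barycentric second form with Chebyshev-extrema weights
    bw = np.ones(m)
    bw[1::2] = -1.0
    bw[0] *= 0.5
    bw[-1] *= 0.5
    terms = bw / diffs
    return terms / terms.sum()


@dataclass(frozen=True)
class TensorGrid:
    """Full tensor product of 1D rules with per-dimension orders ``index``."""

    index: MultiIndex
    rules: Tuple[Rule1D, ...]

    @property
    def shape(self) -> Tuple[int, ...]:
        return tuple(r.size for r in self.rules)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    @property
    def points(self) -> list[Point]:
        """Row-major list of d-dimensional grid points."""
        axes = [r.points for r in self.rules]
        return [tuple(p) for p in itertools.product(*axes)]

    @property
    def weights(self) -> np.ndarray:
        """Product-rule weights, flattened row-major; sum to 1."""
        w = np.array([1.0])
        for r in self.rules:
            w = np.outer(w, r.weights).ravel()
        return w


def tensor_grid(index: MultiIndex) -> TensorGrid:
    """Build the tensor-product grid for one quadrature-order multi-index."""
    idx = tuple(int(i) for i in index)
    return TensorGrid(index=idx, rules=tuple(clenshaw_curtis_rule(l) for l in idx))


def _is_downward_closed(index_set: frozenset) -> bool:
    for l in index_set:
        for i, li in enumerate(l):
            if li > 0:
                back = l[:i] + (li - 1,) + l[i + 1 :]
                if back not in index_set:
                    return False
    return True


def combination_coefficients(
    index_set: Iterable[MultiIndex],
) -> Dict[MultiIndex, int]:
    """Combination-technique coefficients ``c_l`` for a downward-closed set.

    c_l = sum over z in {0,1}^d with l + z in the set of (-1)^|z|.
    The coefficients always sum to 1 (a telescoping partition of unity over
    the index hierarchy).
    """
    idx = frozenset(tuple(int(i) for i in l) for l in index_set)
    if not idx:
        raise ValueError("index set is empty")
    (d,) = {len(l) for l in idx}
    if not _is_downward_closed(idx):
        raise ValueError("index set is not admissible (downward closed)")
    # scan set members instead of the 2^d shift cube: k contributes to c_l
    # iff k - l is a 0/1 vector, with sign (-1)^{|k - l|}
    coeffs: Dict[MultiIndex, int] = {l: 0 for l in idx}
    members = list(idx)
    for l in members:
        c = 0
        for k in members:
            total = 0
            for a, b in zip(l, k):
                step = b - a
                if step < 0 or step > 1:
                    total = -1
                    break
                total += step
            if total >= 0:
                c += 1 if total % 2 == 0 else -1
        coeffs[l] = c
    return coeffs


@dataclass
class SparseGridPlan:
    """A sparse sampling plan: index set, combination coefficients, unique points.

    ``unique_points`` is the deduplicated union of the member tensor grids.
    Nesting of the 1D rules makes coincident points bitwise identical, so
    deduplication is exact coordinate equality.
    """

    index_set: frozenset
    coefficients: Dict[MultiIndex, int]
    unique_points: list
    dimension: int
    _grids: Dict[MultiIndex, TensorGrid] = field(default_factory=dict, repr=False)

    @classmethod
    def from_index_set(cls, index_set: Iterable[MultiIndex]) -> "SparseGridPlan":
        coeffs = combination_coefficients(index_set)
        idx = frozenset(coeffs)
        (d,) = {len(l) for l in idx}
        grids = {l: tensor_grid(l) for l in idx}
        seen: dict = {}
        for l in sorted(idx):
            for p in grids[l].points:
                seen.setdefault(p, None)
        return cls(
            index_set=idx,
            coefficients=coeffs,
            unique_points=list(seen),
            dimension=d,
            _grids=grids,
        )

    @property
    def n_points(self) -> int:
        return len(self.unique_points)

    def grid(self, l: MultiIndex) -> TensorGrid:
        if l not in self._grids:
            self._grids[l] = tensor_grid(l)
        return self._grids[l]

    def active_grids(self) -> list:
        """(multi-index, coefficient, grid) triples with nonzero coefficient."""
        return [
            (l, c, self.grid(l)) for l, c in sorted(self.coefficients.items()) if c != 0
        ]

    # ---- serialization -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "dimension": self.dimension,
            "index_set": sorted(list(l) for l in self.index_set),
            "coefficients": [
                {"index": list(l), "c": c} for l, c in sorted(self.coefficients.items())
            ],
            "points": [list(p) for p in self.unique_points],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SparseGridPlan":
        payload = json.loads(text)
        return cls.from_index_set(tuple(l) for l in payload["index_set"])

    def points_dataframe(self, names: Sequence[str]):
        """Unique points as a DataFrame with one column per input name."""
        import pandas as pd

        if len(names) != self.dimension:
            raise ValueError("one column name per dimension required")
        return pd.DataFrame(self.unique_points, columns=list(names))


def _require_values(plan: SparseGridPlan, values: Mapping[Point, float]) -> None:
    missing = [p for p in plan.unique_points if p not in values]
    if missing:
        raise KeyError(
            f"values missing for {len(missing)} plan point(s), e.g. {missing[0]}"
        )


def interpolate(
    plan: SparseGridPlan, values: Mapping[Point, float], x: Sequence[float]
) -> float:
    """Evaluate the combination-technique surrogate at ``x``.

    The surrogate is the signed sum of tensor-product Lagrange interpolants
    over the plan's index set; it reproduces the supplied values exactly at
    every collocation point of the plan.
    """
    _require_values(plan, values)
    x = tuple(float(xi) for xi in x)
    if len(x) != plan.dimension:
        raise ValueError(f"point has dimension {len(x)}, plan is {plan.dimension}-dim")
    total = 0.0
    for l, c, grid in plan.active_grids():
        rows = [_basis_row(r, xi) for r, xi in zip(grid.rules, x)]
        fvals = np.array([values[p] for p in grid.points]).reshape(grid.shape)
        contrib = fvals
        for axis, row in enumerate(rows):
            contrib = np.tensordot(row, contrib, axes=([0], [0]))
        total += c * float(contrib)
    return total


def sparse_quadrature(plan: SparseGridPlan, values: Mapping[Point, float]) -> float:
    """Integrate the surrogate over the uniform measure on the unit cube."""
    _require_values(plan, values)
    total = 0.0
    for l, c, grid in plan.active_grids():
        fv = np.array([values[p] for p in grid.points])
        total += c * float(grid.weights @ fv)
    return total


def grid_moments(
    plan: SparseGridPlan, values: Mapping[Point, float]
) -> Tuple[float, float]:
    """Mean and variance of the surrogate under independent uniform inputs.

    The mean is the sparse quadrature of the point values.  The variance is
    computed by sparse quadrature of the squared surrogate on the same plan
    (the surrogate interpolates the data on the union grid, so this is the
    quadrature of the squared point values), minus the squared mean, clipped
    at zero to absorb rounding.
    """
    mean = sparse_quadrature(plan, values)
    sq = {p: values[p] ** 2 for p in plan.unique_points}
    second = sparse_quadrature(plan, sq)
    return mean, max(second - mean**2, 0.0)


def evaluate_on_plan(
    plan: SparseGridPlan, f: Callable[[Point], float]
) -> Dict[Point, float]:
    """Convenience: tabulate a callable on the plan's unique points."""
    return {p: float(f(p)) for p in plan.unique_points}
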