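"""Dependency network analysis: correlation-influence computations.

The method quantifies the directed influence of each node of a
correlation network on every other node.  For a conditioning triple
``(i, k, j)`` the *correlation influence* of node ``j`` on the pair
``(i, k)`` is the part of the Pearson correlation ``C(i, k)`` that is
explained by ``j``::

    d(i, k | j) = C(i, k) - PC(i, k | j)

where ``PC`` is the first-order partial correlation.  Averaging
``d(i, k | j)`` over the remaining nodes ``k`` yields the asymmetric
dependency matrix ``D``, whose entry ``D(i, j)`` is the total influence
of node ``j`` on node ``i``.  Column sums of ``D`` give each node's
*Influencing Degree* (how much it drives the rest of the network's
correlation structure); row sums give its *Influenced Degree*.

Negative influences — suppressor configurations — are clipped to zero
by default, per triple, before averaging, so that a node's few negative
triples cannot cancel its positive ones; ``absolute`` and ``signed``
modes are provided for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .timeseries import NodeTimeSeries

__all__ = [
    "CorrelationMatrix",
    "DependencyMatrix",
    "DegreeProfile",
    "InfluenceTensor",
    "SingularTripleError",
    "compute_correlations",
    "partial_correlation",
    "correlation_influence",
    "compute_influence_tensor",
    "compute_dependency_matrix",
    "influencing_degree",
    "influenced_degree",
    "depna",
]

NegativeMode = Literal["clip_to_zero", "absolute", "signed"]
Divisor = Literal["n_minus_2", "n_minus_1", "n"]

#: Denominator floor below which a conditioning triple is declared singular.
SINGULAR_TOL = 1e-12
#: Opt-in screening margin: |C| above 1 - JITTER_TOL is treated as singular.
JITTER_TOL = 1e-9


class SingularTripleError(ValueError):
    """A partial correlation's denominator vanished (|C| = 1 with the
    conditioning node), so the triple is undefined."""


def _resolve_indices(node_ids: Sequence[str], key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    try:
        return list(node_ids).index(key)
    except ValueError:
        raise KeyError(f"unknown node {key!r}") from None


@dataclass(frozen=True, eq=False)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over labeled nodes."""

    node_ids: tuple[str, ...]
    values: np.ndarray

    def __init__(self, node_ids: Sequence[str], values: np.ndarray) -> None:
        node_ids = tuple(str(n) for n in node_ids)
        values = np.asarray(values, dtype=float)
        n = len(node_ids)
        if values.shape != (n, n):
            raise ValueError(f"expected ({n}, {n}) matrix, got {values.shape}")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-12, rtol=0.0):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.any(np.abs(values) > 1.0 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")
        # exact symmetry and bounds for downstream arithmetic
        values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(values, 1.0)
        object.__setattr__(self, "node_ids", node_ids)
        object.__setattr__(self, "values", values)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True, eq=False)
class DependencyMatrix:
    """Asymmetric influence matrix; ``values[i, j]`` is the influence of
    node ``j`` on node ``i``.  Diagonal is zero by construction."""

    node_ids: tuple[str, ...]
    values: np.ndarray
    negative_mode: NegativeMode = "clip_to_zero"

    def __init__(
        self,
        node_ids: Sequence[str],
        values: np.ndarray,
        negative_mode: NegativeMode = "clip_to_zero",
    ) -> None:
        node_ids = tuple(str(n) for n in node_ids)
        values = np.asarray(values, dtype=float)
        n = len(node_ids)
        if values.shape != (n, n):
            raise ValueError(f"expected ({n}, {n}) matrix, got {values.shape}")
        if np.any(np.diag(values) != 0.0):
            raise ValueError("dependency matrix diagonal must be zero")
        if negative_mode in ("clip_to_zero", "absolute") and np.any(values < 0):
            raise ValueError(f"negative entries under {negative_mode} mode")
        object.__setattr__(self, "node_ids", node_ids)
        object.__setattr__(self, "values", values.copy())
        object.__setattr__(self, "negative_mode", negative_mode)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True, eq=False)
class DegreeProfile:
    """Per-node Influencing and Influenced Degrees.

    Both vectors sum to the total mass of the dependency matrix they
    were derived from (column sums vs row sums of the same matrix).
    """

    node_ids: tuple[str, ...]
    influencing: np.ndarray
    influenced: np.ndarray

    def __init__(
        self,
        node_ids: Sequence[str],
        influencing: np.ndarray,
        influenced: np.ndarray,
    ) -> None:
        node_ids = tuple(str(n) for n in node_ids)
        influencing = np.asarray(influencing, dtype=float)
        influenced = np.asarray(influenced, dtype=float)
        n = len(node_ids)
        if influencing.shape != (n,) or influenced.shape != (n,):
            raise ValueError("degree vectors must have one entry per node")
        if abs(influencing.sum() - influenced.sum()) > 1e-10 * max(
            1.0, abs(influencing.sum())
        ):
            raise ValueError(
                "influencing and influenced degrees must share their total"
            )
        object.__setattr__(self, "node_ids", node_ids)
        object.__setattr__(self, "influencing", influencing)
        object.__setattr__(self, "influenced", influenced)


@dataclass(frozen=True, eq=False)
class InfluenceTensor:
    """Full triple-influence array ``values[i, k, j] = d(i, k | j)``.

    ``valid_mask`` flags entries whose three indices are pairwise
    distinct; everything else is undefined and stored as 0.  The tensor
    is O(N^3) — the dependency matrix never materializes it, but it is
    useful for edge-influence comparisons and diagnostics.
    """

    node_ids: tuple[str, ...]
    values: np.ndarray
    valid_mask: np.ndarray

    def influence_on_edge(self, i, k) -> np.ndarray:
        """Vector over conditioning nodes j of d(i, k | j); entries at
        j in {i, k} are NaN."""
        i = _resolve_indices(self.node_ids, i)
        k = _resolve_indices(self.node_ids, k)
        if i == k:
            raise ValueError("edge endpoints must differ")
        out = np.where(self.valid_mask[i, k], self.values[i, k], np.nan)
        return out


def compute_correlations(ts: NodeTimeSeries) -> CorrelationMatrix:
    """Pearson correlation of every node pair of a signal panel."""
    if ts.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for a correlation")
    dead = np.flatnonzero(ts.samples.var(axis=1) <= 0.0)
    if dead.size:
        names = [ts.node_ids[i] for i in dead]
        raise ValueError(f"zero-variance node(s): {names}")
    values = np.corrcoef(ts.samples)
    return CorrelationMatrix(ts.node_ids, values)


def partial_correlation(C: CorrelationMatrix, i, k, j) -> float:
    """First-order partial correlation of nodes i and k given node j.

    ``PC(i,k|j) = (C(i,k) - C(i,j) C(k,j)) / sqrt((1-C(i,j)^2)(1-C(k,j)^2))``
    """
    i = _resolve_indices(C.node_ids, i)
    k = _resolve_indices(C.node_ids, k)
    j = _resolve_indices(C.node_ids, j)
    if len({i, k, j}) != 3:
        raise ValueError(f"indices must be pairwise distinct, got {(i, k, j)}")
    V = C.values
    denom_sq = (1.0 - V[i, j] ** 2) * (1.0 - V[k, j] ** 2)
    denom = np.sqrt(max(denom_sq, 0.0))
    if denom < SINGULAR_TOL:
        raise SingularTripleError(
            f"triple (i={C.node_ids[i]}, k={C.node_ids[k]}, j={C.node_ids[j]}): "
            "|C| = 1 with the conditioning node, partial correlation undefined"
        )
    return float((V[i, k] - V[i, j] * V[k, j]) / denom)


def correlation_influence(C: CorrelationMatrix, i, k, j) -> float:
    """Influence of node j on the correlation C(i,k):
    ``d(i,k|j) = C(i,k) - PC(i,k|j)``."""
    i = _resolve_indices(C.node_ids, i)
    k = _resolve_indices(C.node_ids, k)
    j = _resolve_indices(C.node_ids, j)
    return float(C.values[i, k] - partial_correlation(C, i, k, j))


def _influence_slab(V: np.ndarray, j: int, screen_jitter: bool) -> np.ndarray:
    """All d(i, k | j) for one conditioning node j, as an (N, N) slab.

    Entries whose indices are not pairwise distinct are meaningless and
    left at whatever the formula yields; callers must mask them.
    """
    c = V[:, j]
    margin = 1.0 - c**2
    bound = JITTER_TOL if screen_jitter else 0.0
    bad = np.flatnonzero((margin <= bound) | (margin**2 < SINGULAR_TOL**2))
    bad = bad[bad != j]
    if bad.size:
        i = int(bad[0])
        raise SingularTripleError(
            f"conditioning node index {j}: node index {i} has |C| = 1 "
            f"(C = {c[i]:+.17g}) with it; triples (i, k | {j}) undefined"
        )
    denom = np.sqrt(np.outer(margin, margin))
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = (V - np.outer(c, c)) / denom
    slab = V - pc
    # entries involving j itself are undefined (denominator 0); zero them
    # so downstream sums skip them without masking
    slab[j, :] = 0.0
    slab[:, j] = 0.0
    return slab


def _apply_negative_mode(d: np.ndarray, mode: NegativeMode) -> np.ndarray:
    if mode == "clip_to_zero":
        return np.maximum(d, 0.0)
    if mode == "absolute":
        return np.abs(d)
    if mode == "signed":
        return d
    raise ValueError(f"unknown negative_mode {mode!r}")


def compute_influence_tensor(
    C: CorrelationMatrix,
    negative_mode: NegativeMode = "signed",
    screen_jitter: bool = False,
) -> InfluenceTensor:
    """Materialize every triple influence d(i, k | j).  O(N^3) memory."""
    n = C.n_nodes
    values = np.zeros((n, n, n))
    valid = np.zeros((n, n, n), dtype=bool)
    idx = np.arange(n)
    for j in range(n):
        slab = _influence_slab(C.values, j, screen_jitter)
        slab = _apply_negative_mode(slab, negative_mode)
        mask = np.ones((n, n), dtype=bool)
        mask[j, :] = False
        mask[:, j] = False
        mask[idx, idx] = False
        values[:, :, j] = np.where(mask, slab, 0.0)
        valid[:, :, j] = mask
    return InfluenceTensor(C.node_ids, values, valid)


def compute_dependency_matrix(
    C: CorrelationMatrix,
    negative_mode: NegativeMode = "clip_to_zero",
    divisor: Divisor = "n_minus_2",
    screen_jitter: bool = False,
) -> DependencyMatrix:
    """Average each node's triple influences into the dependency matrix.

    ``D(i, j)`` is the mean over valid conditioning targets
    ``k not in {i, j}`` of ``d(i, k | j)``, after applying
    ``negative_mode`` to each triple term.  The ``divisor`` convention
    controls the averaging denominator (``n_minus_2`` counts exactly the
    valid terms; ``n_minus_1`` and ``n`` are provided for comparison
    with conventions that keep degenerate triples in the count).
    Memory is O(N^2): the triple tensor is reduced one conditioning node
    at a time.
    """
    n = C.n_nodes
    if n < 3:
        raise ValueError("dependency matrix requires at least 3 nodes")
    denom = {"n_minus_2": n - 2, "n_minus_1": n - 1, "n": n}[divisor]
    V = C.values
    idx = np.arange(n)
    D = np.zeros((n, n))
    for j in range(n):
        slab = _apply_negative_mode(
            _influence_slab(V, j, screen_jitter), negative_mode
        )
        # sum over k excluding k == i and k == j, for every row i != j
        row_sum = slab.sum(axis=1) - slab[idx, idx] - slab[:, j]
        D[:, j] = row_sum / denom
        D[j, j] = 0.0
    return DependencyMatrix(C.node_ids, D, negative_mode)


def influencing_degree(D: DependencyMatrix) -> np.ndarray:
    """Column sums of D: node j's total outgoing influence."""
    return D.values.sum(axis=0)


def influenced_degree(D: DependencyMatrix) -> np.ndarray:
    """Row sums of D: node j's total incoming influence."""
    return D.values.sum(axis=1)


class DepnaDecomposition(NamedTuple):
    correlation: CorrelationMatrix
    dependency: DependencyMatrix
    degrees: DegreeProfile


def depna(
    ts: NodeTimeSeries,
    negative_mode: NegativeMode = "clip_to_zero",
    divisor: Divisor = "n_minus_2",
    screen_jitter: bool = False,
) -> DepnaDecomposition:
    """Run the full pipeline on one panel: correlations, dependency
    matrix, and both degree measures."""
    C = compute_correlations(ts)
    D = compute_dependency_matrix(C, negative_mode, divisor, screen_jitter)
    profile = DegreeProfile(
        ts.node_ids, influencing_degree(D), influenced_degree(D)
    )
    return DepnaDecomposition(C, D, profile)
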