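"""Two-condition comparison of dependency networks.

Per-subject dependency matrices and degree profiles from two
experimental conditions (or two groups) are compared with t statistics
at three granularities:

* **node degrees** — paired (or Welch) t per node and measure, corrected
  across nodes with Benjamini–Hochberg FDR (default q = 0.05);
* **dependency edges** — per ordered pair (i, j), Fisher-Z-transformed
  D(i, j) values compared across subjects, thresholded on raw p
  (default p < 0.001; 0.05 is the other convention in circulation) and
  returned as a directed graph with edge direction j -> i;
* **edge influences** — for one pair (i, k), the triple influences
  d(i, k | j) of every conditioning node j, FDR-corrected across the
  N - 2 influencers.

Sign convention: t > 0 means condition ``a`` exceeds condition ``b``.

Degrees are sums of dependencies and routinely exceed 1, so they are
tested on the raw scale; only dependency and influence coefficients
(correlation-like, bounded by 1) get the Fisher-Z variance-stabilizing
transform, with clipping just inside +/-1 to absorb boundary values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from . import core
from .core import NegativeMode
from .timeseries import NodeTimeSeries

__all__ = [
    "ConditionResults",
    "fisher_z",
    "bh_fdr",
    "paired_t",
    "compare_degrees",
    "compare_dependency_edges",
    "compare_edge_influences",
    "DEPNAComparison",
    "ComparisonResults",
]

#: Margin used to keep Fisher-Z inputs strictly inside (-1, 1).
FISHER_EPS = 1e-6


@dataclass(frozen=True, eq=False)
class ConditionResults:
    """Per-subject dependency analyses for one condition.

    Subjects are ordered; for paired comparisons the i-th subject of
    each condition must be the same individual.
    """

    label: str
    correlations: tuple[core.CorrelationMatrix, ...]
    dependencies: tuple[core.DependencyMatrix, ...]
    profiles: tuple[core.DegreeProfile, ...]
    node_ids: tuple[str, ...]
    negative_mode: NegativeMode = "clip_to_zero"

    def __post_init__(self) -> None:
        if len(self.dependencies) < 3:
            raise ValueError("need at least 3 subjects per condition")
        for D in self.dependencies:
            if D.node_ids != self.node_ids:
                raise ValueError("all subjects must share node labels")

    @property
    def n_subjects(self) -> int:
        return len(self.dependencies)

    @classmethod
    def from_panels(
        cls,
        label: str,
        panels: Sequence[NodeTimeSeries],
        negative_mode: NegativeMode = "clip_to_zero",
    ) -> "ConditionResults":
        """Run the dependency analysis on one panel per subject."""
        cors, deps, profs = [], [], []
        for panel in panels:
            C, D, prof = core.depna(panel, negative_mode)
            cors.append(C)
            deps.append(D)
            profs.append(prof)
        return cls(
            label,
            tuple(cors),
            tuple(deps),
            tuple(profs),
            tuple(panels[0].node_ids),
            negative_mode,
        )

    def degree_array(self, measure: str) -> np.ndarray:
        """(n_subjects, n_nodes) array of one degree measure."""
        if measure not in ("influencing", "influenced"):
            raise ValueError(f"unknown measure {measure!r}")
        return np.array([getattr(p, measure) for p in self.profiles])

    def dependency_array(self) -> np.ndarray:
        """(n_subjects, n_nodes, n_nodes) stack of dependency matrices."""
        return np.array([D.values for D in self.dependencies])

    def edge_influence_array(self, i, k) -> np.ndarray:
        """(n_subjects, n_nodes) array of d(i, k | j) per conditioning
        node j; columns at j in {i, k} are NaN."""
        i = core._resolve_indices(self.node_ids, i)
        k = core._resolve_indices(self.node_ids, k)
        if i == k:
            raise ValueError("edge endpoints must differ")
        rows = []
        for C in self.correlations:
            vals = np.full(len(self.node_ids), np.nan)
            for j in range(len(self.node_ids)):
                if j in (i, k):
                    continue
                vals[j] = core.correlation_influence(C, i, k, j)
            if self.negative_mode == "clip_to_zero":
                vals = np.maximum(vals, 0.0)
            elif self.negative_mode == "absolute":
                vals = np.abs(vals)
            rows.append(vals)
        return np.array(rows)


def fisher_z(values) -> np.ndarray:
    """Fisher variance-stabilizing transform arctanh(x), with inputs
    clipped to +/-(1 - 1e-6) so boundary values stay finite."""
    values = np.asarray(values, dtype=float)
    return np.arctanh(np.clip(values, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS))


def bh_fdr(p_values, q_threshold: float = 0.05):
    """Benjamini–Hochberg step-up FDR correction.

    Returns (adjusted q values, boolean rejection flags at
    ``q_threshold``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, reject


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired two-tailed t test of a - b.

    Zero variance of the differences with zero mean (identical inputs)
    yields (0, 1) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    if np.ptp(diff) == 0.0:
        if diff[0] == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff[0]) * np.inf), 0.0
    t, p = sp_stats.ttest_rel(a, b)
    return float(t), float(p)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample two-tailed t test (unpaired group designs)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sp_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _check_matched(a: ConditionResults, b: ConditionResults, paired: bool):
    if a.node_ids != b.node_ids:
        raise ValueError("conditions must share node labels")
    if paired and a.n_subjects != b.n_subjects:
        raise ValueError(
            "paired design needs equal subject counts "
            f"({a.n_subjects} vs {b.n_subjects})"
        )


def _test(paired: bool):
    return paired_t if paired else welch_t


def compare_degrees(
    a: ConditionResults,
    b: ConditionResults,
    measure: Literal["influencing", "influenced"] = "influencing",
    q_threshold: float = 0.05,
    paired: bool = True,
) -> pd.DataFrame:
    """Per-node degree comparison with BH-FDR across nodes.

    t > 0 means the degree is higher in condition ``a``.
    """
    _check_matched(a, b, paired)
    xa = a.degree_array(measure)
    xb = b.degree_array(measure)
    stats = [_test(paired)(xa[:, r], xb[:, r]) for r in range(xa.shape[1])]
    t = np.array([s[0] for s in stats])
    p = np.array([s[1] for s in stats])
    q, reject = bh_fdr(p, q_threshold)
    return pd.DataFrame(
        {
            "node": list(a.node_ids),
            "measure": measure,
            "t": t,
            "p": p,
            "q": q,
            "significant": reject,
        }
    )


def compare_dependency_edges(
    a: ConditionResults,
    b: ConditionResults,
    p_threshold: float = 0.001,
    paired: bool = True,
) -> tuple[pd.DataFrame, nx.DiGraph]:
    """Per-edge dependency comparison on Fisher-Z values.

    Each ordered pair (i, j) — the influence of j on i — is tested
    across subjects; pairs passing the raw-p threshold become directed
    graph edges j -> i carrying the signed t.
    """
    _check_matched(a, b, paired)
    za = fisher_z(a.dependency_array())
    zb = fisher_z(b.dependency_array())
    n = len(a.node_ids)
    rows = []
    graph = nx.DiGraph()
    graph.add_nodes_from(a.node_ids)
    test = _test(paired)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            t, p = test(za[:, i, j], zb[:, i, j])
            passed = bool(p < p_threshold)
            rows.append(
                (a.node_ids[i], a.node_ids[j], t, p, passed)
            )
            if passed:
                graph.add_edge(
                    a.node_ids[j], a.node_ids[i], t=t, p=p,
                    sign=int(np.sign(t)),
                )
    table = pd.DataFrame(
        rows, columns=["target_i", "influencer_j", "t", "p", "pass"]
    )
    return table, graph


def compare_edge_influences(
    a: ConditionResults,
    b: ConditionResults,
    edge: tuple,
    q_threshold: float = 0.05,
    paired: bool = True,
) -> pd.DataFrame:
    """Which nodes' influence on the correlation of one pair (i, k)
    differs between conditions; BH-FDR across the N - 2 influencers."""
    _check_matched(a, b, paired)
    i, k = edge
    da = fisher_z(a.edge_influence_array(i, k))
    db = fisher_z(b.edge_influence_array(i, k))
    ii = core._resolve_indices(a.node_ids, i)
    kk = core._resolve_indices(a.node_ids, k)
    influencers = [
        j for j in range(len(a.node_ids)) if j not in (ii, kk)
    ]
    test = _test(paired)
    stats = [test(da[:, j], db[:, j]) for j in influencers]
    t = np.array([s[0] for s in stats])
    p = np.array([s[1] for s in stats])
    q, reject = bh_fdr(p, q_threshold)
    return pd.DataFrame(
        {
            "edge_i": a.node_ids[ii],
            "edge_k": a.node_ids[kk],
            "influencer_j": [a.node_ids[j] for j in influencers],
            "t": t,
            "p": p,
            "q": q,
            "pass": reject,
        }
    )


class DEPNAComparison:
    """Model object for a two-condition dependency-network comparison.

    Parameters
    ----------
    a, b : ConditionResults or sequences of NodeTimeSeries
        The two conditions; sequences of panels (one per subject) are
        analysed on construction.
    paired : bool
        Paired within-subject design (default) or unpaired Welch tests.
    """

    def __init__(
        self,
        a,
        b,
        paired: bool = True,
        negative_mode: NegativeMode = "clip_to_zero",
        labels: tuple[str, str] = ("a", "b"),
    ) -> None:
        if not isinstance(a, ConditionResults):
            a = ConditionResults.from_panels(labels[0], a, negative_mode)
        if not isinstance(b, ConditionResults):
            b = ConditionResults.from_panels(labels[1], b, negative_mode)
        _check_matched(a, b, paired)
        self.a = a
        self.b = b
        self.paired = paired

    def fit(
        self, fdr_q: float = 0.05, edge_p: float = 0.001
    ) -> "ComparisonResults":
        node_tables = [
            compare_degrees(self.a, self.b, m, fdr_q, self.paired)
            for m in ("influencing", "influenced")
        ]
        edge_table, graph = compare_dependency_edges(
            self.a, self.b, edge_p, self.paired
        )
        return ComparisonResults(
            self, pd.concat(node_tables, ignore_index=True), edge_table,
            graph, fdr_q, edge_p,
        )


class ComparisonResults:
    """Fitted comparison: node-degree table, edge table, edge graph."""

    def __init__(self, model, node_table, edge_table, graph, fdr_q, edge_p):
        self.model = model
        self.node_table = node_table
        self.edge_table = edge_table
        self.graph = graph
        self.fdr_q = fdr_q
        self.edge_p = edge_p
        self.node_ids = list(model.a.node_ids)

    def edge_influences(self, edge: tuple, q_threshold: float | None = None):
        """Influencer comparison for one pair, FDR across influencers."""
        return compare_edge_influences(
            self.model.a, self.model.b, edge,
            self.fdr_q if q_threshold is None else q_threshold,
            self.model.paired,
        )

    def significant_nodes(self) -> pd.DataFrame:
        return self.node_table[self.node_table["significant"]]

    def summary(self) -> str:
        sig = self.significant_nodes()
        lines = [
            "Dependency Network Comparison "
            f"({self.model.a.label} vs {self.model.b.label}, "
            f"{'paired' if self.model.paired else 'Welch'} t)",
            f"  subjects: {self.model.a.n_subjects} vs "
            f"{self.model.b.n_subjects}   nodes: {len(self.node_ids)}",
            f"  node FDR q <= {self.fdr_q}; edge raw p < {self.edge_p}",
            "",
            "Significant node degrees:"
            if len(sig) else "Significant node degrees: none",
        ]
        if len(sig):
            lines.append(sig.round(4).to_string(index=False))
        n_edges = int(self.edge_table["pass"].sum())
        lines.append(f"Edges passing p < {self.edge_p}: {n_edges}")
        return "\n".join(lines)
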