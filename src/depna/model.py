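"""Model/results interface to dependency network analysis.

``DEPNA`` wraps a signal panel the way statistical modelling packages
wrap a design matrix: construct it from data, call :meth:`DEPNA.fit`,
and read estimates off the returned :class:`DEPNAResults` object.

Example
-------
>>> import numpy as np
>>> from depna import DEPNA
>>> rng = np.random.default_rng(0)
>>> x = rng.standard_normal((4, 200))
>>> res = DEPNA(x, node_ids=["A", "B", "C", "D"]).fit()
>>> res.influencing_degree.round(3)  # doctest: +SKIP
A    0.1...
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import core
from .core import (
    CorrelationMatrix,
    DegreeProfile,
    DependencyMatrix,
    Divisor,
    NegativeMode,
)
from .timeseries import NodeTimeSeries

__all__ = ["DEPNA", "DEPNAResults"]


class DEPNA:
    """Dependency network analysis of one node-by-timepoint panel.

    Parameters
    ----------
    data : NodeTimeSeries, DataFrame, or (n_nodes, n_timepoints) array
        The signal panel.  DataFrames are read with nodes as columns.
    node_ids : sequence of str, optional
        Labels for array input; defaults to ``n0, n1, ...``.
    negative_mode : {"clip_to_zero", "absolute", "signed"}
        Treatment of negative (suppressor) triple influences before
        averaging.  The default resets them to zero.
    divisor : {"n_minus_2", "n_minus_1", "n"}
        Averaging denominator for the dependency matrix; the default
        counts exactly the valid conditioning targets.
    """

    def __init__(
        self,
        data,
        node_ids: Sequence[str] | None = None,
        negative_mode: NegativeMode = "clip_to_zero",
        divisor: Divisor = "n_minus_2",
        screen_jitter: bool = False,
        sampling_interval: float | None = None,
    ) -> None:
        if isinstance(data, NodeTimeSeries):
            ts = data
        elif isinstance(data, pd.DataFrame):
            ts = NodeTimeSeries.from_dataframe(data, sampling_interval)
        else:
            arr = np.asarray(data, dtype=float)
            if node_ids is None:
                node_ids = [f"n{i}" for i in range(arr.shape[0])]
            ts = NodeTimeSeries(node_ids, arr, sampling_interval)
        self.data = ts
        self.negative_mode: NegativeMode = negative_mode
        self.divisor: Divisor = divisor
        self.screen_jitter = screen_jitter

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, nodes_as_columns: bool = True, **kwargs
    ) -> "DEPNA":
        ts = NodeTimeSeries.from_dataframe(
            frame, nodes_as_columns=nodes_as_columns
        )
        return cls(ts, **kwargs)

    def fit(self) -> "DEPNAResults":
        """Compute correlations, the dependency matrix and both degrees."""
        C, D, profile = core.depna(
            self.data, self.negative_mode, self.divisor, self.screen_jitter
        )
        return DEPNAResults(self, C, D, profile)


class DEPNAResults:
    """Fitted dependency network: correlation matrix, dependency matrix,
    Influencing and Influenced Degrees, and summaries thereof."""

    def __init__(
        self,
        model: DEPNA,
        correlation: CorrelationMatrix,
        dependency: DependencyMatrix,
        degrees: DegreeProfile,
    ) -> None:
        self.model = model
        self.correlation_matrix = correlation
        self.dependency_matrix = dependency
        self.degrees = degrees
        self.node_ids = list(correlation.node_ids)

    @property
    def correlation(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.correlation_matrix.values,
            index=self.node_ids,
            columns=self.node_ids,
        )

    @property
    def dependency(self) -> pd.DataFrame:
        """``dependency.loc[i, j]`` is the influence of node j on node i."""
        return pd.DataFrame(
            self.dependency_matrix.values,
            index=self.node_ids,
            columns=self.node_ids,
        )

    @property
    def influencing_degree(self) -> pd.Series:
        return pd.Series(
            self.degrees.influencing, index=self.node_ids, name="influencing"
        )

    @property
    def influenced_degree(self) -> pd.Series:
        return pd.Series(
            self.degrees.influenced, index=self.node_ids, name="influenced"
        )

    def influence_tensor(self) -> core.InfluenceTensor:
        """Materialize every triple influence d(i, k | j) (O(N^3))."""
        return core.compute_influence_tensor(
            self.correlation_matrix,
            self.model.negative_mode,
            self.model.screen_jitter,
        )

    def degree_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "influencing": self.degrees.influencing,
                "influenced": self.degrees.influenced,
            },
            index=pd.Index(self.node_ids, name="node"),
        )

    def summary(self) -> str:
        table = self.degree_table().sort_values(
            "influencing", ascending=False
        )
        lines = [
            "Dependency Network Analysis",
            f"  nodes: {len(self.node_ids)}   "
            f"timepoints: {self.model.data.n_timepoints}   "
            f"negative mode: {self.dependency_matrix.negative_mode}",
            "",
            table.round(4).to_string(),
        ]
        return "\n".join(lines)

    def plot_dependency(self, ax=None):
        """Heat map of the dependency matrix (influencer on x-axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.dependency_matrix.values, cmap="viridis")
        ax.set_xticks(range(len(self.node_ids)), self.node_ids, rotation=90)
        ax.set_yticks(range(len(self.node_ids)), self.node_ids)
        ax.set_xlabel("influencing node j")
        ax.set_ylabel("influenced node i")
        ax.figure.colorbar(im, ax=ax, label="D(i, j)")
        return ax
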