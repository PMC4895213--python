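"""Labeled node-by-timepoint signal panels.

A :class:`NodeTimeSeries` holds the multivariate signal that dependency
network analysis operates on: one row per network node (e.g. an fMRI
region of interest), one column per timepoint.  The container validates
the minimal requirements of the analysis — at least three nodes (a
partial correlation needs a conditioning triple), at least three
timepoints, and strictly positive variance in every row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["NodeTimeSeries"]


@dataclass(frozen=True, eq=False)
class NodeTimeSeries:
    """A labeled panel of node signals.

    Parameters
    ----------
    node_ids : sequence of str
        Unique labels, one per row of ``samples``.
    samples : ndarray, shape (n_nodes, n_timepoints)
        Signal values; every row must have strictly positive variance.
    sampling_interval : float, optional
        Seconds between consecutive samples (the fMRI TR), if known.
    require_variance : bool
        If True (default) reject rows with zero variance.  Simulated
        noise-free panels may legitimately be flat; they are rejected
        again, with the node named, when correlations are computed.
    """

    node_ids: tuple[str, ...]
    samples: np.ndarray
    sampling_interval: float | None = None

    def __init__(
        self,
        node_ids: Sequence[str],
        samples: np.ndarray,
        sampling_interval: float | None = None,
        require_variance: bool = True,
    ) -> None:
        node_ids = tuple(str(n) for n in node_ids)
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError(f"samples must be 2-D, got shape {samples.shape}")
        n_nodes, n_time = samples.shape
        if len(node_ids) != n_nodes:
            raise ValueError(
                f"{len(node_ids)} node_ids for {n_nodes} signal rows"
            )
        if len(set(node_ids)) != len(node_ids):
            dupes = sorted({n for n in node_ids if node_ids.count(n) > 1})
            raise ValueError(f"duplicate node labels: {dupes}")
        if n_nodes < 3:
            raise ValueError(
                "dependency analysis requires at least 3 nodes "
                f"(got {n_nodes}): a conditioning triple is needed"
            )
        if n_time < 3:
            raise ValueError(f"need at least 3 timepoints, got {n_time}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if require_variance:
            variances = samples.var(axis=1)
            dead = np.flatnonzero(variances <= 0.0)
            if dead.size:
                names = [node_ids[i] for i in dead]
                raise ValueError(f"zero-variance node(s): {names}")
        if sampling_interval is not None and sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        object.__setattr__(self, "node_ids", node_ids)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sampling_interval", sampling_interval)

    @property
    def n_nodes(self) -> int:
        return self.samples.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        sampling_interval: float | None = None,
        nodes_as_columns: bool = True,
    ) -> "NodeTimeSeries":
        """Build from a DataFrame (default orientation: columns are nodes)."""
        values = frame.to_numpy(dtype=float)
        if nodes_as_columns:
            return cls(list(map(str, frame.columns)), values.T, sampling_interval)
        return cls(list(map(str, frame.index)), values, sampling_interval)

    def to_dataframe(self) -> pd.DataFrame:
        """Timepoints as rows, nodes as columns."""
        return pd.DataFrame(self.samples.T, columns=list(self.node_ids))

    def reorder(self, node_ids: Sequence[str]) -> "NodeTimeSeries":
        """Return a copy with rows permuted into the given label order."""
        index = {n: i for i, n in enumerate(self.node_ids)}
        try:
            rows = [index[str(n)] for n in node_ids]
        except KeyError as exc:
            raise KeyError(f"unknown node label {exc.args[0]!r}") from None
        if len(rows) != self.n_nodes:
            raise ValueError("reorder must use every node exactly once")
        return NodeTimeSeries(
            [str(n) for n in node_ids],
            self.samples[rows],
            self.sampling_interval,
        )
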