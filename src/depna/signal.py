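"""Signal preparation: ROI summary time courses and block handling.

These are the generic preprocessing steps between voxel-level data and
the node-by-timepoint panels the dependency analysis consumes: reducing
an ROI's voxel matrix to its principal eigenvariate, and averaging the
repeated blocks of one condition into a single panel.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .timeseries import NodeTimeSeries

__all__ = [
    "principal_eigenvariate",
    "average_condition_blocks",
    "concatenate_blocks",
]


def principal_eigenvariate(voxel_matrix: np.ndarray) -> np.ndarray:
    """First-principal-component summary time course of an ROI.

    The voxel-by-timepoint matrix is row-centered and decomposed by
    SVD; the first right singular vector, scaled by its singular value
    over sqrt(n_voxels), is returned with its sign chosen so that it
    correlates nonnegatively with the mean voxel time course.
    """
    X = np.asarray(voxel_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(
            f"need a 2-D matrix with >= 2 voxels and >= 2 timepoints, "
            f"got shape {X.shape}"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        raise ValueError("voxel matrix has no variance")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    course = vt[0] * (s[0] / np.sqrt(X.shape[0]))
    mean_course = Xc.mean(axis=0)
    if float(course @ mean_course) < 0:
        course = -course
    return course


def _check_stackable(panels: Sequence[NodeTimeSeries]) -> None:
    if not panels:
        raise ValueError("no panels given")
    first = panels[0]
    for p in panels[1:]:
        if p.node_ids != first.node_ids:
            raise ValueError("panels must share node labels")
        if p.n_timepoints != first.n_timepoints:
            raise ValueError(
                "panels must share timepoint count "
                f"({p.n_timepoints} vs {first.n_timepoints})"
            )


def average_condition_blocks(
    panels: Sequence[NodeTimeSeries],
) -> NodeTimeSeries:
    """Pointwise mean of equal-length blocks of one condition.

    Averaging raises SNR by sqrt(n_blocks) for a deterministic
    block-locked signal.  The result may legitimately be flat (e.g.
    blocks cancelling); it is rejected downstream when correlations are
    computed.
    """
    _check_stackable(panels)
    mean = np.mean([p.samples for p in panels], axis=0)
    return NodeTimeSeries(
        panels[0].node_ids,
        mean,
        panels[0].sampling_interval,
        require_variance=False,
    )


def concatenate_blocks(panels: Sequence[NodeTimeSeries]) -> NodeTimeSeries:
    """Concatenate blocks along time (alternative to averaging)."""
    _check_stackable(panels)
    return NodeTimeSeries(
        panels[0].node_ids,
        np.concatenate([p.samples for p in panels], axis=1),
        panels[0].sampling_interval,
        require_variance=False,
    )
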