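"""Cluster-free L1 geometry of a subject's IPS evolution.

Hard state assignment collapses every sample onto a single label; the
trajectory view instead follows the raw sequence of P-dimensional IPS
vectors and summarizes its path with five L1 measures:

* ``length``   — total L1 distance between successive samples;
* ``span``     — maximum L1 distance over all sample pairs;
* ``capacity`` — mean L1 distance over all unordered sample pairs;
* ``efficiency`` — capacity / length (diverse patterns per unit path);
* ``smoothness`` — mean reciprocal of consecutive L1 distances.

The L1 norm is preferred over L2 in this high-dimensional setting
(P = 1225 for 50 components).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist

from .containers import IPSSeries, TrajectoryMetrics

__all__ = ["l1_distance", "trajectory_metrics"]


def l1_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Sum of absolute coordinate differences."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    return float(np.abs(u - v).sum())


def trajectory_metrics(
    ips: IPSSeries | np.ndarray, epsilon: float = 1e-6
) -> TrajectoryMetrics:
    """All five L1 trajectory measures of one session.

    Consecutive distances below ``epsilon`` are floored at ``epsilon`` for
    the smoothness reciprocal and counted in ``n_floored`` (a warning is
    issued); a fully constant trajectory yields length 0, span 0 and a
    flagged degenerate smoothness of ``1/epsilon``.
    """
    x = ips.ips if isinstance(ips, IPSSeries) else np.asarray(ips, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("trajectory needs at least 3 samples")
    step = np.abs(np.diff(x, axis=0)).sum(axis=1)
    pair = pdist(x, metric="cityblock")
    length = float(step.sum())
    span = float(pair.max())
    capacity = float(pair.mean())
    efficiency = capacity / length if length > 0 else np.nan
    floored = step < epsilon
    n_floored = int(floored.sum())
    if n_floored:
        warnings.warn(
            f"{n_floored} consecutive distance(s) below epsilon floored",
            stacklevel=2,
        )
    smoothness = float((1.0 / np.maximum(step, epsilon)).mean())
    return TrajectoryMetrics(
        length=length,
        span=span,
        capacity=capacity,
        efficiency=float(efficiency),
        smoothness=smoothness,
        n_samples=n,
        n_floored=n_floored,
    )
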