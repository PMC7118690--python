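"""Core in-memory containers shared by all pipeline stages.

Conventions
-----------
* Time-course data is a ``T x C`` float array (T samples, C network components).
* Pairwise quantities over the C components are stored as length
  ``P = C*(C-1)/2`` vectors in row-major upper-triangle order
  ``(0,1),(0,2),...,(0,C-1),(1,2),...`` — the same ordering everywhere.
* State labels are 1-based integers (state 1 is the most prevalent one after
  relabelling); metastate labels are 1 or 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimecourseSet",
    "AnalyticSeries",
    "IPSSeries",
    "SFNCResult",
    "StateModel",
    "TemporalProfile",
    "MetastatePartition",
    "TrajectoryMetrics",
]


@dataclass
class TimecourseSet:
    """One subject's network time courses.

    Parameters
    ----------
    subject_id : str
    data : ndarray, shape (T, C)
        Real-valued component time courses (arbitrary units).
    tr : float
        Sampling interval in seconds.
    component_labels : list of str, optional
        One label per component; generated as ``c001..`` when omitted.
    module_map : ndarray of int, shape (C,), optional
        Assignment of each component to a functional network (1-based).
    motion_params : ndarray, shape (T, 6), optional
        Realignment parameters: x, y, z translations (mm) then pitch, roll,
        yaw rotations (radians).
    group : int, optional
        Group label (0 or 1).
    covariates : dict, optional
        Per-subject scalars such as ``age``, ``sex``, ``mfd``.
    """

    subject_id: str
    data: np.ndarray
    tr: float
    component_labels: list[str] | None = None
    module_map: np.ndarray | None = None
    motion_params: np.ndarray | None = None
    group: int | None = None
    covariates: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x C matrix")
        t, c = self.data.shape
        if t < 2 or c < 2:
            raise ValueError(f"need T >= 2 and C >= 2, got T={t}, C={c}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-course data contains non-finite entries")
        if self.component_labels is None:
            self.component_labels = [f"c{i + 1:03d}" for i in range(c)]
        if len(self.component_labels) != c:
            raise ValueError("component_labels length must equal C")
        if self.module_map is not None:
            self.module_map = np.asarray(self.module_map, dtype=int)
            if self.module_map.shape != (c,):
                raise ValueError("module_map must assign every component")
        if self.motion_params is not None:
            self.motion_params = np.asarray(self.motion_params, dtype=float)
            if self.motion_params.shape != (t, 6):
                raise ValueError("motion_params must be T x 6")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "TimecourseSet":
        """Return a copy of this set carrying new data but the same metadata."""
        return TimecourseSet(
            subject_id=self.subject_id,
            data=np.asarray(data, dtype=float),
            tr=self.tr,
            component_labels=list(self.component_labels),
            module_map=None if self.module_map is None else self.module_map.copy(),
            motion_params=None
            if self.motion_params is None
            else self.motion_params.copy(),
            group=self.group,
            covariates=None if self.covariates is None else dict(self.covariates),
        )


@dataclass
class AnalyticSeries:
    """Analytic (complex) representation of a set of narrowband time courses.

    ``envelope`` is the instantaneous amplitude and ``phase`` the
    four-quadrant instantaneous phase in (-pi, pi]. Columns whose envelope is
    identically zero carry an undefined phase and are flagged in
    ``undefined_columns``.
    """

    real_part: np.ndarray
    imag_part: np.ndarray
    envelope: np.ndarray
    phase: np.ndarray
    tr: float
    subject_id: str = ""
    undefined_columns: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


@dataclass
class IPSSeries:
    """Per-subject instantaneous phase synchrony, one P-vector per sample.

    ``ips[t, k]`` is the cosine of the phase difference of component pair
    ``pair_index[k]`` at sample ``t``; all entries lie in [-1, 1].
    """

    subject_id: str
    ips: np.ndarray
    pair_index: list[tuple[int, int]]
    tr: float
    group: int | None = None

    def __post_init__(self) -> None:
        self.ips = np.asarray(self.ips, dtype=float)
        if self.ips.ndim != 2 or self.ips.shape[1] != len(self.pair_index):
            raise ValueError("ips must be T x P with P matching pair_index")

    @property
    def n_samples(self) -> int:
        return self.ips.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.ips.shape[1]


@dataclass
class SFNCResult:
    """Static functional network connectivity: correlations and Fisher z."""

    r: np.ndarray
    z: np.ndarray
    undefined: np.ndarray | None = None  # boolean mask of zero-variance components


@dataclass
class StateModel:
    """Clustering solution over the pooled cohort of IPS samples."""

    k: int
    centroids: np.ndarray  # k x P mean IPS vectors
    labels: np.ndarray  # pooled hard assignments, 1..k
    sample_index: list[tuple[str, int]]  # (subject_id, t) per pooled row
    db_scores: dict[int, float]
    embedding_dim: int
    seed: int

    def labels_for(self, subject_id: str) -> np.ndarray:
        """State-label sequence of one subject, in time order."""
        idx = [i for i, (sid, _) in enumerate(self.sample_index) if sid == subject_id]
        return self.labels[idx]


@dataclass
class TemporalProfile:
    """State-sequence summary for one subject (or one metastate sequence).

    ``transition`` rows of states never visited are NaN; ``persistence`` is in
    seconds (mean uninterrupted run length times the sampling interval).
    """

    prevalence: np.ndarray
    persistence: np.ndarray
    transition: np.ndarray
    dwell: np.ndarray
    n_samples: int
    tr: float


@dataclass
class MetastatePartition:
    """Two-way partition of the state repertoire from the transition graph."""

    partition: np.ndarray  # length K, entries 1 or 2
    fiedler_vector: np.ndarray
    ms_profiles: np.ndarray | None = None  # 2 x P mean IPS vectors
    cophenetic_coefficient: float | None = None
    network_profiles: np.ndarray | None = None  # 2 x 28 network couplings

    def members(self, ms: int) -> np.ndarray:
        return np.flatnonzero(self.partition == ms) + 1


@dataclass
class TrajectoryMetrics:
    """L1 geometry of one subject's IPS evolution."""

    length: float
    span: float
    capacity: float
    efficiency: float
    smoothness: float
    n_samples: int
    n_floored: int = 0  # consecutive distances clamped to the epsilon floor

    def as_dict(self) -> dict[str, float]:
        return {
            "length": self.length,
            "span": self.span,
            "capacity": self.capacity,
            "efficiency": self.efficiency,
            "smoothness": self.smoothness,
        }
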