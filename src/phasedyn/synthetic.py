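"""Synthetic cohorts of phase-coupled network time series with planted truth.

The generator is a stand-in for a resting-state cohort whose inter-network
coupling is organised as a small repertoire of phase-coupling *states*: each
state k fixes a phase offset ``theta[k, c]`` per component, a hidden Markov
chain over states drives which offset pattern is active at each sample, and
every component oscillates on a shared narrowband carrier. By construction
the noise-free instantaneous phase synchrony of state k between components
p and q is ``cos(theta[k, p] - theta[k, q])``, so every downstream stage has
an analytic ground truth.

The transition matrix is block structured: states split into two *metastates*
with within-block transitions more probable than across. A group effect is
planted by rescaling the across-block exit probabilities asymmetrically for
group 1, which shifts the stationary occupancy balance of the metastates
without touching the within-block structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import TimecourseSet

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "block_transition_matrix",
    "default_transition_matrix",
    "paperlike_transition_matrix",
    "default_state_phase_offsets",
    "group_transition_matrix",
    "stationary_distribution",
    "sample_state_sequence",
    "synthesize_subject",
    "generate_cohort",
    "write_cohort",
]

#: approximate sizes of the seven canonical resting-state networks
#: (subcortical, auditory, somatomotor, visual, cognitive control,
#: default mode, cerebellum) for a 50-component parcellation
NETWORK_SIZES = (5, 2, 6, 11, 13, 10, 3)
NETWORK_NAMES = ("SC", "AUD", "SM", "VIS", "CC", "DMN", "CB")

#: phase-clique angles used when drawing default state patterns
CLIQUE_ANGLES = (0.0, np.pi / 3, 2 * np.pi / 3, np.pi)


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort; see module docstring."""

    n_states: int
    n_components: int
    module_map: np.ndarray  # component -> network, 1-based
    state_phase_offsets: np.ndarray  # K x C radians
    transition_matrix: np.ndarray  # K x K row-stochastic
    metastate_partition: np.ndarray  # state -> {1, 2}
    carrier_freq: float  # Hz
    tr: float  # seconds
    n_timepoints: int
    phase_noise_sd: float  # radians
    additive_noise_sd: float
    n_subjects_per_group: int
    group_occupancy_shift: float  # in [0, 1)
    seed: int
    carrier_jitter: float = 0.005  # per-subject uniform jitter, Hz
    #: step SD (radians/sample) of a slow phase random walk shared by all
    #: components of a subject. It cancels exactly in pairwise phase
    #: differences (no effect on IPS or state recovery) but spreads each
    #: column's spectral line as real slow oscillations wander, which is
    #: what lets phase-shuffle/circular-shift surrogates decorrelate in time
    #: instead of freezing into one random pattern per subject.
    phase_drift_sd: float = 0.35

    def __post_init__(self) -> None:
        self.module_map = np.asarray(self.module_map, dtype=int)
        self.state_phase_offsets = np.asarray(self.state_phase_offsets, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.metastate_partition = np.asarray(self.metastate_partition, dtype=int)
        self.validate()

    def validate(self) -> None:
        k, c = self.n_states, self.n_components
        if self.module_map.shape != (c,):
            raise ValueError("module_map must assign all components")
        if self.state_phase_offsets.shape != (k, c):
            raise ValueError("state_phase_offsets must be K x C")
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition_matrix must be K x K")
        if np.any(self.transition_matrix < 0):
            raise ValueError("transition probabilities must be nonnegative")
        rowsum = self.transition_matrix.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must sum to 1 within 1e-12")
        if self.metastate_partition.shape != (k,):
            raise ValueError("metastate_partition must cover all states")
        if not (0.01 <= self.carrier_freq <= 0.08):
            raise ValueError("carrier_freq must lie in the 0.01-0.08 Hz band")
        if not (0.0 <= self.group_occupancy_shift < 1.0):
            raise ValueError("group_occupancy_shift must be in [0, 1)")
        within, across = _block_transition_means(
            self.transition_matrix, self.metastate_partition
        )
        # degenerate chains (absorbing, or singleton blocks) carry no
        # hierarchy to check
        if np.isfinite(within) and np.isfinite(across) and (within + across) > 0:
            if not within > across:
                raise ValueError(
                    "planted hierarchy violated: mean within-metastate "
                    f"transition probability ({within:.4f}) must exceed "
                    f"across ({across:.4f})"
                )

    def state_ips_pattern(self, state: int) -> np.ndarray:
        """Noise-free IPS P-vector of a 1-based state: cos(theta_p - theta_q)."""
        theta = self.state_phase_offsets[state - 1]
        iu, ju = np.triu_indices(self.n_components, k=1)
        return np.cos(theta[iu] - theta[ju])


@dataclass
class GroundTruth:
    """Planted quantities for recovery tests."""

    state_labels: dict[str, np.ndarray]  # subject_id -> length-T sequence, 1..K
    group_labels: dict[str, int]
    transition_matrix: dict[int, np.ndarray]  # group -> generating K x K matrix
    metastate_partition: np.ndarray
    subject_ids: list[str] = field(default_factory=list)


def _block_transition_means(
    transition: np.ndarray, partition: np.ndarray
) -> tuple[float, float]:
    """Mean off-diagonal within-block and across-block transition
    probabilities (NaN when a set is empty, e.g. singleton blocks)."""
    k = transition.shape[0]
    same = partition[:, None] == partition[None, :]
    off = ~np.eye(k, dtype=bool)
    within = transition[same & off]
    across = transition[~same]
    return (
        float(within.mean()) if within.size else float("nan"),
        float(across.mean()) if across.size else float("nan"),
    )


def block_transition_matrix(
    n_states: int,
    partition: np.ndarray,
    dwell: float,
    across_mass: float,
) -> np.ndarray:
    """Row-stochastic matrix with dwell ``dwell`` on the diagonal, total
    across-block probability ``across_mass`` per row, and the remaining
    off-diagonal mass spread uniformly within the block."""
    partition = np.asarray(partition, dtype=int)
    within_mass = 1.0 - dwell - across_mass
    if within_mass <= 0:
        raise ValueError("dwell + across_mass must leave within-block mass")
    t = np.empty((n_states, n_states))
    for i in range(n_states):
        same = partition == partition[i]
        n_within = int(same.sum()) - 1
        n_across = n_states - n_within - 1
        row = np.where(
            same, within_mass / max(n_within, 1), across_mass / n_across
        )
        row[i] = dwell
        t[i] = row / row.sum()
    return t


def default_transition_matrix(
    n_states: int = 8, partition: np.ndarray | None = None
) -> np.ndarray:
    """The default chain: slow, strongly hierarchical states.

    Dwell 0.92 (mean state lifetime ~25 s at TR = 2 s) and within-block
    off-diagonal mass three times the across-block mass, so planted states
    persist long enough to be resolved through the narrowband analysis
    filter, whose temporal support is ~14 s.
    """
    if partition is None:
        partition = np.repeat([1, 2], n_states // 2)
    return block_transition_matrix(n_states, partition, dwell=0.92, across_mass=0.02)


def paperlike_transition_matrix(
    n_states: int = 8, partition: np.ndarray | None = None
) -> np.ndarray:
    """A chain calibrated to empirically reported temporal magnitudes:
    state dwell 0.7 (lifetimes of a few samples) and metastate dwell 0.85
    (across-block exit probability 0.15 per sample).

    Metastates alternate ~10 times per 145-sample session here, so
    per-subject occupancy ratios are well estimable — the right regime for
    exercising group statistics. The hierarchy is weaker than the default
    chain's (within-block mean still exceeds across-block mean) and state
    lifetimes are too short for phase-based state recovery at this sampling
    rate, which is why it is not the default.
    """
    if partition is None:
        partition = np.repeat([1, 2], n_states // 2)
    return block_transition_matrix(n_states, partition, dwell=0.7, across_mass=0.15)


def default_state_phase_offsets(
    n_states: int,
    module_map: np.ndarray,
    rng: np.random.Generator,
    n_candidates: int = 400,
) -> np.ndarray:
    """Draw mutually well-separated state patterns as network-level cliques.

    Each candidate state assigns every network one angle from a four-angle
    palette (0, pi/3, 2pi/3, pi), so components form 2-4 phase cliques whose
    planted IPS values are cosines of the clique differences. From a pool of
    random candidates a greedy max-min selection keeps the ``n_states``
    patterns whose pairwise IPS distances are largest, making the states
    mutually distinguishable by construction (IPS is blind to a global
    rotation or reflection of the offsets, so distinctness must be enforced
    in IPS space, not on the angles).
    """
    networks = np.unique(module_map)
    iu, ju = np.triu_indices(module_map.size, k=1)
    thetas: list[np.ndarray] = []
    patterns: list[np.ndarray] = []
    while len(thetas) < n_candidates:
        net_angles = rng.choice(CLIQUE_ANGLES, size=networks.size)
        if np.unique(net_angles).size < 2:
            continue
        theta = net_angles[np.searchsorted(networks, module_map)]
        thetas.append(theta)
        patterns.append(np.cos(theta[iu] - theta[ju]))
    pats = np.vstack(patterns)
    selected = [0]
    dist = np.linalg.norm(pats - pats[0], axis=1)
    for _ in range(n_states - 1):
        nxt = int(np.argmax(dist))
        if dist[nxt] < 1e-9:  # pragma: no cover - pool far exceeds n_states
            raise RuntimeError("could not draw distinct state patterns")
        selected.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pats - pats[nxt], axis=1))
    return np.vstack([thetas[i] for i in selected])


def default_config(seed: int = 7) -> SyntheticConfig:
    """Cohort geometry mirroring the study: C=50 components in 7 networks,
    K=8 states in two metastates {1-4},{5-8}, T=145 samples at TR=2 s,
    a 0.04 Hz carrier inside the 0.01-0.08 Hz analysis band."""
    n_states, n_components = 8, 50
    module_map = np.repeat(np.arange(1, 8), NETWORK_SIZES)
    partition = np.repeat([1, 2], 4)
    # pattern draw is tied to the config seed so a config is reproducible
    rng = np.random.default_rng(seed)
    offsets = default_state_phase_offsets(n_states, module_map, rng)
    return SyntheticConfig(
        n_states=n_states,
        n_components=n_components,
        module_map=module_map,
        state_phase_offsets=offsets,
        transition_matrix=default_transition_matrix(n_states, partition),
        metastate_partition=partition,
        carrier_freq=0.04,
        tr=2.0,
        n_timepoints=145,
        phase_noise_sd=0.2,
        additive_noise_sd=0.1,
        n_subjects_per_group=10,
        group_occupancy_shift=0.5,
        seed=seed,
    )


def group_transition_matrix(config: SyntheticConfig, group: int) -> np.ndarray:
    """Generating chain for a group.

    Group 0 uses the configured matrix. For group 1 the across-block exit
    probabilities are rescaled asymmetrically — leaving metastate 1 becomes
    ``(1 + shift)`` times more probable, leaving metastate 2 ``(1 - shift)``
    times — and rows are renormalized, which tilts stationary occupancy
    toward metastate 2 without altering within-block structure.
    """
    t = config.transition_matrix.copy()
    s = config.group_occupancy_shift
    if group == 0 or s == 0.0:
        return t
    part = config.metastate_partition
    for i in range(config.n_states):
        across = part != part[i]
        factor = 1.0 + s if part[i] == 1 else 1.0 - s
        t[i, across] *= factor
        t[i] /= t[i].sum()
    return t


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic chain (left Perron vector)."""
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_state_sequence(
    config: SyntheticConfig, group: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a length-T state sequence (1-based) from the group's chain.

    The first state comes from the chain's stationary distribution so the
    sequence is stationary from sample one.
    """
    t_mat = group_transition_matrix(config, group)
    rowsum = t_mat.sum(axis=1)
    if np.any(t_mat < 0) or np.any(np.abs(rowsum - 1.0) > 1e-9):
        raise ValueError("transition matrix is not row-stochastic")
    n = config.n_timepoints
    if n < 2:
        raise ValueError("need at least two time points")
    k = config.n_states
    cum = np.cumsum(t_mat, axis=1)
    seq = np.empty(n, dtype=int)
    seq[0] = rng.choice(k, p=stationary_distribution(t_mat))
    u = rng.random(n - 1)
    for t in range(1, n):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t - 1], side="right")
    return seq + 1


def synthesize_subject(
    config: SyntheticConfig,
    state_sequence: np.ndarray,
    rng: np.random.Generator,
    subject_id: str = "sub",
    group: int | None = None,
    carrier_freq: float | None = None,
) -> TimecourseSet:
    """Render a state sequence as narrowband component time courses.

    Component c at sample t is
    ``cos(2*pi*f*t*tr + theta[s(t), c] + phase noise) + additive noise``;
    the offset ramps across a single sampling interval at state switches
    (sampled values always carry the active state's exact pattern), keeping
    the signal narrowband.
    """
    state_sequence = np.asarray(state_sequence, dtype=int)
    if state_sequence.shape != (config.n_timepoints,):
        raise ValueError(
            f"state sequence length {state_sequence.size} != T={config.n_timepoints}"
        )
    if state_sequence.min() < 1 or state_sequence.max() > config.n_states:
        raise ValueError("state labels must lie in 1..K")
    f = config.carrier_freq if carrier_freq is None else carrier_freq
    t_idx = np.arange(config.n_timepoints)
    carrier = 2 * np.pi * f * t_idx * config.tr
    if config.phase_drift_sd > 0:
        carrier = carrier + np.cumsum(
            rng.normal(0.0, config.phase_drift_sd, size=config.n_timepoints)
        )
    theta = config.state_phase_offsets[state_sequence - 1]  # T x C
    phase = carrier[:, None] + theta
    if config.phase_noise_sd > 0:
        phase = phase + rng.normal(0.0, config.phase_noise_sd, size=phase.shape)
    data = np.cos(phase)
    if config.additive_noise_sd > 0:
        data = data + rng.normal(0.0, config.additive_noise_sd, size=data.shape)
    return TimecourseSet(
        subject_id=subject_id,
        data=data,
        tr=config.tr,
        module_map=config.module_map.copy(),
        group=group,
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[TimecourseSet], GroundTruth]:
    """Generate the two-group cohort plus full ground truth, reproducibly
    from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    subjects: list[TimecourseSet] = []
    truth = GroundTruth(
        state_labels={},
        group_labels={},
        transition_matrix={g: group_transition_matrix(config, g) for g in (0, 1)},
        metastate_partition=config.metastate_partition.copy(),
    )
    for group in (0, 1):
        for i in range(config.n_subjects_per_group):
            sid = f"g{group}s{i + 1:03d}"
            seq = sample_state_sequence(config, group, rng)
            jitter = rng.uniform(-config.carrier_jitter, config.carrier_jitter)
            ts = synthesize_subject(
                config,
                seq,
                rng,
                subject_id=sid,
                group=group,
                carrier_freq=config.carrier_freq + jitter,
            )
            subjects.append(ts)
            truth.state_labels[sid] = seq
            truth.group_labels[sid] = group
            truth.subject_ids.append(sid)
    return subjects, truth


def write_cohort(
    subjects: list[TimecourseSet],
    truth: GroundTruth,
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Write one delimited-text matrix per subject plus a cohort manifest
    (CSV) and a ground-truth JSON. Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id,group,seed,timecourse_path"]
    for ts in subjects:
        fname = f"{ts.subject_id}.tsv"
        header = "\t".join(ts.component_labels)
        np.savetxt(out_dir / fname, ts.data, delimiter="\t", header=header, comments="")
        rows.append(f"{ts.subject_id},{ts.group},{'' if seed is None else seed},{fname}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    gt = {
        "state_labels": {k: v.tolist() for k, v in truth.state_labels.items()},
        "group_labels": truth.group_labels,
        "transition_matrix": {
            str(g): m.tolist() for g, m in truth.transition_matrix.items()
        },
        "metastate_partition": truth.metastate_partition.tolist(),
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return manifest
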