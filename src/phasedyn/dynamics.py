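"""State-sequence statistics, metastate discovery, and network averaging.

A subject's hard state sequence is summarized by four quantities: the
*prevalence* (occupancy fraction) of each state, its *persistence* (mean
uninterrupted lifetime, seconds), the row-stochastic *transition* matrix of
consecutive-pair counts, and the *dwell* probability (the transition
diagonal). The transition graph carries slower structure as well: grouping
states so that within-group transitions are more probable than across yields
*metastates*, found here by the sign pattern of the Fiedler vector (second
smallest eigenvector) of the Laplacian of the symmetrized transition graph,
and cross-checked with an average-linkage hierarchical two-cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import squareform

from .containers import MetastatePartition, StateModel, TemporalProfile

__all__ = [
    "summarize_sequence",
    "mean_transition_matrix",
    "fiedler_bipartition",
    "hierarchical_validate",
    "metastate_dynamics",
    "metastate_profiles",
    "network_average",
    "transition_similarity_correlation",
]


def _run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state of each maximal run, its length) in time order."""
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    lengths = np.diff(bounds)
    return labels[bounds[:-1]], lengths


def summarize_sequence(labels: np.ndarray, k: int, tr: float) -> TemporalProfile:
    """Prevalence, persistence, transition matrix and dwell of one sequence.

    Transition rows of never-visited states are NaN; persistence of a state
    is its mean maximal-run length times the sampling interval (NaN when the
    state never occurs).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise ValueError("sequence must have length >= 2")
    if labels.min() < 1:
        raise ValueError("labels must be 1-based")
    if labels.max() > k:
        raise ValueError(f"label {labels.max()} exceeds K={k}")
    prevalence = np.bincount(labels - 1, minlength=k) / labels.size
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1)
    rowsum = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        transition = counts / rowsum[:, None]
    transition[rowsum == 0] = np.nan
    run_states, run_lens = _run_lengths(labels)
    persistence = np.full(k, np.nan)
    for s in range(1, k + 1):
        mask = run_states == s
        if mask.any():
            persistence[s - 1] = run_lens[mask].mean() * tr
    return TemporalProfile(
        prevalence=prevalence,
        persistence=persistence,
        transition=transition,
        dwell=np.diag(transition).copy(),
        n_samples=labels.size,
        tr=tr,
    )


def mean_transition_matrix(profiles: list[TemporalProfile]) -> np.ndarray:
    """Entrywise mean of per-subject transition matrices, ignoring NaN rows."""
    stack = np.stack([p.transition for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack, axis=0)


def fiedler_bipartition(
    transition: np.ndarray,
    centroids: np.ndarray | None = None,
    normalized: bool = False,
) -> MetastatePartition:
    """Two-way split of the state graph by the Fiedler vector's signs.

    The (possibly asymmetric) transition matrix is symmetrized as
    ``(T + T') / 2`` with the diagonal removed; the Fiedler vector is the
    eigenvector of the second-smallest eigenvalue of the (unnormalized by
    default) Laplacian ``L = D - W``. Zero entries join the smaller side.
    When centroids are given, metastate 1 is the side with the higher mean
    centroid coupling.
    """
    t_mat = np.asarray(transition, dtype=float)
    k = t_mat.shape[0]
    if k < 3 or t_mat.shape != (k, k):
        raise ValueError("need a square transition matrix with K >= 3")
    if np.any(np.nan_to_num(t_mat) < 0):
        raise ValueError("transition entries must be nonnegative")
    w = (np.nan_to_num(t_mat) + np.nan_to_num(t_mat).T) / 2
    np.fill_diagonal(w, 0.0)
    deg = w.sum(axis=1)
    lap = np.diag(deg) - w
    if normalized:
        with np.errstate(divide="ignore"):
            d_is = np.where(deg > 0, 1 / np.sqrt(deg), 0.0)
        lap = np.eye(k) - d_is[:, None] * w * d_is[None, :]
    vals, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1]
    tol = 1e-10 * max(1.0, float(np.abs(fiedler).max()))
    pos = fiedler > tol
    neg = fiedler < -tol
    zero = ~pos & ~neg
    if pos.any() and neg.any():
        partition = np.where(pos, 1, 2)
        if zero.any():  # zero entries join the smaller side
            smaller = 1 if pos.sum() <= neg.sum() else 2
            partition[zero] = smaller
    elif zero.any() and (pos.any() or neg.any()):
        # disconnected graphs: the Fiedler vector is an indicator of one
        # component, the complementary zeros form the other side
        partition = np.where(zero, 2, 1)
    else:
        raise ValueError("Fiedler vector has one sign only: no bipartition")
    if centroids is not None:
        m1 = centroids[partition == 1].mean()
        m2 = centroids[partition == 2].mean()
        if m2 > m1:
            partition = 3 - partition
    return MetastatePartition(partition=partition, fiedler_vector=fiedler)


def hierarchical_validate(
    transition: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Average-linkage dendrogram over 1 - normalized transition affinity.

    Returns the linkage matrix, the cophenetic correlation coefficient, and
    the two-cluster cut (labels 1/2) for comparison with the Fiedler
    partition. A cophenetic coefficient near zero means the tree imposes
    little real structure and the cut is arbitrary.
    """
    t_mat = np.nan_to_num(np.asarray(transition, dtype=float))
    k = t_mat.shape[0]
    if k < 3:
        raise ValueError("need K >= 3")
    w = (t_mat + t_mat.T) / 2
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    affinity = w / wmax if wmax > 0 else w
    dist = 1.0 - affinity
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = linkage(condensed, method="average")
    if np.allclose(condensed, condensed[0]):
        warnings.warn("uniform transition affinity: arbitrary cut", stacklevel=2)
        coph = 0.0
    else:
        coph = float(cophenet(link, condensed)[0])
        if not np.isfinite(coph):
            coph = 0.0
    two_cut = cut_tree(link, n_clusters=2).ravel() + 1
    return link, coph, two_cut


def metastate_dynamics(
    labels: np.ndarray, partition: MetastatePartition | np.ndarray, tr: float
) -> tuple[TemporalProfile, dict[str, float]]:
    """Project a state sequence onto its metastates and summarize it.

    Returns the K=2 profile plus MS2/MS1 prevalence and persistence ratios
    (NaN-flagged when the MS1 quantity is zero or MS1 is never visited).
    """
    part = (
        partition.partition
        if isinstance(partition, MetastatePartition)
        else np.asarray(partition, dtype=int)
    )
    labels = np.asarray(labels, dtype=int)
    if labels.max() > part.size:
        raise ValueError("partition does not cover all states")
    ms_labels = part[labels - 1]
    profile = summarize_sequence(ms_labels, 2, tr)
    ratios: dict[str, float] = {}
    prev1, prev2 = profile.prevalence
    ratios["prevalence_ratio"] = prev2 / prev1 if prev1 > 0 else np.nan
    pers1, pers2 = profile.persistence
    if np.isnan(pers1) or pers1 == 0:
        ratios["persistence_ratio"] = np.nan
    else:
        ratios["persistence_ratio"] = (0.0 if np.isnan(pers2) else pers2) / pers1
    return profile, ratios


def metastate_profiles(
    model: StateModel, partition: MetastatePartition
) -> np.ndarray:
    """Mean IPS vector of each metastate, weighting member states by their
    pooled occupancy (identical to averaging over all assigned samples)."""
    counts = np.bincount(model.labels, minlength=model.k + 1)[1:]
    out = np.empty((2, model.centroids.shape[1]))
    for ms in (1, 2):
        members = partition.partition == ms
        w = counts[members].astype(float)
        out[ms - 1] = np.average(model.centroids[members], axis=0, weights=w)
    return out


def network_average(
    v: np.ndarray, module_map: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average a pairwise P-vector into network-level couplings.

    Entry (A, B) is the mean of v over component pairs with one end in
    network A and the other in B; the within-network entry (A, A) averages
    distinct-component pairs only (NaN-flagged for singleton networks).
    Returns the full symmetric matrix and its unique entries (upper triangle
    including the diagonal), 28 of them for seven networks.
    """
    v = np.asarray(v, dtype=float)
    module_map = np.asarray(module_map, dtype=int)
    c = module_map.size
    if v.size != c * (c - 1) // 2:
        raise ValueError("vector length does not match module_map")
    networks = np.unique(module_map)
    n = networks.size
    iu, ju = np.triu_indices(c, k=1)
    net_i = np.searchsorted(networks, module_map[iu])
    net_j = np.searchsorted(networks, module_map[ju])
    a = np.minimum(net_i, net_j)
    b = np.maximum(net_i, net_j)
    mat = np.full((n, n), np.nan)
    for x in range(n):
        for y in range(x, n):
            mask = (a == x) & (b == y)
            if mask.any():
                mat[x, y] = mat[y, x] = v[mask].mean()
            elif x == y:
                warnings.warn(
                    f"network {networks[x]} has a single component: "
                    "within-network mean undefined",
                    stacklevel=2,
                )
    ru, cu = np.triu_indices(n)
    return mat, mat[ru, cu]


def transition_similarity_correlation(
    model: StateModel,
    profiles: dict[str, TemporalProfile],
    activity: dict[str, np.ndarray] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[dict]:
    """Correlate state-pair similarities with mean transition probabilities.

    For each aspect the K(K-1)/2 off-diagonal state-pair similarities are
    correlated (Pearson) with the symmetrized off-diagonal entries of the
    subject-mean transition matrix:

    * ``pattern`` — correlation between the two states' centroid vectors;
    * ``prevalence`` / ``persistence`` — negative absolute difference of the
      subject-mean values (a monotone, rank-preserving similarity);
    * ``activity`` (optional) — correlation between state-conditioned mean
      component amplitudes, supplied per subject as K x C matrices.

    Confidence intervals are percentile bootstrap over subject resampling.
    """
    k = model.k
    if k < 3:
        raise ValueError("need K >= 3 for pairwise similarities")
    subject_ids = sorted(profiles)
    if len(subject_ids) < 2:
        raise ValueError("need at least two subjects")
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap resamples", stacklevel=2)
    iu, ju = np.triu_indices(k, k=1)
    prev = np.vstack([profiles[s].prevalence for s in subject_ids])
    pers = np.vstack([profiles[s].persistence for s in subject_ids])
    trans = np.stack([np.nan_to_num(profiles[s].transition) for s in subject_ids])

    cent_sim = np.corrcoef(model.centroids)[iu, ju]

    def similarity_vectors(idx: np.ndarray) -> dict[str, np.ndarray]:
        pm = prev[idx].mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sm = np.nanmean(pers[idx], axis=0)
        sims = {
            "pattern": cent_sim,
            "prevalence": -np.abs(pm[iu] - pm[ju]),
            "persistence": -np.abs(sm[iu] - sm[ju]),
        }
        if activity is not None:
            amp = np.stack([activity[subject_ids[i]] for i in idx]).mean(axis=0)
            sims["activity"] = np.corrcoef(amp)[iu, ju]
        return sims

    def transition_vector(idx: np.ndarray) -> np.ndarray:
        tm = trans[idx].mean(axis=0)
        return ((tm + tm.T) / 2)[iu, ju]

    all_idx = np.arange(len(subject_ids))
    sims0 = similarity_vectors(all_idx)
    tv0 = transition_vector(all_idx)
    rng = np.random.default_rng(seed)
    boot_idx = [
        rng.integers(0, all_idx.size, size=all_idx.size) for _ in range(n_boot)
    ]
    results = []
    for aspect, sim0 in sims0.items():
        if np.allclose(sim0, sim0[0]):
            results.append(
                {
                    "aspect": aspect,
                    "r": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "degenerate": True,
                }
            )
            continue
        r, p = sps.pearsonr(sim0, tv0)
        boots = []
        for idx in boot_idx:
            sim_b = similarity_vectors(idx)[aspect]
            tv_b = transition_vector(idx)
            if np.std(sim_b) == 0 or np.std(tv_b) == 0:
                continue
            boots.append(sps.pearsonr(sim_b, tv_b)[0])
        lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
        results.append(
            {
                "aspect": aspect,
                "r": float(r),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p": float(p),
                "degenerate": False,
            }
        )
    return results
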