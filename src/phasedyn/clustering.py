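"""Recurrent phase-synchrony states via spectral clustering of pooled samples.

Every time-indexed IPS vector from every subject becomes one node of a
weighted, unsigned graph whose edge weights are *angular similarities*,

    ang_sim(u, v) = 1 - arccos(cos_sim(u, v)) / pi  in [0, 1].

Spectral clustering in the style of Ng-Jordan-Weiss follows: the k smallest
eigenvectors of the symmetric normalized Laplacian
``L = I - D^{-1/2} W D^{-1/2}`` are stacked, their rows normalized to the
unit sphere, and a Gaussian mixture model clusters the embedded points. The
Davies-Bouldin index over candidate cluster counts selects the number of
states; centroids are then the mean of the *original* IPS vectors per label.

Phase-shuffle and circular-shift surrogates destroy cross-series synchrony
while preserving per-series spectra (or sample values), and provide the null
against which the recurrence of states is judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.linalg import eigsh
from sklearn.mixture import GaussianMixture

from .containers import IPSSeries, StateModel, TimecourseSet

__all__ = [
    "angular_similarity",
    "build_similarity_matrix",
    "spectral_embed",
    "davies_bouldin",
    "fit_states",
    "make_surrogate",
    "SimilarityMatrix",
    "centroid_dynamic_range",
]


@dataclass
class SimilarityMatrix:
    """Pooled pairwise angular similarity with row -> (subject, t) mapping."""

    s: np.ndarray
    sample_index: list[tuple[str, int]]


def angular_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Angular similarity 1 - arccos(cosine similarity)/pi, in [0, 1].

    The angle is evaluated through the chord length of the unit-normalized
    vectors, which is exact at the bounds (identical vectors give exactly 1,
    antipodal exactly 0) and numerically accurate for small angles, where
    the naive arccos of a dot product loses half the significant digits.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("angular similarity undefined for zero vectors")
    un, vn = u / nu, v / nv
    # angle via chord lengths: exact at both bounds, accurate everywhere
    diff = np.clip(np.linalg.norm(un - vn) / 2.0, 0.0, 1.0)
    if diff <= np.sqrt(0.5):  # angle <= pi/2: use the difference chord
        angle = 2.0 * np.arcsin(diff)
    else:  # obtuse: the sum chord is the numerically stable one
        summ = np.clip(np.linalg.norm(un + vn) / 2.0, 0.0, 1.0)
        angle = np.pi - 2.0 * np.arcsin(summ)
    return float(1.0 - angle / np.pi)


def build_similarity_matrix(
    ips_list: list[IPSSeries], block_size: int = 2048
) -> SimilarityMatrix:
    """All-pairs angular similarity of the pooled cohort samples.

    Row blocks bound the working memory of the Gram computation; the result
    itself is a dense MN x MN symmetric matrix.
    """
    if not ips_list:
        raise ValueError("empty cohort")
    p = ips_list[0].n_pairs
    order = ips_list[0].pair_index
    for s in ips_list[1:]:
        if s.n_pairs != p or s.pair_index != order:
            raise ValueError("all subjects must share P and pair ordering")
    x = np.vstack([s.ips for s in ips_list])
    sample_index = [
        (s.subject_id, t) for s in ips_list for t in range(s.n_samples)
    ]
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"zero IPS vector at pooled sample {bad}")
    xn = x / norms[:, None]
    n = xn.shape[0]
    s_mat = np.empty((n, n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        g = np.clip(xn[start:stop] @ xn.T, -1.0, 1.0)
        s_mat[start:stop] = 1.0 - np.arccos(g) / np.pi
    s_mat = (s_mat + s_mat.T) / 2
    return SimilarityMatrix(s=s_mat, sample_index=sample_index)


def spectral_embed(
    sim: SimilarityMatrix | np.ndarray, k: int, _cache: dict | None = None
) -> np.ndarray:
    """Rows of the k smallest normalized-Laplacian eigenvectors, unit-scaled.

    The graph uses the similarity matrix with a zeroed diagonal (no
    self-loops); degrees are off-diagonal row sums. Eigenvector signs are
    fixed by making each column's largest-magnitude entry positive; zero rows
    are left at zero with a warning.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    s = sim.s if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    vecs = _laplacian_eigenvectors(s, k, _cache)[:, :k]
    # fix signs, then normalize rows
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    norms = np.linalg.norm(vecs, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} embedded row(s) are zero", stacklevel=2)
        norms[zero] = 1.0
    return vecs / norms[:, None]


def _laplacian_eigenvectors(
    s: np.ndarray, k: int, cache: dict | None
) -> np.ndarray:
    """Eigenvectors of the k smallest eigenvalues of L_sym, cached on demand."""
    if cache is not None and cache.get("n_vecs", 0) >= k:
        return cache["vecs"]
    w = s.copy()
    np.fill_diagonal(w, 0.0)
    if np.any(w < 0):
        raise ValueError("similarity matrix must be nonnegative off-diagonal")
    deg = w.sum(axis=1)
    if np.any(deg <= 0):
        bad = int(np.flatnonzero(deg <= 0)[0])
        raise ValueError(f"sample {bad} is disconnected (zero degree)")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    a = w * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    n = a.shape[0]
    # smallest eigenvalues of L = I - A are the largest of A
    if n <= 400 or k >= n - 1:
        vals, vecs = eigh(a)
        order = np.argsort(vals)[::-1]
    else:
        # fixed start vector keeps the Lanczos iteration deterministic
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = eigsh(a, k=min(k, n - 2), which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
    vecs = vecs[:, order]
    if cache is not None:
        cache["vecs"] = vecs
        cache["n_vecs"] = vecs.shape[1]
    return vecs


def davies_bouldin(features: np.ndarray, labels: np.ndarray) -> float:
    """Classic Davies-Bouldin index (lower is better).

    Mean over clusters of ``max_{j!=i} (s_i + s_j) / d_ij`` where ``s`` is the
    mean Euclidean distance of members to their centroid and ``d`` the
    centroid distance. Raises on coincident centroids (undefined ratio).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    cents = np.vstack([features[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [
            np.linalg.norm(features[labels == u] - cents[i], axis=1).mean()
            for i, u in enumerate(uniq)
        ]
    )
    d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
    off = ~np.eye(uniq.size, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident centroids: Davies-Bouldin undefined")
    ratio = (scatter[:, None] + scatter[None, :]) / np.where(off, d, np.inf)
    return float(np.max(np.where(off, ratio, -np.inf), axis=1).mean())


def _hard_assign_gmm(
    features: np.ndarray,
    k: int,
    seed: int,
    n_init: int = 10,
    covariance_type: str = "tied",
) -> np.ndarray:
    """Gaussian mixture with restarts; retries on empty hard clusters.

    The covariance structure is shared across components by default: on
    row-normalized spectral embeddings the clusters are compact and
    comparably spread, and per-component full covariances systematically
    inflate to swallow neighbouring clusters.
    """
    for attempt in range(10):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            n_init=n_init,
            reg_covar=1e-6,
            random_state=seed + attempt,
        )
        labels = gmm.fit_predict(features)
        if np.unique(labels).size == k:
            return labels
    raise RuntimeError(f"GMM produced an empty cluster for k={k} in 10 attempts")


def fit_states(
    ips_list: list[IPSSeries],
    k_range: range | list[int] = range(2, 11),
    seed: int = 0,
    db_space: str = "raw",
    covariance_type: str = "tied",
    similarity: SimilarityMatrix | None = None,
) -> StateModel:
    """Cluster the pooled cohort and select the state count by Davies-Bouldin.

    For each candidate k the pooled samples are embedded in k dimensions and
    a k-component Gaussian mixture is fitted; the k minimizing the
    Davies-Bouldin index wins. The index is computed on the raw IPS vectors
    by default so every candidate k is scored in one common metric space;
    ``db_space='embedding'`` scores each candidate in its own k-dimensional
    embedding instead (there the index acquires a dimension-dependent bias
    toward small k, because scatter/separation ratios shrink with embedding
    dimension). Centroids are recomputed as means of the original IPS
    vectors, and states are relabelled by descending prevalence (state 1
    most prevalent; ties by first occurrence).
    """
    k_range = list(k_range)
    if similarity is None:
        similarity = build_similarity_matrix(ips_list)
    n = similarity.s.shape[0]
    if n < 10 * max(k_range):
        raise ValueError(
            f"{n} pooled samples is too few for k up to {max(k_range)}"
        )
    x = np.vstack([s.ips for s in ips_list])
    cache: dict = {}
    db_scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in sorted(k_range, reverse=True):  # largest first primes the cache
        emb = spectral_embed(similarity, k, _cache=cache)
        labels = _hard_assign_gmm(emb, k, seed, covariance_type=covariance_type)
        space = emb if db_space == "embedding" else x
        db_scores[k] = davies_bouldin(space, labels)
        labelings[k] = labels
    best_k = min(db_scores, key=lambda k: (db_scores[k], k))
    labels = labelings[best_k]
    # relabel by descending prevalence, ties by first occurrence
    counts = np.bincount(labels, minlength=best_k)
    first_seen = np.array(
        [np.flatnonzero(labels == u)[0] for u in range(best_k)]
    )
    order = sorted(range(best_k), key=lambda u: (-counts[u], first_seen[u]))
    remap = np.empty(best_k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    labels = remap[labels]
    centroids = np.vstack(
        [x[labels == s].mean(axis=0) for s in range(1, best_k + 1)]
    )
    return StateModel(
        k=best_k,
        centroids=centroids,
        labels=labels,
        sample_index=similarity.sample_index,
        db_scores=db_scores,
        embedding_dim=best_k,
        seed=seed,
    )


def centroid_dynamic_range(centroids: np.ndarray) -> float:
    """Mean over states of (max - min) centroid entry; large for states with
    strong coupling/anticoupling structure, small for flat surrogate states."""
    c = np.asarray(centroids, dtype=float)
    return float((c.max(axis=1) - c.min(axis=1)).mean())


def make_surrogate(
    ts: TimecourseSet, method: str, seed: int | np.random.Generator = 0
) -> TimecourseSet:
    """Surrogate time courses that break cross-series synchrony.

    ``phase_shuffle`` randomizes the phase of every positive-frequency bin
    independently per column while keeping amplitude spectra (conjugate
    symmetry enforced, output real). ``circular_shift`` rotates each column
    by an independent uniform shift in [1, T-1], preserving each column's
    sample values exactly.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t, c = ts.data.shape
    if t < 8:
        raise ValueError("surrogates need T >= 8")
    if method == "phase_shuffle":
        spec = np.fft.rfft(ts.data, axis=0)
        n_bins = spec.shape[0]
        phases = rng.uniform(0, 2 * np.pi, size=(n_bins, c))
        phases[0] = 0.0  # keep DC real
        if t % 2 == 0:
            phases[-1] = 0.0  # Nyquist bin must stay real
        out = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=t, axis=0)
    elif method == "circular_shift":
        shifts = rng.integers(1, t, size=c)
        out = np.empty_like(ts.data)
        for j in range(c):
            out[:, j] = np.roll(ts.data[:, j], int(shifts[j]))
    else:
        raise ValueError(f"unknown surrogate method {method!r}")
    return ts.copy_with(out)
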