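"""Analytic-signal phases, instantaneous phase synchrony, and static FNC.

For a narrowband real signal ``x(t) = a(t) cos(phi(t))`` the analytic signal
``x_a(t) = x(t) + j H{x(t)}`` has envelope ``a(t)`` and instantaneous phase
``phi(t)``. The instantaneous phase synchrony of two components p, q at
sample t is the cosine of their momentary phase difference,

    IPS_pq(t) = cos(phi_p(t) - phi_q(t)),

which is +1 when the phases align, -1 in antiphase, and 0 in quadrature.
Pairwise values are stored as P = C(C-1)/2 vectors in row-major
upper-triangle order.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import hilbert

from .containers import AnalyticSeries, IPSSeries, SFNCResult, TimecourseSet

__all__ = [
    "analytic_signal",
    "ips_series",
    "vectorize_upper",
    "matricize",
    "pair_index",
    "sfnc",
]


def analytic_signal(ts: TimecourseSet) -> AnalyticSeries:
    """Discrete Hilbert-transform analytic representation, per column.

    Phases are kept wrapped in (-pi, pi] (no unwrapping). Columns that are
    identically zero have an undefined phase and are flagged.
    """
    if ts.n_timepoints < 8:
        raise ValueError("analytic_signal requires T >= 8")
    if not np.all(np.isfinite(ts.data)):
        raise ValueError("non-finite input")
    xa = hilbert(ts.data, axis=0)
    envelope = np.abs(xa)
    phase = np.angle(xa)
    undefined = np.flatnonzero(np.all(envelope < 1e-300, axis=0))
    return AnalyticSeries(
        real_part=np.real(xa),
        imag_part=np.imag(xa),
        envelope=envelope,
        phase=phase,
        tr=ts.tr,
        subject_id=ts.subject_id,
        undefined_columns=undefined,
    )


def pair_index(n_components: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle pair ordering (0-based component indices)."""
    iu, ju = np.triu_indices(n_components, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def ips_series(
    analytic: AnalyticSeries, group: int | None = None
) -> IPSSeries:
    """Instantaneous phase synchrony for every component pair at every sample."""
    if analytic.undefined_columns.size:
        cols = ", ".join(map(str, analytic.undefined_columns.tolist()))
        raise ValueError(f"phase undefined for column(s): {cols}")
    phase = analytic.phase
    c = phase.shape[1]
    iu, ju = np.triu_indices(c, k=1)
    vals = np.cos(phase[:, iu] - phase[:, ju])
    return IPSSeries(
        subject_id=analytic.subject_id,
        ips=vals,
        pair_index=list(zip(iu.tolist(), ju.tolist())),
        tr=analytic.tr,
        group=group,
    )


def vectorize_upper(matrix: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Unique entries of a symmetric matrix, row-major upper-triangle order."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    if np.max(np.abs(m - m.T)) > atol:
        raise ValueError("input matrix is not symmetric")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju]


def matricize(vector: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`, with the given diagonal value."""
    v = np.asarray(vector, dtype=float)
    p = v.size
    c = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    if c * (c - 1) // 2 != p:
        raise ValueError(f"vector length {p} is not C(C-1)/2 for integer C")
    out = np.full((c, c), 0.0)
    iu, ju = np.triu_indices(c, k=1)
    out[iu, ju] = v
    out = out + out.T
    np.fill_diagonal(out, diagonal)
    return out


def sfnc(ts: TimecourseSet) -> SFNCResult:
    """Static functional network connectivity: Pearson r and Fisher z.

    The input is expected to be bandpass filtered to the static-connectivity
    band already. Correlations with |r| at the +-1 boundary are clipped just
    inside before ``atanh``; zero-variance components get NaN rows/columns.
    """
    data = ts.data
    sd = data.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    finite = np.isfinite(r)
    clip_needed = finite & (np.abs(r) >= 1 - 1e-12)
    np.fill_diagonal(clip_needed, False)
    if clip_needed.any():
        warnings.warn(
            f"{int(clip_needed.sum() // 2)} correlation(s) at |r|=1 clipped "
            "before Fisher transform",
            stacklevel=2,
        )
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, np.nan)
    return SFNCResult(r=r, z=z, undefined=degenerate if degenerate.any() else None)
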