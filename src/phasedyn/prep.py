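"""Time-course cleanup: detrend, nuisance regression, despiking, bandpass, FD.

The canonical order is ``detrend -> regress_nuisance -> despike_mad ->
bandpass``; every stage preserves the T x C shape and finiteness. Two filter
designs are supported: a linear-phase equiripple FIR (applied with exact
group-delay compensation) for the phase-synchrony band, and a zero-phase
forward-backward Butterworth for the static-connectivity band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .containers import TimecourseSet

__all__ = [
    "detrend",
    "regress_nuisance",
    "despike_mad",
    "bandpass",
    "design_fir_bandpass",
    "framewise_displacement",
    "FDResult",
]


def detrend(ts: TimecourseSet) -> TimecourseSet:
    """Remove each column's least-squares linear trend (slope + intercept)."""
    if ts.n_timepoints < 3:
        raise ValueError("detrend requires T >= 3")
    out = signal.detrend(ts.data, axis=0, type="linear")
    return ts.copy_with(out)


def _append_derivatives(nuisance: np.ndarray) -> np.ndarray:
    """First differences, zero at t=0, stacked next to the originals."""
    deriv = np.diff(nuisance, axis=0, prepend=nuisance[:1])
    return np.hstack([nuisance, deriv])


def regress_nuisance(
    ts: TimecourseSet,
    nuisance: np.ndarray | None = None,
    add_derivatives: bool | None = None,
) -> TimecourseSet:
    """Orthogonalize the data with respect to nuisance regressors.

    When ``nuisance`` is omitted the subject's motion parameters are used and
    their first differences appended (the conventional 12-regressor motion
    design). A constant column is always included. Rank-deficient designs are
    reduced to an independent column subset with a warning.
    """
    if nuisance is None:
        if ts.motion_params is None:
            raise ValueError("no nuisance matrix given and no motion parameters set")
        nuisance = ts.motion_params
        if add_derivatives is None:
            add_derivatives = True
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if add_derivatives:
        nuisance = _append_derivatives(nuisance)
    t = ts.n_timepoints
    if nuisance.shape[0] != t:
        raise ValueError("nuisance rows must match T")
    if nuisance.shape[1] >= t:
        raise ValueError("need fewer regressors than time points")
    design = np.hstack([np.ones((t, 1)), nuisance])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"nuisance design rank-deficient ({rank}/{design.shape[1]}); "
            "dropping dependent columns",
            stacklevel=2,
        )
        _, r_mat, piv = _qr_pivot(design)
        keep = np.sort(piv[:rank])
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return ts.copy_with(resid)


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr

    return qr(a, mode="economic", pivoting=True)


def despike_mad(
    ts: TimecourseSet, z_thresh: float = 5.0
) -> tuple[TimecourseSet, int]:
    """Replace outlier samples with spline-interpolated values.

    A sample is an outlier when its robust z score
    ``0.6745 * |x - median| / MAD`` exceeds ``z_thresh``. Outliers are
    replaced by a cubic spline through the non-outlier samples (linear near
    the series ends or when too few support points remain). Columns with zero
    MAD are skipped with a warning. Returns the cleaned set and the number of
    replaced samples.
    """
    if ts.n_timepoints < 7:
        raise ValueError("despike_mad requires T >= 7")
    data = ts.data.copy()
    t_idx = np.arange(ts.n_timepoints)
    n_replaced = 0
    for c in range(ts.n_components):
        col = data[:, c]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        if mad == 0:
            warnings.warn(f"column {c} has zero MAD; despike skipped", stacklevel=2)
            continue
        z = 0.6745 * np.abs(col - med) / mad
        bad = z > z_thresh
        if not bad.any():
            continue
        good = ~bad
        if good.sum() < 4:
            warnings.warn(
                f"column {c}: too few clean samples for spline; skipped",
                stacklevel=2,
            )
            continue
        interior = (t_idx >= t_idx[good].min()) & (t_idx <= t_idx[good].max())
        spline = interpolate.CubicSpline(t_idx[good], col[good])
        fill = np.where(
            interior,
            spline(t_idx),
            np.interp(t_idx, t_idx[good], col[good]),
        )
        col[bad] = fill[bad]
        n_replaced += int(bad.sum())
    return ts.copy_with(data), n_replaced


@dataclass
class FIRDesign:
    taps: np.ndarray
    transition_hz: float
    order: int
    meets_spec: bool


def design_fir_bandpass(
    low: float,
    high: float,
    fs: float,
    transition_hz: float = 0.005,
    max_taps: int | None = None,
    passband_ripple_db: float = 0.5,
    stopband_atten_db: float = 20.0,
) -> FIRDesign:
    """Equiripple (Parks-McClellan) linear-phase bandpass design.

    Searches for the smallest even order whose realized response keeps the
    passband within ``+/- passband_ripple_db`` and attenuates the stopband
    by ``stopband_atten_db`` beyond twice the transition width. When no
    order up to ``max_taps`` achieves that — unavoidable for short records
    whose length cannot resolve the transition band — the largest admissible
    order is used instead and a warning reports the achieved ripple and
    attenuation; linear phase is exact either way, and ripple perturbs
    amplitudes only, to which phase-synchrony analysis is insensitive.
    Records too short for any usable design raise an error naming the
    minimum series length.
    """
    nyq = fs / 2
    if not (0 < low < high < nyq):
        raise ValueError("need 0 < low < high < Nyquist")
    delta_p = 10 ** (passband_ripple_db / 20) - 1
    delta_s = 10 ** (-stopband_atten_db / 20)
    trans = min(transition_hz, 0.9 * low, 0.9 * (nyq - high))

    def _design(ntaps: int) -> np.ndarray:
        return signal.remez(
            ntaps,
            [0, low - trans, low, high, high + trans, nyq],
            [0, 1, 0],
            weight=[delta_p / delta_s, 1, delta_p / delta_s],
            fs=fs,
        )

    # Bellanger's estimate of the required order
    n_est = int(np.ceil(2 / 3 * np.log10(1 / (10 * delta_p * delta_s)) * fs / trans))
    n_est += n_est % 2
    cap = max_taps if max_taps is not None else 4 * n_est + 1
    order = 16
    while order + 1 <= cap:
        taps = _design(order + 1)
        if _fir_meets_spec(taps, low, high, trans, fs, delta_p, delta_s):
            return FIRDesign(
                taps=taps, transition_hz=trans, order=order, meets_spec=True
            )
        order += 2
    # capped fallback: best admissible order
    order = cap - 1 - (cap - 1) % 2
    if order < 8:
        raise ValueError(
            f"series too short for any bandpass FIR; need T >= {3 * (n_est + 1)}"
        )
    taps = _design(order + 1)
    w, h = signal.freqz(taps, worN=8192, fs=fs)
    mag = np.abs(h)
    passband = (w >= low) & (w <= high)
    far_stop = w >= min(high + 4 * trans, nyq)
    ripple = float(np.max(np.abs(mag[passband] - 1)))
    atten = float(mag[far_stop].max())
    warnings.warn(
        f"FIR capped at {order + 1} taps (spec needs ~{n_est}): achieved "
        f"passband ripple {ripple:.3f}, upper-stopband gain {atten:.3f}",
        stacklevel=2,
    )
    return FIRDesign(taps=taps, transition_hz=trans, order=order, meets_spec=False)


def _fir_meets_spec(taps, low, high, trans, fs, delta_p, delta_s) -> bool:
    w, h = signal.freqz(taps, worN=4096, fs=fs)
    mag = np.abs(h)
    passband = (w >= low) & (w <= high)
    stop = (w <= max(low - 2 * trans, 0.0)) | (w >= high + 2 * trans)
    ok_pass = np.all(np.abs(mag[passband] - 1) <= delta_p * 1.05)
    ok_stop = np.all(mag[stop] <= delta_s * 1.05)
    return bool(ok_pass and ok_stop)


def bandpass(
    ts: TimecourseSet,
    low: float,
    high: float,
    design: str = "fir_equiripple",
    order: int | None = None,
    transition_hz: float = 0.005,
) -> tuple[TimecourseSet, np.ndarray]:
    """Bandpass filter every column; returns (filtered set, edge-flag mask).

    ``fir_equiripple`` applies a linear-phase FIR with exact group-delay
    compensation; the first and last ``ceil(order/2)`` samples are usable but
    flagged True in the returned mask. ``butterworth`` applies the filter
    forward-backward (zero phase); its mask flags one filter length at each
    end.
    """
    fs = 1.0 / ts.tr
    nyq = fs / 2
    if not (0 < low < high < nyq):
        raise ValueError(f"need 0 < {low} < {high} < Nyquist {nyq} Hz")
    t = ts.n_timepoints
    edge_mask = np.zeros(t, dtype=bool)
    if design == "fir_equiripple":
        max_taps = t // 3 if order is None else order + 1
        fir = design_fir_bandpass(
            low, high, fs, transition_hz=transition_hz, max_taps=max_taps
        )
        taps = fir.taps
        delay = (len(taps) - 1) // 2
        padded = np.vstack([ts.data, np.zeros((delay, ts.n_components))])
        out = signal.lfilter(taps, [1.0], padded, axis=0)[delay:]
        n_edge = int(np.ceil(fir.order / 2))
        edge_mask[:n_edge] = True
        edge_mask[t - n_edge :] = True
    elif design == "butterworth":
        n = 5 if order is None else order
        sos = signal.butter(n, [low, high], btype="bandpass", fs=fs, output="sos")
        if t <= 3 * (2 * n + 1):
            raise ValueError(f"series too short for order-{n} Butterworth: T={t}")
        out = signal.sosfiltfilt(sos, ts.data, axis=0)
        n_edge = min(3 * n, t // 4)
        edge_mask[:n_edge] = True
        edge_mask[t - n_edge :] = True
    else:
        raise ValueError(f"unknown filter design {design!r}")
    return ts.copy_with(out), edge_mask


@dataclass
class FDResult:
    fd: np.ndarray  # mm, length T, fd[0] = 0
    mfd: float  # mean framewise displacement, mm
    max_translation: np.ndarray  # per-axis max |translation|, mm


def framewise_displacement(
    motion_params: np.ndarray,
    head_radius: float = 50.0,
    rotations_in_degrees: bool = False,
) -> FDResult:
    """Per-sample head-motion summary.

    ``FD(t) = sum |d translation| + head_radius * sum |d rotation|`` with
    rotations converted to arc length at the given head radius (mm);
    ``FD(0) = 0``.
    """
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError("motion parameters must be T x 6")
    if mp.shape[0] < 2:
        raise ValueError("need at least two time points")
    trans, rot = mp[:, :3], mp[:, 3:]
    if rotations_in_degrees:
        rot = np.deg2rad(rot)
    d_trans = np.abs(np.diff(trans, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(rot, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + head_radius * d_rot])
    return FDResult(
        fd=fd,
        mfd=float(fd.mean()),
        max_translation=np.abs(trans).max(axis=0),
    )


def standard_prep(
    ts: TimecourseSet,
    low: float = 0.01,
    high: float = 0.08,
    design: str = "fir_equiripple",
    despike: bool = True,
    trim_edges: bool = False,
) -> TimecourseSet:
    """The canonical cleanup chain used before phase-synchrony analysis."""
    out = detrend(ts)
    if out.motion_params is not None:
        out = regress_nuisance(out)
    if despike:
        out, _ = despike_mad(out)
    out, edge_mask = bandpass(out, low, high, design=design)
    if trim_edges:
        keep = ~edge_mask
        trimmed = out.copy_with(out.data[keep])
        if out.motion_params is not None:
            trimmed.motion_params = out.motion_params[keep]
        return trimmed
    return out
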