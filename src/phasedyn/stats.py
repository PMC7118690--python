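"""Group inference: permutation t tests, FDR, effect sizes, regressions.

Group differences in phase-synchrony measures are tested with
permutation-based t tests (Welch statistic for two independent samples,
sign-flip null for paired differences; exhaustive enumeration whenever all
arrangements fit the permutation budget), corrected across measures with
Benjamini-Hochberg FDR, and accompanied by Cohen's d and percentile
bootstrap confidence intervals. Diagnostic value of a measure is assessed by
OLS of the 0/1 group label on the measure plus confounds (age, gender and
optionally mean framewise displacement), with an overall-model F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "permutation_ttest",
    "fdr_bh",
    "cohens_d",
    "bootstrap_ci",
    "regress_diagnosis",
    "drowsiness_trend",
    "motion_association",
    "signed_neglog_q",
    "compare_groups",
    "GroupComparison",
    "RegressionResult",
]


@dataclass
class GroupComparison:
    measure_name: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_perm: float
    q_fdr: float
    cohens_d: float
    n_permutations: int
    seed: int
    paired: bool


@dataclass
class RegressionResult:
    measure_name: str
    beta_measure: float
    beta_age: float | None
    beta_gender: float | None
    beta_mfd: float | None
    intercept: float
    adjusted_r2: float
    f_statistic: float
    p_f: float
    q_fdr: float | None = None


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    denom = np.sqrt(va + vb)
    diff = a.mean() - b.mean()
    if denom == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / denom)


def _paired_t(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        m = d.mean()
        return 0.0 if m == 0 else float(np.sign(m) * np.inf)
    return float(d.mean() / (sd / np.sqrt(d.size)))


def permutation_ttest(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    paired: bool = False,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided permutation t test.

    Unpaired: observed Welch t; null by random relabelling of the pooled
    samples. Paired: t of the differences; null by random sign flips. When
    the total number of distinct arrangements is at most ``n_perm`` the null
    is enumerated exhaustively and the p value is exact
    (``count / n_arrangements``); otherwise Monte Carlo with the add-one
    correction ``(1 + count) / (n_perm + 1)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    if paired:
        if a.size != b.size or a.size < 3:
            raise ValueError("paired test needs equal lengths >= 3")
        d = a - b
        t_obs = _paired_t(d)
        if d.std(ddof=1) == 0 and d.mean() == 0:
            return 0.0, 1.0
        n = d.size
        if 2**n <= n_perm:
            count = 0
            total = 2**n
            for mask in range(total):
                signs = 1 - 2 * ((mask >> np.arange(n)) & 1)
                if abs(_paired_t(d * signs)) >= abs(t_obs) - 1e-12:
                    count += 1
            return t_obs, count / total
        count = 0
        for _ in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)
            if abs(_paired_t(d * signs)) >= abs(t_obs) - 1e-12:
                count += 1
        return t_obs, (1 + count) / (n_perm + 1)
    if a.size < 3 or b.size < 3:
        raise ValueError("unpaired test needs at least 3 samples per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t_obs = _welch_t(a, b)
    pooled = np.concatenate([a, b])
    n_a = a.size
    n_total = pooled.size
    from math import comb

    if comb(n_total, n_a) <= n_perm:
        count = 0
        total = comb(n_total, n_a)
        idx_all = frozenset(range(n_total))
        for idx in combinations(range(n_total), n_a):
            sel = np.array(idx)
            rest = np.array(sorted(idx_all - set(idx)))
            if abs(_welch_t(pooled[sel], pooled[rest])) >= abs(t_obs) - 1e-12:
                count += 1
        return t_obs, count / total
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        if abs(_welch_t(pooled[perm[:n_a]], pooled[perm[n_a:]])) >= abs(t_obs) - 1e-12:
            count += 1
    return t_obs, (1 + count) / (n_perm + 1)


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two samples per group")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        warnings.warn("zero pooled SD: Cohen's d undefined", stacklevel=2)
        return np.nan if a.mean() != b.mean() else 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def bootstrap_ci(
    samples: np.ndarray,
    statistic,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval over subject-level resampling."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 5:
        raise ValueError("need at least 5 samples to bootstrap")
    rng = np.random.default_rng(seed)
    boots = np.array(
        [
            statistic(samples[rng.integers(0, samples.size, size=samples.size)])
            for _ in range(n_boot)
        ]
    )
    alpha = (1 - level) / 2
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    if lo == hi:
        warnings.warn("degenerate statistic: zero-width interval", stacklevel=2)
    return float(lo), float(hi)


def regress_diagnosis(
    measure: np.ndarray,
    labels: np.ndarray,
    age: np.ndarray | None = None,
    gender: np.ndarray | None = None,
    mfd: np.ndarray | None = None,
) -> RegressionResult:
    """OLS of the 0/1 diagnosis label on a measure plus confounds.

    The design is intercept + measure [+ age + gender + mfd]; collinear
    columns are dropped with a warning. Returns coefficients, adjusted R²
    and the overall-model F test; FDR across measures is the caller's job.
    """
    y = np.asarray(labels, dtype=float)
    cols = {"measure": np.asarray(measure, dtype=float)}
    if age is not None:
        cols["age"] = np.asarray(age, dtype=float)
    if gender is not None:
        cols["gender"] = np.asarray(gender, dtype=float)
    if mfd is not None:
        cols["mfd"] = np.asarray(mfd, dtype=float)
    x = pd.DataFrame(cols)
    if y.size <= x.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    design = sm.add_constant(x)
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        keep = ["const"]
        for c in x.columns:
            trial = design[keep + [c]].values
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep.append(c)
            else:
                warnings.warn(f"dropping collinear regressor {c!r}", stacklevel=2)
        design = design[keep]
    fit = sm.OLS(y, design).fit()

    def coef(name):
        return float(fit.params[name]) if name in fit.params else None

    return RegressionResult(
        measure_name="",
        beta_measure=coef("measure"),
        beta_age=coef("age"),
        beta_gender=coef("gender"),
        beta_mfd=coef("mfd"),
        intercept=float(fit.params["const"]),
        adjusted_r2=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        p_f=float(fit.f_pvalue),
    )


def drowsiness_trend(
    label_sequences: list[np.ndarray], k: int, window: int = 5
) -> pd.DataFrame:
    """Linear trend of each state's occurrence rate over the session.

    Per subject and state, the occurrence fraction is computed in
    consecutive non-overlapping windows and a least-squares line fitted
    across windows; the slopes are tested against zero with a one-sample t
    test across subjects. States that never occur for a subject contribute a
    zero slope (their rate is identically zero).
    """
    t_len = min(len(s) for s in label_sequences)
    if t_len < 3 * window:
        raise ValueError(f"need T >= {3 * window} samples")
    n_win = t_len // window
    centers = np.arange(n_win, dtype=float)
    slopes = np.zeros((len(label_sequences), k))
    for i, seq in enumerate(label_sequences):
        seq = np.asarray(seq, dtype=int)[: n_win * window]
        wins = seq.reshape(n_win, window)
        for s in range(1, k + 1):
            rate = (wins == s).mean(axis=1)
            slopes[i, s - 1] = np.polyfit(centers, rate, 1)[0]
    rows = []
    for s in range(k):
        t, p = sps.ttest_1samp(slopes[:, s], 0.0)
        rows.append(
            {
                "state": s + 1,
                "mean_slope": slopes[:, s].mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def motion_association(
    label_sequences: list[np.ndarray],
    fd_series: list[np.ndarray],
    k: int,
) -> tuple[pd.DataFrame, float, float, tuple[int, int]]:
    """State-motion coupling: occurrence-FD correlations and rm-ANOVA.

    Per state, the Pearson correlation between the pooled binary occurrence
    indicator and the pooled framewise displacement; plus a classic one-way
    repeated-measures ANOVA on per-subject state-conditioned mean FD
    (subjects lacking any state are excluded listwise). Returns the
    correlation table, the ANOVA F, its p value, and (df1, df2).
    """
    if len(label_sequences) != len(fd_series):
        raise ValueError("need one FD series per label sequence")
    pooled_labels = np.concatenate([np.asarray(s, int) for s in label_sequences])
    pooled_fd = np.concatenate([np.asarray(f, float) for f in fd_series])
    if pooled_labels.size != pooled_fd.size:
        raise ValueError("FD series must align with label series")
    rows = []
    fd_scale = max(1.0, float(np.abs(pooled_fd).max(initial=0.0)))
    const_fd = pooled_fd.std() <= 1e-12 * fd_scale
    for s in range(1, k + 1):
        ind = (pooled_labels == s).astype(float)
        if const_fd or ind.std() == 0:
            rows.append({"state": s, "r": 0.0, "degenerate": True})
            continue
        r = float(np.corrcoef(ind, pooled_fd)[0, 1])
        rows.append({"state": s, "r": r, "degenerate": False})
    # state-conditioned mean FD per subject, listwise complete subjects only
    cell_means = []
    for seq, fd in zip(label_sequences, fd_series):
        seq = np.asarray(seq, int)
        fd = np.asarray(fd, float)
        means = [
            fd[seq == s].mean() if np.any(seq == s) else np.nan
            for s in range(1, k + 1)
        ]
        if not np.any(np.isnan(means)):
            cell_means.append(means)
    if len(cell_means) < 3:
        raise ValueError("fewer than 3 complete subjects for rm-ANOVA")
    y = np.asarray(cell_means)  # subjects x states
    n, kk = y.shape
    grand = y.mean()
    ss_states = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = kk * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_states - ss_subj
    df1, df2 = kk - 1, (kk - 1) * (n - 1)
    tol = 1e-12 * max(1.0, float(np.abs(y).max()) ** 2) * y.size
    if ss_err <= tol:
        f_stat, p = (0.0, 1.0) if ss_states <= tol else (np.inf, 0.0)
    else:
        f_stat = (ss_states / df1) / (ss_err / df2)
        p = float(sps.f.sf(f_stat, df1, df2))
    return pd.DataFrame(rows), float(f_stat), float(p), (df1, df2)


def signed_neglog_q(q: float, t_sign: float, cap: float = 100.0) -> float:
    """Display transform -10*log10(q)*sign(t); q = 0 capped with a warning."""
    if q < 0 or q > 1:
        raise ValueError("q must lie in (0, 1]")
    sign = float(np.sign(t_sign))
    if q == 0:
        warnings.warn("q = 0 capped for display", stacklevel=2)
        return cap * sign
    return float(-10.0 * np.log10(q) * sign)


def compare_groups(
    measures: pd.DataFrame,
    group_col: str = "group",
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation t test + FDR + Cohen's d for every measure column.

    ``measures`` has one row per subject, a 0/1 ``group`` column, and one
    column per measure. Rows with NaN in a measure are dropped for that
    measure only. Returns one row per measure with t, permutation p,
    BH-adjusted q, and Cohen's d (group 0 minus group 1).
    """
    measure_cols = [c for c in measures.columns if c != group_col]
    rows = []
    for j, col in enumerate(measure_cols):
        sub = measures[[group_col, col]].dropna()
        a = sub.loc[sub[group_col] == 0, col].to_numpy()
        b = sub.loc[sub[group_col] == 1, col].to_numpy()
        t, p = permutation_ttest(a, b, n_perm=n_perm, seed=seed + j)
        rows.append(
            {
                "measure": col,
                "mean_g0": a.mean(),
                "mean_g1": b.mean(),
                "sem_g0": a.std(ddof=1) / np.sqrt(a.size),
                "sem_g1": b.std(ddof=1) / np.sqrt(b.size),
                "t": t,
                "p_perm": p,
                "cohens_d": cohens_d(a, b),
            }
        )
    out = pd.DataFrame(rows)
    out["q_fdr"] = fdr_bh(out["p_perm"].to_numpy())
    return out
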