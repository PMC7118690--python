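# Methods

This note records the models, parameter choices and numerical decisions
behind `phasedyn`, and what the synthetic validation does and does not
establish about real data.

## Signal model of the synthetic cohort

Each subject is a hidden-Markov process over K = 8 phase-coupling states.
State k fixes one phase offset per component, organised as network-level
*cliques*: every one of the 7 networks is assigned an angle from
{0, π/3, 2π/3, π}, and all components of a network share it. The noise-free
IPS of state k between components p and q is therefore exactly
`cos(θ_kp − θ_kq)` ∈ {±1, ±0.5}. Component c's signal is

    x_c(t) = cos(2π f t·TR + w(t) + θ_{s(t),c} + ε_c(t)) + η_c(t)

with carrier f = 0.04 Hz (mid-band of the 0.01–0.08 Hz analysis band,
±0.005 Hz uniform per-subject jitter), per-sample phase jitter
ε ~ N(0, 0.2²) rad, additive noise η ~ N(0, 0.1²), and a *common-mode*
phase random walk w(t) (step SD 0.35 rad/sample, shared by all components
of a subject).

Two choices deserve explanation:

* **Pattern separation.** IPS is blind to a global rotation or reflection
  of the offsets (cos is even), so distinctness of states must be enforced
  in IPS space, not on angles. The default patterns are drawn by greedy
  max-min selection over 400 random clique candidates, giving minimum
  pairwise IPS distance ≈ 35 (L2 over 1225 entries). Without this, randomly
  drawn states can be near-duplicates in IPS space and no clustering method
  can separate them.
* **Common phase drift.** The walk cancels exactly in every pairwise phase
  difference, so it changes neither the planted IPS nor state recovery. Its
  purpose is spectral realism: real slow oscillations wander in frequency,
  and surrogate methods (phase shuffling, circular shifting) rely on that
  bandwidth to decorrelate. A drift-free pure carrier makes surrogates
  degenerate — each column stays a sinusoid at the same frequency, phase
  differences are constant in time, and every surrogate subject freezes
  into a single random coupling pattern. With the walk, each column has
  ≈ 0.03 Hz of instantaneous-frequency spread and surrogates wander as they
  do for real data.

### Two temporal presets

* `default_transition_matrix()` — dwell 0.92 (mean state lifetime ≈ 25 s at
  TR = 2 s), within-block off-diagonal mass 3× the across-block mass. The
  slow clock is deliberate: the analytic-phase estimate of a 0.01–0.08 Hz
  signal has ≈ 14 s of temporal support (the band-limited filter plus the
  Hilbert kernel), so states living only a few samples are smeared into
  their neighbours and are unrecoverable *in principle* at this sampling
  rate. Lifetimes must comfortably exceed that support for the clustering
  stage to see them; this is a physical constraint of phase-based state
  analysis, not an implementation artifact.
* `paperlike_transition_matrix()` — state dwell 0.7, metastate dwell 0.85,
  matching the temporal magnitudes typically reported for empirical
  phase-coupling states. Metastates then alternate ~10 times per
  145-sample session, so per-subject occupancy *ratios* (MS2/MS1) are well
  estimable. This is the right regime for exercising the group-statistics
  machinery: under the slow default chain a session holds only ~3 metastate
  runs, occupancy ratios are dominated by a heavy right tail (a subject that
  visits MS1 for a single sample contributes a ratio of 144), and no test on
  raw ratios can be well powered, regardless of the planted effect size.

The group effect multiplies across-block exit probabilities by (1 + s) for
metastate-1 rows and (1 − s) for metastate-2 rows (rows renormalized),
s = `group_occupancy_shift` = 0.5 by default, tilting group 1's stationary
occupancy toward metastate 2 without touching within-block structure.

## Preprocessing

Canonical order: linear detrend → nuisance regression (motion parameters
plus first differences, constant always included; rank-deficient designs
reduced with a warning) → MAD despiking (robust z > 5 replaced by a cubic
spline through clean samples; linear near series ends) → bandpass.

Two filters are used: a linear-phase equiripple FIR for the phase band
(0.01–0.08 Hz), applied with exact group-delay compensation, and a 5th-order
Butterworth applied forward–backward (zero phase) for the static-connectivity
band (0.01–0.15 Hz). The FIR designer searches for the smallest even order
meeting ±0.5 dB passband ripple and 20 dB stopband attenuation with a
0.005 Hz transition, capped at T/3 taps. At T = 145 and TR = 2 s that spec
needs ≈ 100+ taps and cannot be met within the cap — a resolution limit of
the record length, not of the design method — so the designer falls back to
the largest admissible order and reports the achieved ripple/attenuation in
a warning. Linear phase is exact either way; ripple perturbs amplitudes
only, and phase-synchrony analysis is insensitive to amplitude. Edge samples
within half the filter length are flagged; they are kept by default (a
`trim_edges` switch removes them).

Framewise displacement is the sum of absolute translation increments plus
head-radius-scaled (50 mm) absolute rotation increments, with FD(0) = 0.

## State clustering

The pooled MN × MN angular-similarity matrix is computed blockwise; angles
are evaluated through chord lengths of the unit-normalized vectors, which is
exact at both bounds (self-similarity exactly 1, antipodal exactly 0) and
accurate at small angles where arccos of a dot product loses half the
significant digits. The graph has no self-loops (diagonal zeroed); degrees
are off-diagonal row sums; the embedding uses the k smallest eigenvectors of
`L_sym = I − D^{−1/2} W D^{−1/2}`, computed by a Lanczos iteration with a
fixed start vector (determinism) for large pooled samples and dense
factorization below n = 400, rows scaled to unit norm, eigenvector signs
fixed by the largest-magnitude entry.

Clustering per candidate k is a Gaussian mixture with **tied** covariance,
10 restarts, covariance floor 1e−6, hard assignment by maximum posterior,
with refits on empty clusters. Tied rather than per-component full
covariance: on row-normalized spectral embeddings the clusters are compact
and comparably spread, and full covariances systematically inflate to
swallow neighbouring clusters (label agreement with planted states dropped
from ≈ 0.86 to ≈ 0.48 ARI in our recovery experiments).

The Davies–Bouldin index (classic definition; errors on coincident
centroids) is computed **on the raw IPS vectors** by default, so every
candidate k is scored in one common metric space. Scoring each candidate in
its own k-dimensional embedding (available via `db_space="embedding"`) is
dimension-inconsistent — scatter/separation ratios shrink with embedding
dimension, biasing selection toward k = 2 regardless of structure. States
are relabelled by descending prevalence; centroids are recomputed as means
of the original IPS vectors.

## Metastates and dynamics

The transition graph is symmetrized as (T + Tᵀ)/2 with the diagonal removed;
the Fiedler vector of the unnormalized Laplacian (a normalized variant is a
switch; immaterial at K = 8) splits states by sign, near-zero entries
joining the smaller side — for disconnected graphs the Fiedler vector is a
component indicator and the zero entries form the other side. Metastate 1
is the side with the higher mean centroid coupling. Validation uses
average-linkage clustering on 1 − max-normalized affinity with the
cophenetic correlation as a structure score. Group-level transition matrices
are entrywise means of per-subject matrices (NaN rows of unvisited states
ignored).

Transition-vs-similarity correlations relate the K(K−1)/2 symmetrized
off-diagonal mean transition probabilities to state-pair similarities:
centroid Pearson correlation (pattern), negative absolute difference of
subject-mean values (prevalence, persistence — a monotone, rank-preserving
choice), and optionally the correlation of state-conditioned mean component
amplitudes (activity). CIs are percentile bootstrap over subject resampling
(default 1000 resamples).

## Trajectory measures

All five L1 measures (length, span, capacity, efficiency, smoothness) are
computed from consecutive-step distances and the full pairwise distance set
(unordered pairs, self-pairs excluded). Consecutive distances below an
epsilon floor (1e−6) are floored for the smoothness reciprocal and counted;
a constant trajectory is flagged degenerate rather than producing infinities.

## Statistics

Permutation t tests use the Welch statistic (unpaired) or the paired t of
differences with a sign-flip null; when the number of distinct arrangements
fits the permutation budget the null is enumerated exhaustively and p is
exact (`count/total`), otherwise Monte Carlo with the add-one correction.
Degenerate inputs (zero-variance) map to t = ±∞ or 0 explicitly. FDR is
Benjamini–Hochberg step-up. The one-way repeated-measures ANOVA for
state-conditioned motion uses the classic decomposition with listwise
exclusion of subjects lacking any state (cross-checked against an
independent implementation in the tests). The diagnosis regression is OLS
of the 0/1 label on intercept + measure + age + gender (+ mean FD — the
confound set includes motion by default), with adjusted R² and the
overall-model F test; q values across measures are the caller's job.

## What the synthetic validation does and does not show

The generator plants exactly the structure the pipeline is designed to
detect: narrowband signals, a finite repertoire of well-separated coupling
patterns, block-structured Markov switching, and a clean group effect. The
passing recovery suites therefore establish the *correctness of the
machinery* — phases are estimated faithfully, the similarity/embedding/
mixture path finds the right number and membership of states, the Fiedler
bipartition finds planted blocks, trajectory metrics equal brute-force
enumeration, and the statistics control type-I error while detecting
planted effects. They do **not** establish that real resting-state data
contains such states: empirical signals are broadband within the analysis
band, state patterns overlap, lifetimes are shorter than the default chain's
(see the paper-like preset), and artifacts (motion, drowsiness) correlate
with dynamics — which is what the motion-association, drowsiness-trend and
surrogate controls are for on real data.

One surrogate caveat is known and deliberate: with network-level clique
patterns, within-network pairs are phase-locked in *every* state, so
circular-shift surrogates — whose columns keep their waveform and can
receive near-equal shifts — retain a few near-coherent pairs. The
max-minus-min centroid entry range of surrogate states therefore stays
around 55–65% of the empirical value rather than collapsing below half,
even though surrogate Davies–Bouldin scores are ~20× worse than empirical
ones (the meaningful control). Forcing the range lower with stronger
spectral drift starts to erode genuine state recovery; we keep the honest
configuration.

## Problem sizes used in the validation suite

Recovery suites run on the default cohort (2 × 10 subjects × 145 samples =
2,900 pooled IPS vectors of dimension 1,225); power and type-I suites use
20 and 100 label-level replicates at n = 20+20 and 10+10 subjects with
1,000 permutations per test; the trajectory oracle checks 50 random
sessions up to N = 200 samples. These sizes make the full suite run in
about a minute while keeping every estimate's sampling error far from the
asserted margins.
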