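"""Cluster-free view: L1 geometry of each subject's IPS trajectory.

Computes the five trajectory measures (length, span, capacity, efficiency,
smoothness) for two subjects of the default cohort and for a surrogate
version of one of them. Length is the total L1 path through the 1225-d IPS
space; span/capacity describe how much of the space the session explores;
efficiency is capacity per unit path; smoothness is the mean reciprocal of
consecutive step sizes (large = gradual evolution).
"""

import warnings

import phasedyn as pdn
from phasedyn import clustering, ips, prep, trajectory

cfg = pdn.default_config()
cfg.n_subjects_per_group = 2
subjects, _ = pdn.generate_cohort(cfg)


def metrics_of(ts):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean = prep.standard_prep(ts, 0.01, 0.08)
    series = ips.ips_series(ips.analytic_signal(clean))
    return trajectory.trajectory_metrics(series)


header = f"{'subject':<16}{'length':>9}{'span':>8}{'capacity':>10}{'efficiency':>12}{'smoothness':>12}"
print(header)
for ts in subjects[:2]:
    m = metrics_of(ts)
    print(
        f"{ts.subject_id:<16}{m.length:>9.0f}{m.span:>8.1f}{m.capacity:>10.1f}"
        f"{m.efficiency:>12.4f}{m.smoothness:>12.4f}"
    )

surr = clustering.make_surrogate(subjects[0], "phase_shuffle", 1)
m = metrics_of(surr)
print(
    f"{'phase-shuffled':<16}{m.length:>9.0f}{m.span:>8.1f}{m.capacity:>10.1f}"
    f"{m.efficiency:>12.4f}{m.smoothness:>12.4f}"
)
print("\nSurrogates keep wandering but lose the recurrent state structure;")
print("their path length stays comparable while organized revisits vanish.")
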