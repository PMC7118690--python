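"""Shared fixtures: small deterministic inputs plus one session-scoped
default-cohort clustering run reused by the recovery tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import phasedyn as pdn
from phasedyn import clustering, ips as ipsmod, prep


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_ts(rng):
    """A 64-sample, 6-component narrowband set with two networks."""
    t = np.arange(64) * 2.0
    phases = np.array([0, 0, np.pi / 2, np.pi / 2, np.pi, np.pi])
    data = np.cos(2 * np.pi * 0.04 * t[:, None] + phases[None, :])
    data += 0.01 * rng.standard_normal(data.shape)
    return pdn.TimecourseSet(
        subject_id="s1",
        data=data,
        tr=2.0,
        module_map=np.array([1, 1, 1, 2, 2, 2]),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort with its planted ground truth."""
    cfg = pdn.default_config()
    subjects, truth = pdn.generate_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def default_ips(default_cohort):
    """Cleaned, band-limited IPS series of the default cohort."""
    _, subjects, _ = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cleaned = [prep.standard_prep(ts, 0.01, 0.08) for ts in subjects]
    return [
        ipsmod.ips_series(ipsmod.analytic_signal(ts), group=ts.group)
        for ts in cleaned
    ]


@pytest.fixture(scope="session")
def fitted_model(default_ips):
    """State model fitted once on the default cohort (expensive)."""
    return clustering.fit_states(default_ips, seed=0)


@pytest.fixture(scope="session")
def pooled_truth(default_cohort):
    _, _, truth = default_cohort
    return np.concatenate([truth.state_labels[s] for s in truth.subject_ids])
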