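"""Shared fixtures: canonical patients and cached simulated sessions."""

import numpy as np
import pytest

import blinkpk as b
from blinkpk.synth import PopulationConfig


@pytest.fixture(scope="session")
def mean_demographics():
    """The studied cohort's mean patient (female branch)."""
    return b.Demographics(age=61.0, weight=72.0, height=162.0, sex="female")


@pytest.fixture(scope="session")
def sd0_population():
    """Degenerate population: every draw is the mean patient."""
    return PopulationConfig(
        ce_lor2_sd=0.0, ce_lor1_sd=0.0, ce_lorp_sd=0.0,
        age_sd=0.0, weight_sd=0.0, height_sd=0.0, p_female=1.0,
        noise_sd_uv=0.0,
    )


@pytest.fixture(scope="session")
def mean_profile(mean_demographics):
    """Mean-threshold, noise-free patient profile."""
    return b.PatientProfile(
        demographics=mean_demographics,
        ce_lor2=1.45, ce_lor1=2.99, ce_lorp=4.22,
        noise_sd_uv=0.0, latency_jitter_ms=0.0,
    )


@pytest.fixture(scope="session")
def noisefree_session(mean_profile):
    """One full noise-free induction of the mean patient."""
    return b.simulate_session(mean_profile, b.session_rng(0, 0))


@pytest.fixture(scope="session")
def noisy_session(mean_demographics):
    """One induction with the default 2-µV noise floor."""
    profile = b.PatientProfile(
        demographics=mean_demographics,
        ce_lor2=1.45, ce_lor1=2.99, ce_lorp=4.22,
    )
    return b.simulate_session(profile, b.session_rng(3, 0))
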