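"""Shared fixtures: expensive simulations are computed once per session."""

import numpy as np
import pytest

import riskbn
from riskbn.transforms import apply_transforms


@pytest.fixture(scope="session")
def designs20():
    return riskbn.build_designs(20, seed=0)


@pytest.fixture(scope="session")
def indicator_table(designs20):
    return riskbn.simulate_indicators(designs20, seed=1)


@pytest.fixture(scope="session")
def transformed(indicator_table):
    return apply_transforms(indicator_table)


@pytest.fixture(scope="session")
def clean_trace_session():
    """One zero-noise simulated session, fully processed through the signal
    chain (preprocess -> decompose -> detect)."""
    design = riskbn.build_design(seed=2)
    sim = riskbn.simulate_traces(
        design,
        seed=7,
        noise_sd_us=0.0,
        tonic_drift_us_per_min=0.0,
        amplitude_floor_us=0.1,
    )
    pre = riskbn.preprocess(sim.eda)
    tonic, driver = riskbn.decompose(pre)
    events = riskbn.detect_scrs(driver)
    return {
        "design": design,
        "sim": sim,
        "pre": pre,
        "tonic": tonic,
        "driver": driver,
        "events": events,
    }


@pytest.fixture(scope="session")
def noisy_benchmark_sessions():
    """Detector benchmark: noisy sessions with events of at least 0.1 uS."""
    out = []
    for seed in range(3):
        design = riskbn.build_design(seed=seed)
        sim = riskbn.simulate_traces(
            design, seed=100 + seed, noise_sd_us=0.01, amplitude_floor_us=0.1
        )
        pre = riskbn.preprocess(sim.eda)
        _, driver = riskbn.decompose(pre)
        events = riskbn.detect_scrs(driver)
        out.append((sim, events))
    return out
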