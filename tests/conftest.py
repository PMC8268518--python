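"""Shared fixtures: short synthetic traces keep the unit tests fast."""

import numpy as np
import pytest

from smbjid.preprocess import ConductanceTrace, PreprocessConfig, preprocess_dataset
from smbjid.synthetic_data import ClassSignature, SimulatorConfig, simulate_dataset
from smbjid.trace_io import CurrentTrace


@pytest.fixture
def fast_sim_cfg() -> SimulatorConfig:
    """Short (0.1 s) traces: 3000 samples at 30 kHz."""
    return SimulatorConfig(trace_duration=0.1, decay_time=0.02)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trace(samples, fs=30000.0, bias=0.1, label="S1", trace_id="S1:0"):
    return CurrentTrace(
        samples=np.asarray(samples, dtype=float),
        sampling_rate=fs,
        bias_voltage=bias,
        dataset_label=label,
        trace_id=trace_id,
    )


def make_conductance(values, label="S1", trace_id="S1:0"):
    return ConductanceTrace(
        values=np.asarray(values, dtype=float),
        source_trace_id=trace_id,
        dataset_label=label,
    )


@pytest.fixture(scope="session")
def three_class_pools():
    """Small preprocessed pools for three well-separated classes."""
    cfg = SimulatorConfig(trace_duration=0.1, decay_time=0.02)
    sigs = {
        lab: ClassSignature((center,), (0.08,), (1.0,), plateau_prob=1.0, n_plateaus_mean=2.0)
        for lab, center in [("A", -5.5), ("B", -4.0), ("C", -2.5)]
    }
    raw, _ = simulate_dataset(sigs, cfg, 160, seed=99)
    return {lab: preprocess_dataset(traces, PreprocessConfig())[0] for lab, traces in raw.items()}
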