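"""Shared fixtures: noise-free study conditions and small synthetic cohorts."""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from tcdflow import FLOW_TYPES, SimConfig, generate_recording, process_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noise-free, artifact-free recording conditions with mild HR variability."""
    return SimConfig(noise_sd=0.0, artifact_beat_rate=0.0, heart_rate_sd=4.0)


def make_typed_beats(cfg, n_per_type, seed, group_of=None):
    """Normalized beats for each flow type with their planted type labels."""
    rng = np.random.default_rng(seed)
    beats, truth = [], []
    for ft, spec in FLOW_TYPES.items():
        group = group_of(ft) if group_of else "IHC"
        for i in range(n_per_type):
            rec = generate_recording(
                cfg, spec, rng, subject_id=f"{ft}{i:03d}", group=group
            )
            nb, reason = process_recording(rec)
            assert nb is not None, f"{ft} recording {i} excluded: {reason}"
            beats.append(nb)
            truth.append(ft)
    return beats, truth


@pytest.fixture(scope="session")
def typed_cohort():
    """Session-scoped noise-free cohort: 20 normalized beats per flow type."""
    cfg = SimConfig(noise_sd=0.0, artifact_beat_rate=0.0, heart_rate_sd=4.0)
    return make_typed_beats(cfg, 20, seed=777)
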