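import numpy as np
import pandas as pd
import pytest

from megdenoise import MultiSubjectDataset, SensorTable, SimConfig, generate, make_folds


def make_sensor_table(n=6):
    regions = ["left-occipital", "left-temporal", "right-temporal",
               "left-parietal", "right-parietal", "other"]
    return SensorTable(
        pd.DataFrame(
            {
                "sensor": [f"MEG{i}" for i in range(n)],
                "kind": ["gradiometer" if i % 2 == 0 else "magnetometer" for i in range(n)],
                "region": [regions[i % len(regions)] for i in range(n)],
                "x": np.cos(np.linspace(0, 2 * np.pi, n, endpoint=False)),
                "y": np.sin(np.linspace(0, 2 * np.pi, n, endpoint=False)),
            }
        )
    )


def make_dataset(n_subjects=2, n_events=40, n_sensors=6, n_time=5, n_runs=2, seed=0):
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1}" for i in range(n_subjects)]
    data = {s: rng.standard_normal((n_events, n_sensors, n_time)) for s in subjects}
    edges = np.linspace(0, n_events, n_runs + 1).round().astype(int)
    runs = list(zip(edges[:-1].tolist(), edges[1:].tolist()))
    return MultiSubjectDataset(
        subjects, data, np.arange(n_time) * 25.0, make_sensor_table(n_sensors), runs
    )


@pytest.fixture
def tiny_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic simulated session shared by slower tests."""
    # higher SNR than the default preset: with 3 subjects and 450 events the
    # cross-subject maps need a stronger shared signal to be identifiable
    cfg = SimConfig(
        n_subjects=3, n_events=450, n_runs=3, n_sensors=18, n_time=20, seed=11, snr=0.05
    )
    ds, stim, shared = generate(cfg)
    scheme = make_folds(ds.n_events, runs=ds.runs, n_edge_drop=15)
    return cfg, ds, stim, shared, scheme
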