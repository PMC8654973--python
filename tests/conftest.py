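import numpy as np
import pytest

from icumotion.features import WindowFeatureSeries, extract_features
from icumotion.synthetic import (CohortConfig, LatentTrajectory, SensorRecording,
                                 generate_patient, synthesize_accelerometry)


@pytest.fixture(scope="session")
def short_config():
    """One-hour cohort conditions used by most unit tests."""
    return CohortConfig(n_patients=4, recording_hours=1.0, seed=11,
                        missing_fraction=0.016)


@pytest.fixture(scope="session")
def patient_recording(short_config):
    return generate_patient(short_config, 0)


@pytest.fixture(scope="session")
def feature_series(patient_recording):
    return extract_features(patient_recording)


@pytest.fixture(scope="session")
def flat_level_recording():
    """One patient pinned at a single GCSm level per call (factory)."""
    def build(level, hours=0.5, seed=5, placements=("RW", "RA", "BED"), **kw):
        cfg = CohortConfig(n_patients=1, recording_hours=hours, seed=seed,
                           missing_fraction=0.0, **kw)
        traj = LatentTrajectory("PX", ((0.0, hours * 3600.0, level),))
        streams = {p: synthesize_accelerometry(traj, p, cfg, 7) for p in placements}
        return SensorRecording("PX", cfg.fs, streams, [], 3, 3, trajectory=traj)
    return build


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_window(x, y=None, z=None, fs=10.0, complete=True):
    """Convenience AccelWindow builder for feature tests."""
    from icumotion.preprocessing import AccelWindow
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
    return AccelWindow(x=x, y=y, z=z, fs=fs, start_time=0.0, placement="RW",
                       complete=complete)
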