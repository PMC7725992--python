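import numpy as np
import pytest

from pentrace.io import TaskRecording


def make_recording(
    flags,
    x=None,
    y=None,
    dt=10,
    task_id="l",
    pressure=None,
    azimuth=None,
    altitude=None,
):
    """Build a TaskRecording from a contact-flag sequence with simple
    defaults (10 ms sampling, linear x, constant y)."""
    n = len(flags)
    flags = np.asarray(flags, dtype=np.int64)
    return TaskRecording(
        task_id=task_id,
        t=np.arange(n, dtype=np.int64) * dt,
        x=np.asarray(x, dtype=float) if x is not None else np.arange(n, dtype=float),
        y=np.asarray(y, dtype=float) if y is not None else np.zeros(n),
        on_surface=flags,
        azimuth=np.asarray(azimuth, dtype=float) if azimuth is not None else np.full(n, 1800.0),
        altitude=np.asarray(altitude, dtype=float) if altitude is not None else np.full(n, 600.0),
        pressure=np.asarray(pressure, dtype=float)
        if pressure is not None
        else np.where(flags == 1, 50.0, 0.0),
    )


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture(scope="session")
def small_session():
    """One complete generated session, shared across tests."""
    from pentrace import synthetic

    rng = np.random.default_rng(42)
    return synthetic.generate_session(
        "S000", "dysgraphia", age=10, sex="M", handedness="R",
        config=synthetic.table1_config(seed=42), rng=rng,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-subject cohort with a strong planted effect, for fast
    pipeline-level tests (12 dysgraphia / 12 control)."""
    from dataclasses import replace

    from pentrace import synthetic

    cfg = replace(synthetic.table1_config(seed=5), n_subjects=24, n_dysgraphia=12)
    return synthetic.generate_cohort(cfg)
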