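import numpy as np
import pytest

import pilotmind as pm


@pytest.fixture(scope="session")
def montage20():
    return pm.make_montage(20)


@pytest.fixture(scope="session")
def small_sim():
    """Short balanced-ish recording with all artifact types, plus truth."""
    cfg = pm.SimConfig(
        class_durations={"NE": 60.0, "CA": 20.0, "DA": 20.0, "SS": 20.0},
        seed=101,
    )
    rec, truth = pm.simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def clean_epochs():
    """Artifact-free labelled epochs, 40 per class."""
    cfg = pm.SimConfig(
        class_durations={s: 40.0 for s in ("NE", "CA", "DA", "SS")},
        artifact_spec=pm.ArtifactSpec.none(),
        seed=7,
    )
    eps, truth = pm.synth.simulate_epochs(cfg)
    return eps, truth


def random_spd(rng, n, scale=1.0):
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T + n * np.eye(n))
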