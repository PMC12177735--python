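import numpy as np
import pytest
from hypothesis import settings

from photohop.dynamics import TrajectoryConfig, run_ensemble
from photohop.initial_conditions import sample_wigner
from photohop.model_systems import ModelSpec, build_model, normal_modes

# derandomized, seeded hypothesis profile: reproducible CI runs
settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ladder():
    return build_model(ModelSpec("ladder", {}))


@pytest.fixture(scope="session")
def ladder_modes(ladder):
    return normal_modes(ladder, ladder.reference_geometry())


@pytest.fixture(scope="session")
def small_oracle_ensemble(ladder, ladder_modes):
    """12 oracle trajectories, 300 fs — reused by several analysis tests."""
    ics = sample_wigner(ladder_modes, 12, seed=314)
    return run_ensemble(ladder, ics, TrajectoryConfig(max_time_fs=300.0),
                        base_seed=2718)


def rigid_rotation(seed: int) -> np.ndarray:
    """A deterministic proper rotation matrix."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
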