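import numpy as np
import pytest

from il18design import GeneratorConfig, gen_toy_structure, gen_trajectory


@pytest.fixture(scope="session")
def toy():
    """20-residue extended chain with one engineered H-bond (2.9 Å, 170°)."""
    return gen_toy_structure(20)


@pytest.fixture(scope="session")
def jitter_traj(toy):
    """Isotropic 0.5 Å jitter, 300 frames, no elevated loop, no rigid motion."""
    cfg = GeneratorConfig(seed=11, n_frames=300, base_amplitude=0.5,
                          loop_region=(0, 0), loop_amplitude_factor=1.0)
    return gen_trajectory(toy.frame, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
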