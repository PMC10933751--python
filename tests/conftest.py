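import numpy as np
import pytest

from segepi import sampling, synth


@pytest.fixture(scope="session")
def phantom48():
    return synth.make_phantom(synth.PhantomSpec())


@pytest.fixture(scope="session")
def compact_phantom48():
    """Small-support variant used by the low-rank premise checks."""
    return synth.make_phantom(synth.PhantomSpec(support_scale=0.2))


@pytest.fixture(scope="session")
def maps8():
    return synth.make_coil_maps(8, (48, 48), seed=0)


@pytest.fixture(scope="session")
def seg_schedule_g2():
    """Fully sampled 48x48 seg-CAIPI schedule with 2 shot groups."""
    cfg = sampling.TrajectoryConfig(
        ny=48, nz=48, ry=1, rz=1, width=2, dkz=1, scheme="seg_caipi"
    )
    return sampling.build_schedule(cfg)


@pytest.fixture(scope="session")
def std_schedule():
    """Fully sampled 48x48 standard sequential schedule."""
    cfg = sampling.TrajectoryConfig(
        ny=48, nz=48, ry=1, rz=1, width=1, dkz=0, scheme="standard"
    )
    return sampling.build_schedule(cfg)


@pytest.fixture(scope="session")
def slow_phase_model():
    """Phase model slow enough that each shot group is near-coherent."""
    return synth.PhaseModel(
        amplitudes=(0.24, 0.2, 0.16, 0.08, 0.08, 0.12),
        freq_hz=0.05,
        shot_tr=0.02,
    )


@pytest.fixture(scope="session")
def resp_phase_model():
    """Respiratory-like model with broadband jitter for tSNR fixtures."""
    return synth.PhaseModel(
        amplitudes=(0.24, 0.2, 0.16, 0.08, 0.08, 0.12),
        freq_hz=0.25,
        jitter_std=0.25,
        shot_tr=0.012,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
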