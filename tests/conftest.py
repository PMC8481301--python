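"""Shared fixtures: meshes, solvers, a trained GREIT matrix, and simulated
breathing recordings reused across test modules (session-scoped because
forward simulation dominates suite runtime)."""

import numpy as np
import pytest

import eitvent as ev


@pytest.fixture(scope="session")
def coarse_mesh():
    return ev.build_thorax_mesh("circle", 1)


@pytest.fixture(scope="session")
def mesh2():
    return ev.build_thorax_mesh("circle", 2)


@pytest.fixture(scope="session")
def solver2(mesh2):
    return ev.CEMForwardSolver(mesh2)


@pytest.fixture(scope="session")
def greit2(mesh2, solver2):
    """GREIT matrix trained on the refinement-2 mesh at defaults."""
    return ev.train_greit(mesh2, solver2)


@pytest.fixture(scope="session")
def protocol25():
    """Default breathing protocol sampled at 25 Hz to keep the suite fast."""
    return ev.BreathingProtocol(frame_rate=25.0)


@pytest.fixture(scope="session")
def sim_symmetric(mesh2, protocol25):
    return ev.PhantomSimulator(ev.PhantomConfig(right_weight=0.5),
                               protocol25, mesh=mesh2)


@pytest.fixture(scope="session")
def sim_right60(mesh2, protocol25):
    return ev.PhantomSimulator(ev.PhantomConfig(right_weight=0.6),
                               protocol25, mesh=mesh2)


@pytest.fixture(scope="session")
def run_pipeline(greit2, protocol25):
    """Factory: simulate one recording on a prepared simulator and analyse it."""

    def _run(simulator, noise_level=5e-4, seed=0, **kwargs):
        noise = ev.NoiseModel(relative_noise=noise_level, seed=seed)
        seq = simulator.noisy_frames(noise)
        spiro = ev.volume_waveform(simulator.protocol)
        return ev.analyze_recording(seq, spiro, greit2, **kwargs)

    return _run


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
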