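import numpy as np
import pytest

from pcpdyn.core_model import build_tracks
from pcpdyn.synthetic_tissue import SimConfig, generate_intensities, generate_tissue


@pytest.fixture(scope="session")
def control_sim():
    """A small control-regime movie with planted polarity, flow, T1s and rosettes."""
    cfg = SimConfig(n_cells=64, n_frames=25, seed=11)
    frames, gt = generate_tissue(cfg)
    traces, cyto = generate_intensities(frames, gt, cfg)
    return cfg, frames, gt, traces, cyto


@pytest.fixture(scope="session")
def control_tracks(control_sim):
    cfg, frames, gt, traces, _ = control_sim
    return build_tracks(frames, traces, eps_t2_um=cfg.eps_t2_um)


@pytest.fixture(scope="session")
def static_sim():
    """No flow, no events: geometry and intensities are time-constant up to noise."""
    cfg = SimConfig(
        n_cells=25, n_frames=5, seed=7, convergence_rate_per_s=0.0,
        n_t1_events=0, n_rosettes=0, noise_sd=0.0,
    )
    frames, gt = generate_tissue(cfg)
    traces, cyto = generate_intensities(frames, gt, cfg)
    return cfg, frames, gt, traces, cyto


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
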