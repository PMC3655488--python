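"""Shared fixtures: synthetic sessions at several scales.

Session-scoped fixtures keep the expensive simulations to one run each.
"""

import numpy as np
import pytest

import fingerdec as fd


@pytest.fixture(scope="session")
def small_setup():
    """Tiny default-effect session: 16 channels, 10 trials/finger."""
    montage = fd.make_montage(16, seed=5)
    cfg = fd.SimulationConfig(n_channels=16, n_trials_per_finger=10, seed=5)
    rec, gt = fd.simulate_session(cfg, montage)
    movement, rest = fd.preprocess_recording(rec)
    return {"montage": montage, "cfg": cfg, "rec": rec, "gt": gt,
            "movement": movement, "rest": rest}


@pytest.fixture(scope="session")
def default_session():
    """Full default-parameter session (64 channels, 80 trials/finger)."""
    montage = fd.make_montage(64, seed=7)
    cfg = fd.SimulationConfig(seed=7)
    rec, gt = fd.simulate_session(cfg, montage)
    movement, rest = fd.preprocess_recording(rec)
    return {"montage": montage, "cfg": cfg, "gt": gt,
            "movement": movement, "rest": rest}


@pytest.fixture(scope="session")
def null_session():
    """Full-size session with all movement effects switched off."""
    montage = fd.make_montage(64, seed=13)
    cfg = fd.SimulationConfig(
        seed=13, broadband_gain=1.0, erd_depth_alpha=0.0, erd_depth_beta=0.0
    )
    rec, _ = fd.simulate_session(cfg, montage)
    movement, rest = fd.preprocess_recording(rec)
    return {"montage": montage, "movement": movement, "rest": rest}


def make_segments(data: np.ndarray, labels, fs: float = 250.0, tag: str = "movement"):
    """Convenience constructor for hand-built SegmentSets."""
    labels = np.asarray(labels)
    return fd.SegmentSet(
        data=np.asarray(data, dtype=float),
        labels=labels,
        fs=fs,
        window_tag=tag,
        source_trial=np.arange(len(labels)),
    )
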