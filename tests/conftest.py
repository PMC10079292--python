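import warnings

import numpy as np
import pandas as pd
import pytest

from fiberphot import photometry, process_session, synth


@pytest.fixture(scope="session")
def default_sessions():
    """20 seeded default synthetic sessions, processed, with ground truth.

    Shared by the artifact-rejection and recovery checks; generation is the
    expensive part, the assertions differ.
    """
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(20):
            session, truth = synth.make_default_session(seed=seed)
            out.append((process_session(session), truth))
    return out


@pytest.fixture
def clean_session():
    """A short noiseless, artifact-free session with well-separated transients.

    Events are placed exactly on 473-frame sample times so kernel rows align
    sample-exactly.
    """
    fs = 15
    events = [(int(30 * fs * k) + 0.5) / fs for k in range(1, 9)]  # 30 s apart
    cfg = synth.PhotometrySimConfig(duration_s=280.0, multiplex_rate_per_channel_hz=fs,
                                    noise_sd=0.0, seed=0)
    session, truth = synth.simulate_photometry_session(cfg, events)
    return cfg, session, truth


def build_session(n_pairs=50, fs=15, s405=None, s473=None, ctrl=None, bg=2.0,
                  n_bg=30):
    """Hand-built interleaved frame stream for unit tests of the raw pipeline."""
    if s405 is not None:
        n_pairs = len(s405)
    elif s473 is not None:
        n_pairs = len(s473)
    s405 = np.arange(n_pairs, dtype=float) if s405 is None else np.asarray(s405, float)
    s473 = 10.0 + np.arange(n_pairs, dtype=float) if s473 is None else np.asarray(s473, float)
    ctrl = np.full(n_pairs, 5.0) if ctrl is None else np.asarray(ctrl, float)
    assert len(s405) == len(s473) == len(ctrl) == n_pairs
    dt = 1.0 / (2 * fs)
    idx = np.arange(n_bg + 2 * n_pairs)
    frames = pd.DataFrame({
        "frame_index": idx,
        "t_s": idx * dt,
        "channel": np.concatenate((np.full(n_bg, "off"), np.tile(["405", "473"], n_pairs))),
        "roi_signal": np.concatenate((np.full(n_bg, bg),
                                      np.column_stack((s405, s473)).ravel())),
        "roi_control": np.concatenate((np.full(n_bg, bg),
                                       np.column_stack((ctrl, ctrl)).ravel())),
    })
    return photometry.RawPhotometrySession(frames, fs)
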