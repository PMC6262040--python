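import numpy as np
import pytest

import hyphatrack as ht


@pytest.fixture(scope="session")
def fast_params():
    """Small, quick simulation: early germination, short horizon."""
    return ht.SimulationParams(seed=11, n_frames=24, germ_delay_mean_h=3.0,
                               germ_delay_sd_h=0.8)


@pytest.fixture(scope="session")
def fast_run(fast_params):
    """One simulated chamber: geometry, ground truth and rendered stack."""
    geometry, truth = ht.simulate_mycelium(fast_params)
    stack = ht.render_frames(geometry, fast_params)
    return geometry, truth, stack


@pytest.fixture(scope="session")
def fast_analysis(fast_run):
    _, _, stack = fast_run
    return ht.analyze_chamber(stack, use_clean_masks=True)


def straight_hypha_geometry(n_frames: int, rate_um_per_frame: float,
                            start=(20.0, 20.0), angle_deg: float = 0.0):
    """Single straight hypha elongating at a fixed per-frame rate."""
    u = np.array([np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))])
    start = np.asarray(start, dtype=float)
    frames = []
    for k in range(n_frames):
        tip = start + u * rate_um_per_frame * (k + 1)
        frames.append([np.vstack([start, tip])])
    return frames


def make_track(times_h, lengths_um, track_id=0):
    """HyphaTrack with the given per-frame geodesic lengths."""
    from hyphatrack.tracking import HyphaTrack, TrackSample

    track = HyphaTrack(track_id=track_id, anchor_pos=(0.0, 0.0))
    for i, (t, ln) in enumerate(zip(times_h, lengths_um)):
        track.samples.append(TrackSample(
            frame_index=i, timestamp_h=float(t), tip_pos=(0, i),
            geodesic_length_um=float(ln)))
    return track
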