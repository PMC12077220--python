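import numpy as np
import pytest

from snowmotility.simulate import SimConfig, simulate_tracks
from snowmotility.tracking import tracks_from_spot_table


@pytest.fixture
def straight_swimmer_track():
    """One noiseless straight swimmer: 10 µm/s for 10 s, 100 µm path."""
    cfg = SimConfig(
        n_motile=1, n_drifting=0, n_stationary=0,
        speed_mean_um_s=10.0, speed_sd_um_s=0.0,
        turn_rate_sd_rad_s=0.0, loop_bias_rad_s=0.0,
        arena_width_um=5000.0, arena_height_um=5000.0, seed=11,
    )
    spots, _ = simulate_tracks(cfg)
    return tracks_from_spot_table(spots)[0]


@pytest.fixture
def random_walk_tracks():
    """A mixed population of noisy tracks for oracle comparisons."""
    cfg = SimConfig(
        n_motile=60, n_drifting=30, n_stationary=30,
        speed_mean_um_s=40.0, speed_sd_um_s=15.0,
        arena_width_um=4000.0, arena_height_um=4000.0, seed=202,
    )
    spots, truth = simulate_tracks(cfg)
    return tracks_from_spot_table(spots), truth


def brute_force_metrics(track):
    """Independent O(n) re-summation of the per-track metrics."""
    xs, ys, ts = track.x_um, track.y_um, track.t_s
    total = 0.0
    for i in range(1, len(xs)):
        total += float(np.hypot(xs[i] - xs[i - 1], ys[i] - ys[i - 1]))
    dmax = 0.0
    for i in range(len(xs)):
        dmax = max(dmax, float(np.hypot(xs[i] - xs[0], ys[i] - ys[0])))
    speed = total / (ts[-1] - ts[0])
    conf = dmax / total if total > 0 else 0.0
    return total, dmax, speed, conf, speed * conf
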