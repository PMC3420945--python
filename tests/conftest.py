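import numpy as np
import pytest

from poletrack.scenes import (
    FixedSchedule,
    NoiseModel,
    SceneConfig,
    generate_movie,
)


@pytest.fixture(scope="session")
def two_reversal_scene():
    """Three cells, fixed reversals at frames 10 and 25, switching lag 1."""
    return SceneConfig(
        n_cells=3,
        n_frames=40,
        reversal_process=FixedSchedule([10, 25]),
        switch_lag_frames=1,
        seed=1,
    )


@pytest.fixture(scope="session")
def two_reversal_movie(two_reversal_scene):
    return generate_movie(two_reversal_scene)


@pytest.fixture(scope="session")
def noiseless_snapshot():
    """Two clean cells without clusters, frame 0 only of a 2-frame movie."""
    cfg = SceneConfig(
        n_cells=2,
        n_frames=2,
        reversal_process=FixedSchedule([1]),
        polar_cluster_amplitudes=(0.0, 0.0),
        noise=NoiseModel(poisson_scale=0.0, gaussian_sd=0.0),
        seed=2,
    )
    stack, truths = generate_movie(cfg)
    return cfg, stack[0].astype(float), truths


@pytest.fixture(scope="session")
def mixed_population():
    """40-cell snapshot with a known unipolar/bipolar/diffuse mix, noisy."""
    cfg = SceneConfig(
        n_cells=40,
        n_frames=2,
        reversal_process=FixedSchedule([1]),
        pattern_mix={
            "unipolar": 0.4,
            "bipolar_symmetric": 0.2,
            "bipolar_asymmetric": 0.3,
            "diffuse": 0.1,
        },
        seed=11,
    )
    stack, truths = generate_movie(cfg)
    return cfg, stack[0].astype(float), truths


def match_truth(mask, truths, frame=0):
    """Nearest ground-truth cell by centroid distance."""
    d = [
        np.hypot(
            t.centroids[frame, 0] - mask.centroid_xy[0],
            t.centroids[frame, 1] - mask.centroid_xy[1],
        )
        for t in truths
    ]
    return truths[int(np.argmin(d))]
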