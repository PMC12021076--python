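import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import axonquant as aq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def straight3_config():
    """Three straight planar axons of 300/600/900 µm from the crush plane."""
    return aq.NerveSimConfig(
        n_axons=3,
        seed=2,
        p_uturn=0.0,
        branch_rate=0.0,
        tortuosity_sd=0.0,
        lengths=(300.0, 600.0, 900.0),
        nerve_length=1000.0,
        nerve_radius=60.0,
        length_scale=300.0,
        shaft_diameter=4.0,
        planar=True,
        min_start_separation=15.0,
        gc_ratio_range=(1.0, 1.0),
    )


@pytest.fixture(scope="session")
def straight3_truth(straight3_config):
    return aq.simulate_nerve(straight3_config)


@pytest.fixture(scope="session")
def noise_free_imaging():
    return aq.ImagingConfig(noise=False, psf_sigma=0.0, pixel_size_xy=1.0)


@pytest.fixture(scope="session")
def straight3_stack(straight3_truth, noise_free_imaging):
    return aq.rasterize_stack(straight3_truth, noise_free_imaging)


@pytest.fixture(scope="session")
def straight3_mask(straight3_stack, noise_free_imaging):
    return aq.binarize(
        straight3_stack, "fixed", threshold=noise_free_imaging.background + 1
    )


@pytest.fixture(scope="session")
def straight3_trace(straight3_mask, straight3_truth):
    return aq.trace_axons(straight3_mask, straight3_truth.geometry)


def brute_force_crossings(trees, geometry, distances):
    """Independent oracle: explicit per-segment plane-crossing count."""
    axis = np.asarray(geometry.axis, dtype=float)
    crush = np.asarray(geometry.crush_position, dtype=float)
    counts = []
    for d in distances:
        n = 0
        for tree in trees:
            proj = (tree.nodes - crush) @ axis
            for child in range(tree.n_nodes):
                par = tree.parent[child]
                if par < 0:
                    continue
                a, b = proj[par], proj[child]
                if min(a, b) < d <= max(a, b):
                    n += 1
        counts.append(n)
    return np.array(counts)
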