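import math

import numpy as np
import pytest

import lidarcanopy as lc


@pytest.fixture(scope="session")
def hemisphere_scene():
    return lc.build_scene(shapes=[{"kind": "hemisphere", "center": [2.0, 0.0], "radius": 1.0}])


@pytest.fixture(scope="session")
def hemisphere_pass(hemisphere_scene):
    """Zero-noise pass over a unit hemisphere (shared across modules)."""
    cfg = lc.PassConfig(seed=1, range_noise_sd=0.0)
    fixes, frames, truth = lc.simulate_pass(hemisphere_scene, cfg, (0.0, 4.0, 0.0))
    return cfg, fixes, frames, truth


@pytest.fixture(scope="session")
def hemisphere_cloud(hemisphere_pass):
    _, fixes, frames, _ = hemisphere_pass
    cloud, stats = lc.reconstruct_cloud(fixes, frames, lc.SensorConfig())
    return cloud, stats


def run_plot_pipeline(scene, pass_cfg, path, seed=1, trait_cfg=None):
    """Full desk-scale pipeline: simulate -> reconstruct -> segment -> traits."""
    fixes, frames, _ = lc.simulate_pass(scene, pass_cfg, path)
    cloud, _ = lc.reconstruct_cloud(fixes, frames, lc.SensorConfig())
    plane, _ = lc.fit_ground_ransac(cloud, seed=seed)
    plant, _ = lc.remove_ground(cloud, plane)
    plant, _ = lc.cluster_denoise(plant, 0.05, 30)
    plant = lc.normalize_to_plane(plant, plane)
    return lc.extract_traits(plant, trait_cfg or lc.TraitConfig(), "plot")


@pytest.fixture(scope="session")
def hemisphere_traits(hemisphere_scene):
    cfg = lc.PassConfig(seed=1)
    return run_plot_pipeline(hemisphere_scene, cfg, (0.0, 4.0, 0.0))
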