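import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from dwel import (SceneSpec, SimulationConfig, build_scene, calibrate_cloud,
                  simulate_scan)
from dwel.pipeline import demo_scan, demo_scene_spec


def make_mono(ranges, shots, band, rho=None, intensity=None):
    """Monospectral cloud on the +y axis with the given ranges/shots."""
    r = np.asarray(ranges, dtype=float)
    n = len(r)
    return pd.DataFrame({
        "x": np.zeros(n), "y": r, "z": np.zeros(n), "range": r,
        "shot_number": np.asarray(shots, dtype=np.int64), "band": band,
        "intensity": np.nan if intensity is None else np.asarray(intensity, float),
        "rho_app": np.nan if rho is None else np.asarray(rho, float),
        "azimuth": np.zeros(n), "zenith": np.full(n, np.pi / 2),
    })


@pytest.fixture(scope="session")
def small_scan_sim():
    """One seeded 4 mrad scan over a small window: raw + calibrated clouds."""
    scan = demo_scan((0.0, 12.0), (55.0, 105.0), angular_resolution=4.0)
    spec = demo_scene_spec((1.0, 11.0), n_trunks=2, n_branches=3,
                           n_leaf_clusters=4)
    config = SimulationConfig(scan=scan, seed=101)
    scene = build_scene(spec, seed=101)
    sim = simulate_scan(scene, config)
    nir = calibrate_cloud(sim.nir, config.calibration)
    swir = calibrate_cloud(sim.swir, config.calibration)
    return sim, nir, swir
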