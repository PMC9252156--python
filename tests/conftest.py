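"""Shared fixtures: small, seeded simulation outputs reused across tests."""

import numpy as np
import pytest

import xpcsre as xr


@pytest.fixture(scope="session")
def ch_params_small() -> xr.CHParams:
    return xr.CHParams(grid_n=64, quench=0.7, mean_u=0.0, seed=12, dt=0.05)


@pytest.fixture(scope="session")
def ch_series_small(ch_params_small) -> xr.FieldSeries:
    """A short 64^2 quench run: 41 frames to t = 80."""
    return xr.evolve(ch_params_small, n_steps=1600, sample_every=40)


@pytest.fixture(scope="session")
def growth_speckle() -> tuple[xr.SpeckleSeries, xr.ParticleEnsembleSpec]:
    """Identical disks, constant growth, dilute: the canonical tail scenario."""
    spec = xr.build_scenario(
        "linear_growth", box_n=256, n_particles=60, duration=80.0, growth_rate=0.15, seed=5
    )
    series = xr.simulate(spec, 80)
    return xr.speckle_series(series), spec


@pytest.fixture(scope="session")
def frozen_speckle() -> xr.SpeckleSeries:
    """Static particles, constant radii: every frame identical."""
    spec = xr.build_scenario("linear_growth", box_n=128, n_particles=30, seed=8, growth_rate=0.0)
    series = xr.simulate(spec, 20)
    return xr.speckle_series(series)


@pytest.fixture(scope="session")
def iid_speckle() -> xr.SpeckleSeries:
    """Frames of i.i.d. uniform noise: the null for every correlation estimator."""
    rng = np.random.default_rng(42)
    frames = [
        xr.SpeckleFrame(intensity=rng.random((128, 128)), time=float(k)) for k in range(40)
    ]
    return xr.SpeckleSeries(frames=frames, qmap=xr.q_map_simulation(128))


def wide_ring(series: xr.SpeckleSeries, q_center: float, halfwidth_pixels: float = 2.0) -> xr.QRing:
    n = series.shape[0]
    return xr.make_q_ring(series, q_center, halfwidth_pixels * 2.0 * np.pi / n)
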