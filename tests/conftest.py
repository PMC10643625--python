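import numpy as np
import pytest

from chd import NPCSimConfig, Particle, simulate_npc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@pytest.fixture
def asym_cloud(rng):
    """Asymmetric 2D cloud (no nontrivial rotational symmetry)."""
    return rng.uniform(-50.0, 50.0, size=(20, 2))


@pytest.fixture(scope="session")
def npc_small():
    """Small simulated NPC set shared by registration-level tests."""
    ps, truth = simulate_npc(
        NPCSimConfig(n_particles=12, radius_dist=("uniform", 40.0, 60.0), seed=31)
    )
    return ps, truth


def make_ring_particle(
    radius=50.0, n_sites=8, locs_per_site=30, sigma=3.0, ellipticity=1.0, seed=0, pid="ring"
):
    rng = np.random.default_rng(seed)
    ang = 2 * np.pi * np.arange(n_sites) / n_sites
    sites = np.stack([radius * np.cos(ang), ellipticity * radius * np.sin(ang)], axis=1)
    pts = np.repeat(sites, locs_per_site, axis=0)
    if sigma > 0:
        pts = pts + rng.normal(0.0, sigma, size=pts.shape)
    return Particle(pts, id=pid)
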