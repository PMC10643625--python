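"""Synthetic heterogeneous SMLM particle datasets with ground truth.

Two structure families are emulated: 8-fold symmetric NPC-like rings (Nup96
labeling geometry: 8 corners with 4 binding sites each) with continuous
variation in radius and/or ellipticity, and DNA-origami tetrahedra (3 base
sites plus a tip) with continuous height variation.  The localization model
is shared: each binding site is active with probability DOL (degree of
labeling, a Bernoulli draw per site), each active site emits a
Poisson-distributed number of repeated localizations (conditioned >= 1),
and every localization is scattered around its site with (an)isotropic
Gaussian localization noise.  Particles receive a random rotation and a
small random translation emulating imperfect picking.

All randomness flows from the single ``seed`` in the config: identical
configs give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import Particle, ParticleSet

logger = logging.getLogger("chd")

__all__ = ["NPCSimConfig", "TetraSimConfig", "simulate_npc", "simulate_tetrahedron"]

# a distribution spec is ("fixed", value) or ("uniform", lo, hi)
Dist = tuple


def _draw(dist: Dist, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    raise ValueError(f"unknown distribution {dist!r}")


@dataclass
class NPCSimConfig:
    """Configuration of the NPC-like ring simulation.

    Defaults follow the simulation studies this generator emulates: 250
    particles per dataset, 8 corners x 4 binding sites collapsed onto the
    corner positions, ~10 localizations per active site, 5 nm localization
    precision, and +/- 10 nm picking jitter.
    """

    n_particles: int = 250
    radius_dist: Dist = ("fixed", 50.0)  # nm
    ellipticity_dist: Dist = ("fixed", 1.0)  # minor/major ratio in (0, 1]
    n_corners: int = 8
    sites_per_corner: int = 4
    dol: float = 1.0
    locs_per_site_mean: float = 10.0
    loc_sigma: float = 5.0  # nm, isotropic
    translation_jitter: float = 10.0  # nm, uniform per axis
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dol <= 1:
            raise ValueError("dol must be in (0, 1]")
        if self.loc_sigma < 0 or self.locs_per_site_mean <= 0:
            raise ValueError("invalid localization model parameters")


@dataclass
class TetraSimConfig:
    """Configuration of the DNA-origami tetrahedron simulation.

    Defaults: 218 particles, 100 nm edge, height uniform over 67.5-112.5 nm
    (centered on 90 nm with a 45 nm span), anisotropic localization noise of
    5 nm laterally and 15 nm axially.
    """

    n_particles: int = 218
    edge: float = 100.0  # nm, base triangle side
    height_dist: Dist = ("uniform", 67.5, 112.5)  # nm
    dol: float = 1.0
    sites_per_corner: int = 4
    locs_per_site_mean: float = 10.0
    loc_sigma_xy: float = 5.0
    loc_sigma_z: float = 15.0
    translation_jitter: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dol <= 1:
            raise ValueError("dol must be in (0, 1]")


def _poisson_ge1(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) draws conditioned on >= 1 (resample zeros)."""
    k = rng.poisson(lam, size=size)
    while np.any(k == 0):
        zero = k == 0
        k[zero] = rng.poisson(lam, size=int(zero.sum()))
    return k


def _scatter_sites(
    sites: np.ndarray,
    rng: np.random.Generator,
    dol: float,
    lam: float,
    sigma: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Activate sites, draw localization counts, and add Gaussian noise.

    Returns (localizations, active mask, attempts); redraws activation up to
    100 times if no site is active.
    """
    for attempt in range(100):
        active = rng.random(sites.shape[0]) < dol
        if active.any():
            break
        logger.info("particle with zero active sites redrawn (attempt %d)", attempt + 1)
    else:
        raise RuntimeError("no active sites after 100 attempts")
    counts = _poisson_ge1(rng, lam, int(active.sum()))
    centers = np.repeat(sites[active], counts, axis=0)
    noise = rng.normal(size=centers.shape) * sigma
    return centers + noise, active, attempt + 1


def _rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def simulate_npc(cfg: NPCSimConfig) -> tuple[ParticleSet, pd.DataFrame]:
    """Simulate heterogeneous NPC-like ring particles.

    Per particle: draw radius ``r`` and ellipticity ``e`` from their
    configured distributions; place ``n_corners * sites_per_corner`` binding
    sites at ``(r cos(theta), e r sin(theta))`` for the 8 symmetric corner
    angles (sites within a corner collapse onto the corner position);
    activate each site independently with probability ``dol``; draw
    localization counts Poisson(``locs_per_site_mean``) conditioned >= 1;
    scatter localizations with isotropic Gaussian noise; apply a random
    in-plane rotation and uniform translation jitter.

    Returns the particle set and a ground-truth table (id, radius,
    ellipticity, n_active_sites).
    """
    rng = np.random.default_rng(cfg.seed)
    particles, rows = [], []
    angles = 2.0 * np.pi * np.arange(cfg.n_corners) / cfg.n_corners
    for idx in range(cfg.n_particles):
        r = _draw(cfg.radius_dist, rng)
        e = _draw(cfg.ellipticity_dist, rng)
        corners = np.stack([r * np.cos(angles), e * r * np.sin(angles)], axis=1)
        sites = np.repeat(corners, cfg.sites_per_corner, axis=0)
        # pose first, then localization noise: noise lives in the lab frame
        theta = rng.uniform(0.0, 2.0 * np.pi)
        shift = rng.uniform(-cfg.translation_jitter, cfg.translation_jitter, size=2)
        posed = sites @ _rot2(theta).T + shift
        coords, active, _ = _scatter_sites(
            posed, rng, cfg.dol, cfg.locs_per_site_mean, np.full(2, cfg.loc_sigma)
        )
        pid = f"npc_{idx:04d}"
        if coords.shape[0] < 3:  # extremely sparse draw; pad is not meaningful
            logger.warning("particle %s has <3 localizations; redrawing", pid)
            continue
        particles.append(Particle(coords, id=pid))
        rows.append(
            {
                "id": pid,
                "radius": r,
                "ellipticity": e,
                "n_active_sites": int(active.sum()),
            }
        )
    truth = pd.DataFrame(rows)
    meta = {"simulator": "npc", "config": cfg, "seed": cfg.seed}
    return ParticleSet(particles, metadata=meta), truth


def simulate_tetrahedron(cfg: TetraSimConfig) -> tuple[ParticleSet, pd.DataFrame]:
    """Simulate DNA-origami tetrahedron particles with height variation.

    Per particle: an equilateral base triangle of side ``edge`` in the z = 0
    plane (centered on its centroid) and a tip at height ``h`` above the
    base centroid, ``h`` drawn from ``height_dist``; the same
    DOL/localization-count model as the ring simulation with anisotropic
    noise (``loc_sigma_xy`` lateral, ``loc_sigma_z`` axial); a uniformly
    random 3D rotation and translation jitter.
    """
    rng = np.random.default_rng(cfg.seed)
    circum = cfg.edge / np.sqrt(3.0)  # base-vertex distance from base centroid
    base_angles = 2.0 * np.pi * np.arange(3) / 3.0
    base = np.stack(
        [circum * np.cos(base_angles), circum * np.sin(base_angles), np.zeros(3)], axis=1
    )
    sigma = np.array([cfg.loc_sigma_xy, cfg.loc_sigma_xy, cfg.loc_sigma_z])
    particles, rows = [], []
    for idx in range(cfg.n_particles):
        h = _draw(cfg.height_dist, rng)
        corners = np.vstack([base, [0.0, 0.0, h]])
        sites = np.repeat(corners, cfg.sites_per_corner, axis=0)
        R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        shift = rng.uniform(-cfg.translation_jitter, cfg.translation_jitter, size=3)
        posed = sites @ R.T + shift
        # anisotropic localization noise in the lab frame (axial sigma_z)
        coords, active, _ = _scatter_sites(posed, rng, cfg.dol, cfg.locs_per_site_mean, sigma)
        pid = f"tetra_{idx:04d}"
        if coords.shape[0] < 3:
            logger.warning("particle %s has <3 localizations; redrawing", pid)
            continue
        particles.append(Particle(coords, id=pid))
        rows.append({"id": pid, "height": h, "n_active_sites": int(active.sum())})
    truth = pd.DataFrame(rows)
    meta = {"simulator": "tetrahedron", "config": cfg, "seed": cfg.seed}
    return ParticleSet(particles, metadata=meta), truth
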