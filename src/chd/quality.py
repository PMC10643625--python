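"""Model-based shape estimators, spectral SNR curves, and outlier flagging.

These are the validation axes of the heterogeneity pipeline: independent,
model-based estimates of ring radius, tetrahedron height and ring
ellipticity that the latent coordinate can be compared against, plus a
Fourier-ring-correlation-based spectral signal-to-noise measure of per-bin
reconstruction quality and a latent-space outlier rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .core import Particle, render_reconstruction
from .embedding import LatentSpace
from .fusion import jrmpc_fuse
from .registration import register_pair

logger = logging.getLogger("chd")

__all__ = [
    "SSNRCurve",
    "HeightEstimate",
    "estimate_radius",
    "estimate_height",
    "estimate_ellipticity",
    "ssnr_curve",
    "detect_outliers",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM of a Gaussian = factor * sd


@dataclass
class SSNRCurve:
    """Ring-averaged spectral signal-to-noise ratio versus spatial frequency."""

    spatial_frequency: np.ndarray  # ring centers, nm^-1, strictly increasing, > 0
    ssnr: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.spatial_frequency = np.asarray(self.spatial_frequency, dtype=float)
        self.ssnr = np.asarray(self.ssnr, dtype=float)
        if self.spatial_frequency[0] <= 0 or np.any(np.diff(self.spatial_frequency) <= 0):
            raise ValueError("frequencies must be strictly increasing and positive")
        if not np.all(np.isfinite(self.ssnr)):
            raise ValueError("non-finite SSNR values (cap them)")


@dataclass
class HeightEstimate:
    height: float
    flagged: bool  # True when the z-histogram is effectively unimodal
    means: tuple[float, float] = (np.nan, np.nan)


def estimate_radius(p: Particle) -> tuple[float, float]:
    """Mean-radial-coordinate estimate of a 2D ring radius, with its SEM.

    The particle is centered by subtracting its mean localization, converted
    to polar coordinates, and the radius is estimated as the mean radial
    coordinate.  The standard error is the FWHM of the radial distribution
    (computed analytically as ``2 sqrt(2 ln 2)`` times the radial sd, which
    avoids histogram bin-width sensitivity) divided by ``sqrt(n)``.
    """
    if p.dim != 2:
        raise ValueError("radius estimation expects a 2D particle")
    xy = p.coords - p.coords.mean(axis=0)
    r = np.hypot(xy[:, 0], xy[:, 1])
    fwhm = FWHM_FACTOR * r.std(ddof=0)
    return float(r.mean()), float(fwhm / math.sqrt(r.size))


def _bimodal_axis(coords: np.ndarray, rng_seed: int = 0) -> np.ndarray:
    """Unit axis along which the point distribution is most bimodal.

    Tries the principal axes of the covariance; on each projection fits a
    two-component Gaussian mixture and scores the separation
    ``|mu2 - mu1| / pooled sd``.  The winning axis is oriented so that the
    smaller-weight mode (e.g. a tetrahedron tip versus its base plate) lies
    on the positive side.
    """
    Xc = coords - coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    best_axis, best_sep = Vt[0], -np.inf
    for axis in Vt:
        z = Xc @ axis
        gm = GaussianMixture(n_components=2, random_state=rng_seed, n_init=3).fit(
            z.reshape(-1, 1)
        )
        mu = gm.means_.ravel()
        sd = math.sqrt(float(gm.covariances_.ravel().mean()))
        sep = abs(mu[1] - mu[0]) / max(sd, 1e-12)
        if sep > best_sep:
            small = mu[np.argmin(gm.weights_)]
            sign = 1.0 if small >= mu.mean() else -1.0
            best_axis, best_sep = sign * axis, sep
    return best_axis


def estimate_height(
    particles: list[Particle] | Particle,
    axis_align: str | np.ndarray = "auto",
    rng_seed: int = 0,
) -> HeightEstimate:
    """Estimate a 3D structure height from the bimodal z-projection.

    Localizations of all particles (assumed already in a common frame, e.g.
    a fused bin) are projected onto the symmetry axis; a two-component
    Gaussian mixture is fitted to the projected histogram and the height is
    the distance between the two fitted means — for a tetrahedron, the base
    plate and the tip.

    ``axis_align="auto"`` finds the axis automatically as the direction of
    strongest bimodality among the principal axes; alternatively pass a
    rotation matrix whose third row is the symmetry axis, or a unit
    3-vector.

    A fit whose mode separation is below twice the pooled component sd is
    flagged as effectively unimodal.
    """
    if isinstance(particles, Particle):
        particles = [particles]
    coords = np.vstack([p.coords for p in particles])
    if coords.shape[1] != 3:
        raise ValueError("height estimation expects 3D particles")
    if isinstance(axis_align, str):
        if axis_align != "auto":
            raise ValueError("axis_align must be 'auto', a rotation or an axis vector")
        axis = _bimodal_axis(coords, rng_seed)
    else:
        arr = np.asarray(axis_align, dtype=float)
        axis = arr[2] if arr.ndim == 2 else arr
        axis = axis / np.linalg.norm(axis)
    z = (coords - coords.mean(axis=0)) @ axis
    if np.ptp(z) <= 0:
        return HeightEstimate(0.0, flagged=True)
    gm = GaussianMixture(n_components=2, random_state=rng_seed, n_init=5).fit(
        z.reshape(-1, 1)
    )
    mu = np.sort(gm.means_.ravel())
    sd = math.sqrt(float(gm.covariances_.ravel().mean()))
    height = float(mu[1] - mu[0])
    # a two-Gaussian mixture is only bimodal when the means are separated by
    # more than ~2 component sds; below that the z-profile is effectively
    # unimodal and the fitted split is arbitrary
    flagged = height < 2.0 * sd
    if flagged:
        logger.warning("z-projection looks unimodal (separation %.3g < sd %.3g)", height, sd)
    return HeightEstimate(height, flagged, (float(mu[0]), float(mu[1])))


def estimate_ellipticity(p: Particle, n_blobs: int = 8, rng_seed: int = 0) -> float:
    """Minor/major axis ratio of the ellipse through the binding-site blobs.

    k-means with ``k = n_blobs`` (best of 10 restarts by within-cluster sum
    of squares) locates the blob centers; a least-squares ellipse fit to the
    centers gives the axis ratio in (0, 1].
    """
    if p.dim != 2:
        raise ValueError("ellipticity estimation expects a 2D particle")
    if p.n_localizations < n_blobs:
        raise ValueError("not enough localizations for the requested blob count")
    for attempt in range(2):
        km = KMeans(n_clusters=n_blobs, n_init=10, random_state=rng_seed + attempt).fit(
            p.coords
        )
        counts = np.bincount(km.labels_, minlength=n_blobs)
        if counts.min() > 0:
            break
    else:
        raise RuntimeError("k-means produced a degenerate (empty) cluster")
    model = EllipseModel.from_estimate(km.cluster_centers_)
    if not model:
        raise RuntimeError("ellipse fit failed")
    a, b = model.axis_lengths
    lo, hi = sorted((abs(a), abs(b)))
    if hi <= 0:
        raise RuntimeError("degenerate ellipse fit")
    return float(lo / hi)


def _frc(img1: np.ndarray, img2: np.ndarray, pixel_size: float):
    """Fourier ring correlation between two equally shaped 2D images."""
    F1 = np.fft.fftshift(np.fft.fft2(img1))
    F2 = np.fft.fftshift(np.fft.fft2(img2))
    ny, nx = img1.shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=pixel_size))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=pixel_size))
    q = np.hypot(fy[:, None], fx[None, :])
    df = 1.0 / (min(nx, ny) * pixel_size)
    q_max = min(abs(fx).max(), abs(fy).max())
    n_rings = int(q_max / df)
    ring = np.floor(q / df).astype(int)
    valid = (ring >= 1) & (ring <= n_rings)
    num = np.bincount(ring[valid], weights=(F1 * np.conj(F2)).real[valid], minlength=n_rings + 1)
    d1 = np.bincount(ring[valid], weights=(np.abs(F1) ** 2)[valid], minlength=n_rings + 1)
    d2 = np.bincount(ring[valid], weights=(np.abs(F2) ** 2)[valid], minlength=n_rings + 1)
    denom = np.sqrt(d1[1:] * d2[1:])
    frc = np.where(denom > 0, num[1:] / np.where(denom > 0, denom, 1.0), 0.0)
    freqs = (np.arange(1, n_rings + 1) + 0.5) * df
    return freqs, frc


def ssnr_curve(
    bin_particles: list[Particle],
    pixel_size: float,
    rng_seed: int = 0,
    symmetry: int = 8,
    blur_sigma: float = 0.0,
    cap: float = 1e6,
    fuse_kwargs: dict | None = None,
) -> SSNRCurve:
    """Spectral signal-to-noise curve of a particle bin from two half-sets.

    The bin is split into two random halves, each fused independently; the
    second half-reconstruction is rigidly aligned onto the first.  To avoid
    spurious correlation from labeling hotspots on a rotationally symmetric
    structure, every particle's fused localizations are then rotated by a
    random integer multiple of ``2 pi / symmetry`` about the reconstruction
    center (``symmetry = 1`` disables this).  Both halves are rendered on a
    common grid, the Fourier ring correlation FRC(q) is computed, and

        SSNR(q) = 2 FRC(q) / (1 - FRC(q)),

    the two-half-dataset convention, capped at ``cap``.
    """
    if len(bin_particles) < 2:
        raise ValueError("SSNR needs at least 2 particles")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(bin_particles))
    halves = [order[::2], order[1::2]]
    fuse_kwargs = fuse_kwargs or {}
    recs = [
        jrmpc_fuse([bin_particles[int(i)] for i in h], rng_seed=rng_seed + hi, **fuse_kwargs)
        for hi, h in enumerate(halves)
    ]
    # align half 2 onto half 1
    c0, c1 = recs[0].fused_coords, recs[1].fused_coords
    d0 = np.linalg.norm(c0 - c0.mean(0), axis=1)
    align_scale = max(float(np.median(d0)) / 5.0, 1.0)
    pr = register_pair(c0, c1, align_scale)
    c1 = pr.transform.apply(c1)

    clouds = []
    for rec, coords in ((recs[0], c0), (recs[1], c1)):
        center = coords.mean(axis=0)
        parts = np.split(coords, np.cumsum(rec.particle_sizes)[:-1])
        rotated = []
        for part in parts:
            mult = int(rng.integers(symmetry)) if symmetry > 1 else 0
            th = 2.0 * np.pi * mult / symmetry if symmetry > 1 else 0.0
            c, s = math.cos(th), math.sin(th)
            R = np.array([[c, -s], [s, c]])
            rotated.append((part - center) @ R.T + center)
        clouds.append(np.vstack(rotated))

    both = np.vstack(clouds)
    lo, hi = both.min(axis=0) - 2 * pixel_size, both.max(axis=0) + 2 * pixel_size
    imgs = [
        render_reconstruction(c, pixel_size, blur_sigma, extent=(lo, hi)) for c in clouds
    ]
    freqs, frc = _frc(imgs[0], imgs[1], pixel_size)
    frc = np.clip(frc, -0.999999, 1.0 - 1e-12)
    ssnr = np.clip(2.0 * frc / (1.0 - frc), -cap, cap)
    return SSNRCurve(freqs, ssnr, n_bins=freqs.size)


def detect_outliers(ls: LatentSpace, fraction: float = 0.01) -> np.ndarray:
    """Flag particles in the extreme tails of the latent-space distribution.

    The total ``fraction`` is split evenly over both tails: particles whose
    latent coordinate falls strictly below the ``fraction/2`` quantile or
    strictly above the ``1 - fraction/2`` quantile are flagged.  Returned
    indices are sorted by extremity (distance beyond the nearer threshold,
    most extreme first).  The rule is invariant under affine rescaling of
    the latent coordinate.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    x = np.asarray(ls.coordinate, dtype=float)
    if fraction == 0:
        return np.array([], dtype=int)
    lo = np.quantile(x, fraction / 2.0)
    hi = np.quantile(x, 1.0 - fraction / 2.0)
    extremity = np.maximum(lo - x, x - hi)
    idx = np.flatnonzero(extremity > 0)
    return idx[np.argsort(extremity[idx])[::-1]]
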