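"""Core domain types and localization-table I/O for SMLM particle analysis.

A *particle* is one cropped point cloud of single-molecule localizations
(coordinates in nm) corresponding to a single copy of a macromolecular
structure.  Particles are exchanged on disk as delimited text tables with a
header row, columns ``x, y[, z]`` in nm, and optionally ``id``,
``uncertainty_xy``, ``uncertainty_z`` and ``frame`` columns.  This matches
common SMLM export conventions (ThunderSTORM/Picasso-style CSVs) while
staying tool-agnostic.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger("chd")

__all__ = [
    "Particle",
    "ParticleSet",
    "RigidTransform",
    "Reconstruction",
    "read_particles",
    "write_particles",
    "render_reconstruction",
]


class FormatError(ValueError):
    """Raised when a localization table does not have the expected layout."""


class DimensionalityError(ValueError):
    """Raised when 2D and 3D data are mixed."""


@dataclass
class Particle:
    """One localization point cloud (a single structure instance).

    Parameters
    ----------
    coords
        ``(n, dim)`` array of localization coordinates in nm, ``dim`` in {2, 3}.
    precision
        Optional ``(n,)`` or ``(n, dim)`` per-localization uncertainty in nm.
    id
        Opaque particle label.
    """

    coords: np.ndarray
    precision: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise DimensionalityError(
                f"particle {self.id!r}: coords must be (n, 2) or (n, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise ValueError(
                f"particle {self.id!r}: at least 3 localizations are required "
                "for rigid registration"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"particle {self.id!r}: non-finite coordinates")
        if self.precision is not None:
            self.precision = np.asarray(self.precision, dtype=float)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def n_localizations(self) -> int:
        return self.coords.shape[0]

    def centered(self) -> "Particle":
        """Copy with the mean localization subtracted."""
        return Particle(
            self.coords - self.coords.mean(axis=0),
            precision=self.precision,
            id=self.id,
        )


@dataclass
class ParticleSet:
    """Ordered collection of particles sharing one dimensionality."""

    particles: list[Particle]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.particles:
            dims = {p.dim for p in self.particles}
            if len(dims) > 1:
                raise DimensionalityError(f"mixed dimensionalities: {sorted(dims)}")
            ids = [p.id for p in self.particles]
            if len(set(ids)) != len(ids):
                raise ValueError("particle ids are not unique")

    @property
    def dim(self) -> int:
        return self.particles[0].dim

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.particles]

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self) -> Iterator[Particle]:
        return iter(self.particles)

    def __getitem__(self, i: int) -> Particle:
        return self.particles[i]

    def subset(self, indices: Sequence[int]) -> "ParticleSet":
        return ParticleSet([self.particles[i] for i in indices], dict(self.metadata))


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in nm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        d = self.translation.shape[0]
        if self.rotation.shape != (d, d):
            raise ValueError("rotation/translation shape mismatch")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(d), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("improper rotation (reflection)")

    @classmethod
    def identity(cls, dim: int) -> "RigidTransform":
        return cls(np.eye(dim), np.zeros(dim))

    @property
    def dim(self) -> int:
        return self.translation.shape[0]

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class Reconstruction:
    """Fused localizations of a group of particles in a common frame."""

    fused_coords: np.ndarray
    transforms: list[RigidTransform]
    bin_label: int | None = None
    particle_sizes: list[int] | None = None
    log_likelihood: np.ndarray | None = None  # EM objective trace, if fused by EM

    @property
    def n_localizations(self) -> int:
        return self.fused_coords.shape[0]


# ---------------------------------------------------------------------------
# Table I/O


@dataclass
class TableDialect:
    """Column naming of a localization table."""

    x: str = "x"
    y: str = "y"
    z: str = "z"
    id: str = "id"
    delimiter: str | None = None  # None: infer from extension (.tsv -> tab)


def _resolve_delimiter(path: str | os.PathLike, dialect: TableDialect) -> str:
    if dialect.delimiter is not None:
        return dialect.delimiter
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_particles(
    path: str | os.PathLike, dialect: TableDialect | None = None
) -> ParticleSet:
    """Read a localization table into a :class:`ParticleSet`.

    The table must have ``x`` and ``y`` columns (nm); a ``z`` column makes the
    set 3D.  Rows are grouped by the ``id`` column; without one, the whole
    file is a single particle named after the file.  Particles with fewer
    than 3 localizations are dropped with a warning.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=_resolve_delimiter(path, dialect))
    for col in (dialect.x, dialect.y):
        if col not in df.columns:
            raise FormatError(f"missing coordinate column {col!r} in {path}")
    cols = [dialect.x, dialect.y]
    if dialect.z in df.columns:
        cols.append(dialect.z)

    if dialect.id in df.columns:
        groups = [(str(k), g) for k, g in df.groupby(dialect.id, sort=False)]
    else:
        stem = os.path.splitext(os.path.basename(str(path)))[0]
        groups = [(stem, df)]

    particles = []
    for pid, g in groups:
        coords = g[cols].to_numpy(dtype=float)
        if coords.shape[0] < 3:
            logger.warning(
                "dropping particle %r: only %d localizations", pid, coords.shape[0]
            )
            continue
        prec = None
        if "uncertainty_xy" in g.columns:
            prec = g["uncertainty_xy"].to_numpy(dtype=float)
        particles.append(Particle(coords, precision=prec, id=pid))
    if not particles:
        raise FormatError(f"no usable particles in {path}")
    return ParticleSet(particles, metadata={"source": str(path)})


def write_particles(
    ps: ParticleSet, path: str | os.PathLike, dialect: TableDialect | None = None
) -> None:
    """Write a :class:`ParticleSet` as a delimited table (one row per localization)."""
    if len(ps) == 0:
        raise ValueError("cannot write an empty ParticleSet")
    dialect = dialect or TableDialect()
    cols = [dialect.x, dialect.y] + ([dialect.z] if ps.dim == 3 else [])
    frames = []
    for p in ps:
        g = pd.DataFrame(p.coords, columns=cols)
        g[dialect.id] = p.id
        if p.precision is not None and p.precision.ndim == 1:
            g["uncertainty_xy"] = p.precision
        frames.append(g)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=_resolve_delimiter(path, dialect), index=False, float_format="%.6f"
    )


# ---------------------------------------------------------------------------
# Rendering


def render_reconstruction(
    recon: Reconstruction | np.ndarray,
    pixel_size: float,
    blur_sigma: float,
    extent: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Render localizations as a density image (2D) or z-stack (3D).

    Each localization contributes a unit-integral Gaussian blob of width
    ``blur_sigma`` (nm); ``blur_sigma = 0`` gives a plain 2D/3D histogram.
    The image integral equals the number of localizations up to boundary
    clipping.

    Parameters
    ----------
    recon
        A :class:`Reconstruction` or a raw ``(n, dim)`` coordinate array.
    pixel_size
        Pixel (voxel) edge length in nm; must be positive.
    blur_sigma
        Gaussian blur width in nm.
    extent
        Optional ``(lo, hi)`` corner vectors in nm fixing the rendered volume;
        by default the data bounds padded by ``3 * blur_sigma``.

    Returns
    -------
    ndarray with axes (y, x) in 2D or (z, y, x) in 3D; pixel (0, 0) covers
    the low corner of the extent.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    coords = recon.fused_coords if isinstance(recon, Reconstruction) else np.asarray(recon)
    dim = coords.shape[1]
    if extent is None:
        pad = 3.0 * blur_sigma + pixel_size
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
    else:
        lo, hi = (np.asarray(e, dtype=float) for e in extent)
    n_bins = np.maximum(np.ceil((hi - lo) / pixel_size).astype(int), 1)
    edges = [lo[a] + pixel_size * np.arange(n_bins[a] + 1) for a in range(dim)]
    hist, _ = np.histogramdd(coords, bins=edges)
    # histogramdd axis order is (x, y[, z]); flip to (z, y, x) image convention
    img = hist.T
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma / pixel_size, mode="constant")
    return img
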