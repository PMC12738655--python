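"""Two-sphere cell model: source sampling and ray-sphere path geometry.

The cell is two homogeneous concentric water spheres (cell radius 10 μm,
nucleus radius 5 μm, density 1 g/cm³) centred in a 30 μm water cube.
Radionuclide sources are placed uniformly in one of four sub-volumes: a
0.01 μm shell on the outer cell wall, the cytoplasm volume, a 0.01 μm
shell on the nucleus wall, or the nucleus volume.  All positions are
Cartesian μm with the cell centre at the origin.

The nucleus-wall shell sits immediately *outside* the nucleus boundary
([r_nucleus, r_nucleus + 0.01] μm): a carrier docked at the nuclear
envelope has not internalised.  Pass ``wall_inside=True`` to
:func:`sample_source_position` for the alternative reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "CellModel",
    "SourceLocation",
    "Region",
    "PathSegment",
    "sample_source_position",
    "isotropic_direction",
    "sphere_segments",
    "nucleus_solid_angle_fraction",
]

MEV_TO_JOULE = 1.602176634e-13


class SourceLocation(str, Enum):
    CELL_MEMBRANE = "cell_membrane"
    CYTOPLASM = "cytoplasm"
    NUCLEUS_WALL = "nucleus_wall"
    NUCLEUS_VOLUME = "nucleus_volume"


class Region(str, Enum):
    NUCLEUS = "nucleus"
    CYTOPLASM = "cytoplasm"
    OUTSIDE_CELL = "outside_cell"


@dataclass(frozen=True)
class CellModel:
    """Geometry and material constants of the spherical cell phantom."""

    r_cell: float = 10.0          # μm
    r_nucleus: float = 5.0        # μm
    shell_thickness: float = 0.01  # μm
    box_half_side: float = 15.0   # μm
    density: float = 1.0          # g/cm³

    def __post_init__(self) -> None:
        if not (0.0 < self.r_nucleus < self.r_cell < self.box_half_side):
            raise ValueError("require 0 < r_nucleus < r_cell < box_half_side")
        if self.shell_thickness <= 0.0:
            raise ValueError("shell_thickness must be positive")

    @property
    def nucleus_mass_kg(self) -> float:
        """Mass of the nucleus sphere in kg (volume in μm³ → cm³ → g → kg)."""
        volume_um3 = 4.0 / 3.0 * math.pi * self.r_nucleus**3
        return volume_um3 * 1e-12 * self.density * 1e-3

    def region_at(self, point: np.ndarray) -> Region:
        r = float(np.linalg.norm(point))
        if r < self.r_nucleus:
            return Region.NUCLEUS
        if r < self.r_cell:
            return Region.CYTOPLASM
        return Region.OUTSIDE_CELL


@dataclass(frozen=True)
class PathSegment:
    region: Region
    entry_distance: float   # μm along the ray
    exit_distance: float

    @property
    def length(self) -> float:
        return self.exit_distance - self.entry_distance


def _uniform_in_shell(
    r_inner: float, r_outer: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform-in-volume points with radius in [r_inner, r_outer]."""
    u = rng.random(n)
    r = np.cbrt(r_inner**3 + u * (r_outer**3 - r_inner**3))
    return r[:, None] * isotropic_direction(rng, n)


def sample_source_position(
    location: SourceLocation,
    cell: CellModel,
    rng: np.random.Generator,
    n: int = 1,
    wall_inside: bool = False,
) -> np.ndarray:
    """Uniform source positions in the named sub-volume, shape (n, 3) μm."""
    location = SourceLocation(location)
    t = cell.shell_thickness
    if location is SourceLocation.CELL_MEMBRANE:
        pts = _uniform_in_shell(cell.r_cell, cell.r_cell + t, n, rng)
    elif location is SourceLocation.CYTOPLASM:
        pts = _uniform_in_shell(cell.r_nucleus, cell.r_cell, n, rng)
    elif location is SourceLocation.NUCLEUS_WALL:
        if wall_inside:
            pts = _uniform_in_shell(cell.r_nucleus - t, cell.r_nucleus, n, rng)
        else:
            pts = _uniform_in_shell(cell.r_nucleus, cell.r_nucleus + t, n, rng)
    else:
        pts = _uniform_in_shell(0.0, cell.r_nucleus, n, rng)
    return pts


def isotropic_direction(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Unit vectors uniform on the sphere (normalised Gaussian triples)."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sphere_crossings(
    origin: np.ndarray, direction: np.ndarray, radius: float
) -> tuple[float, float] | None:
    """Forward interval [t0, t1] (t1 > 0) where the ray is inside the sphere."""
    b = float(np.dot(origin, direction))
    c = float(np.dot(origin, origin)) - radius * radius
    disc = b * b - c
    if disc <= 0.0:
        return None
    s = math.sqrt(disc)
    t0, t1 = -b - s, -b + s
    if t1 <= 0.0:
        return None
    return max(t0, 0.0), t1


def _box_exit(origin: np.ndarray, direction: np.ndarray, half_side: float) -> float:
    """Distance to the first exit from the cube [-h, h]³ (slab method)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-half_side - origin) / direction
        t2 = (half_side - origin) / direction
    t_far = np.where(np.isnan(np.maximum(t1, t2)), np.inf, np.maximum(t1, t2))
    return float(np.min(t_far))


def sphere_segments(
    origin: np.ndarray, direction: np.ndarray, cell: CellModel
) -> list[PathSegment]:
    """Ordered forward path segments by region, truncated at the box wall."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(float(np.linalg.norm(direction)) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    t_end = _box_exit(origin, direction, cell.box_half_side)
    if not math.isfinite(t_end) or t_end <= 0.0:
        return []

    cuts = {0.0, t_end}
    for radius in (cell.r_nucleus, cell.r_cell):
        hit = _sphere_crossings(origin, direction, radius)
        if hit is not None:
            for t in hit:
                if 0.0 < t < t_end:
                    cuts.add(t)
    ts = sorted(cuts)
    segments: list[PathSegment] = []
    for a, b in zip(ts[:-1], ts[1:]):
        if b - a <= 1e-12:
            continue
        mid = origin + direction * (0.5 * (a + b))
        segments.append(PathSegment(cell.region_at(mid), a, b))
    return segments


def nucleus_solid_angle_fraction(origin: np.ndarray, cell: CellModel) -> float:
    """Fraction of isotropic directions from ``origin`` that hit the nucleus.

    Closed form for a sphere of radius r seen from distance d > r:
    ``(1 - sqrt(1 - (r/d)²)) / 2``.  Returns 1.0 inside the nucleus.
    """
    d = float(np.linalg.norm(np.asarray(origin, dtype=float)))
    r = cell.r_nucleus
    if d <= r:
        return 1.0
    return 0.5 * (1.0 - math.sqrt(1.0 - (r / d) ** 2))
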