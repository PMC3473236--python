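"""Grid-based detection of cavities and surface pockets.

The structure is embedded in a cubic grid (default 1.0 A spacing, 4.0 A
padding).  Each grid point is classified:

* *occupied* — inside some atom's solvent-expanded sphere (vdW + probe);
* *bulk solvent* — empty and connected to the grid boundary through empty
  points (6-connectivity, conservative solvent);
* *candidate* — any remaining empty point (an enclosed void), or an empty
  bulk-connected point that is buried by protein along at least 5 of 7
  scan axes (x, y, z and the four body diagonals; an axis counts when
  occupied points occur on both sides).  This buriedness criterion is the
  classic grid pocket test (LIGSITE-style protein-solvent-protein events).

Accepted points are clustered with 26-connectivity (permissive grouping),
clusters of fewer than 3 points are discarded, and cavities are ranked by
volume (point count x spacing^3), ties broken in favour of the cluster
whose centroid is closer to the protein centroid.  A residue belongs to a
cavity if any of its atoms lies within a contact cutoff of any cavity
point; cavity depth is the distance to the nearest bulk-solvent point,
averaged over the cavity's points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from decoybench.sasa import SasaParams
from decoybench.structure_io import ChainStructure, ResidueId

__all__ = [
    "GridSpec",
    "Cavity",
    "GridClassification",
    "classify_grid",
    "detect_cavities",
    "cavity_residues",
    "average_depth",
]

_SCAN_AXES = np.array(
    [
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 1),
        (1, 1, -1),
        (1, -1, 1),
        (-1, 1, 1),
    ],
    dtype=int,
)


@dataclass
class GridSpec:
    spacing: float = 1.0
    padding: float = 4.0
    min_cluster_points: int = 3
    buried_axes_min: int = 5

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.padding < 2.8:  # at least one probe diameter of solvent
            raise ValueError("padding must be at least the probe diameter")


@dataclass
class Cavity:
    points: np.ndarray  # (n, 3) cavity grid points, A
    volume: float  # n * spacing^3, A^3
    residues: set[ResidueId] = field(default_factory=set)
    avg_depth: float = 0.0
    rank: int = 0


@dataclass
class GridClassification:
    """Intermediate grid labelling shared by detection and depth analysis."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    occupied: np.ndarray  # bool grids
    bulk: np.ndarray
    accepted: np.ndarray

    def grid_to_coords(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin + idx * self.spacing

    @property
    def bulk_points(self) -> np.ndarray:
        return self.grid_to_coords(self.bulk)


def _shift(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Shifted view with zero fill: result[x] = a[x + d] where defined."""
    out = a
    for axis, step in enumerate(d):
        if step == 0:
            continue
        out = np.roll(out, -step, axis=axis)
        sl = [slice(None)] * 3
        sl[axis] = slice(None, -step) if step < 0 else slice(-step, None)
        out[tuple(sl)] = False
    return out


def _directional_occlusion(occupied: np.ndarray, d: np.ndarray) -> np.ndarray:
    """True where some occupied point exists along +d (strictly ahead).

    Computed by doubling shifts: after k rounds the result covers
    look-ahead distances 1..2^k, so log2(grid extent) rounds suffice.
    """
    reach = _shift(occupied, d)
    extent = max(occupied.shape)
    step = 1
    while step < extent:
        reach = reach | _shift(reach, d * step)
        step *= 2
    return reach


def _buried_axis_count(occupied: np.ndarray) -> np.ndarray:
    """Per grid point, number of scan axes with protein on both sides."""
    count = np.zeros(occupied.shape, dtype=np.int8)
    for d in _SCAN_AXES:
        fwd = _directional_occlusion(occupied, d)
        bwd = _directional_occlusion(occupied, -d)
        count += (fwd & bwd).astype(np.int8)
    return count


def classify_grid(
    s: ChainStructure, g: GridSpec | None = None, p: SasaParams | None = None
) -> GridClassification:
    """Label grid points as occupied / bulk solvent / accepted cavity points."""
    g = g or GridSpec()
    p = p or SasaParams()
    xyz = s.atom_coords()
    if len(xyz) < 10:
        raise ValueError("cavity detection requires at least 10 atoms")
    radii = np.array(
        [p.radius_of(a.element, a.name) for _r, a in s.atoms()]
    ) + p.probe_radius
    lo = xyz.min(axis=0) - g.padding
    hi = xyz.max(axis=0) + g.padding
    if np.any(hi - lo <= 2 * g.spacing):
        raise ValueError("degenerate bounding box")
    shape = tuple(int(np.floor((hi[k] - lo[k]) / g.spacing)) + 1 for k in range(3))
    axes = [lo[k] + g.spacing * np.arange(shape[k]) for k in range(3)]
    grid_pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    tree = cKDTree(grid_pts)
    occupied_flat = np.zeros(len(grid_pts), dtype=bool)
    for hits in tree.query_ball_point(xyz, radii):
        occupied_flat[hits] = True
    occupied = occupied_flat.reshape(shape)

    empty = ~occupied
    # bulk solvent: empty region 6-connected to the boundary
    six = ndimage.generate_binary_structure(3, 1)
    labels, _n = ndimage.label(empty, structure=six)
    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_labels.update(np.unique(labels[tuple(sl)]))
    boundary_labels.discard(0)
    bulk = np.isin(labels, sorted(boundary_labels))

    enclosed = empty & ~bulk
    buried = _buried_axis_count(occupied) >= g.buried_axes_min
    accepted = enclosed | (empty & buried)
    return GridClassification(
        origin=lo,
        spacing=g.spacing,
        shape=shape,
        occupied=occupied,
        bulk=bulk,
        accepted=accepted,
    )


def average_depth(c: Cavity, bulk_points: np.ndarray) -> float:
    """Mean distance (A) from the cavity's points to the nearest bulk-solvent point."""
    if len(bulk_points) == 0:
        raise ValueError("no bulk solvent points: pathological grid box")
    if len(c.points) == 0:
        raise ValueError("cavity has no points")
    d, _ = cKDTree(bulk_points).query(c.points)
    return float(np.mean(d))


def cavity_residues(
    c: Cavity, s: ChainStructure, contact_cutoff: float | None = None,
    p: SasaParams | None = None, grid_spacing: float = 1.0,
) -> set[ResidueId]:
    """Residues lining a cavity: any atom within the contact cutoff of any
    cavity point (default cutoff: atom vdW + probe + grid spacing)."""
    if len(c.points) == 0:
        raise ValueError("cavity has no points")
    p = p or SasaParams()
    tree = cKDTree(c.points)
    members: set[ResidueId] = set()
    for res, atom in s.atoms():
        if res.id in members:
            continue
        cutoff = (
            contact_cutoff
            if contact_cutoff is not None
            else p.radius_of(atom.element, atom.name) + p.probe_radius + grid_spacing
        )
        if tree.query_ball_point(atom.coord, cutoff, return_length=True) > 0:
            members.add(res.id)
    return members


def detect_cavities(
    s: ChainStructure,
    g: GridSpec | None = None,
    p: SasaParams | None = None,
    contact_cutoff: float | None = None,
) -> list[Cavity]:
    """Detect cavities/pockets; returns them sorted by volume, largest first.

    Each returned :class:`Cavity` carries its grid points, volume, lining
    residues and average depth; ``rank`` is 1 for the largest.
    """
    g = g or GridSpec()
    p = p or SasaParams()
    cls = classify_grid(s, g, p)
    twentysix = ndimage.generate_binary_structure(3, 3)
    labels, n = ndimage.label(cls.accepted, structure=twentysix)
    if n == 0:
        return []
    protein_centroid = s.atom_coords().mean(axis=0)
    bulk_pts = cls.bulk_points
    cavities: list[Cavity] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        npts = int(mask.sum())
        if npts < g.min_cluster_points:
            continue
        pts = cls.grid_to_coords(mask)
        cav = Cavity(points=pts, volume=npts * g.spacing**3)
        cav.residues = cavity_residues(cav, s, contact_cutoff, p, g.spacing)
        cav.avg_depth = average_depth(cav, bulk_pts) if len(bulk_pts) else 0.0
        cavities.append(cav)
    cavities.sort(
        key=lambda c: (
            -c.volume,
            float(np.linalg.norm(c.points.mean(axis=0) - protein_centroid)),
        )
    )
    for i, c in enumerate(cavities, start=1):
        c.rank = i
    return cavities
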