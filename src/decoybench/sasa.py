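"""Solvent accessible surface area (SASA) and exposure classification.

Per-atom SASA is computed with the Shrake-Rupley method: a deterministic
quasi-uniform lattice of test points (golden-spiral / Fibonacci) is placed
on each atom's solvent-expanded sphere (van der Waals radius + probe
radius, probe 1.4 A), and a point counts as accessible iff it lies outside
every other expanded sphere.  Residue SASA is the sum over the residue's
atoms; relative accessibility divides by the residue type's maximum
reference area from Miller et al. (1987), as a percentage.  Residues are
classed *exposed* above 70% relative accessibility and *buried* below 30%
(strict inequalities); everything else is *intermediate*.

Relative values above 100% can occur (e.g. terminal residues) and are kept
as-is; they classify as exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from decoybench.structure_io import ChainStructure, ResidueId

__all__ = [
    "ExposureClass",
    "SasaParams",
    "SasaProfile",
    "MILLER_MAX_SASA",
    "VDW_RADII",
    "shrake_rupley",
    "residue_absolute_sasa",
    "residue_relative_sasa",
    "classify_exposure",
    "sasa_profile",
    "sphere_points",
]

# Maximum residue accessibilities (A^2), Gly-X-Gly standard state,
# Miller, Janin, Lesk & Chothia, J Mol Biol 196 (1987) 641-656.
MILLER_MAX_SASA: dict[str, float] = {
    "ALA": 113.0, "ARG": 241.0, "ASN": 158.0, "ASP": 151.0, "CYS": 140.0,
    "GLN": 189.0, "GLU": 183.0, "GLY": 85.0, "HIS": 194.0, "ILE": 182.0,
    "LEU": 180.0, "LYS": 211.0, "MET": 204.0, "PHE": 218.0, "PRO": 143.0,
    "SER": 122.0, "THR": 146.0, "TRP": 259.0, "TYR": 229.0, "VAL": 160.0,
}

# single published van der Waals radius per element (A)
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
_FALLBACK_RADIUS = 1.70


class ExposureClass(str, Enum):
    EXPOSED = "exposed"
    BURIED = "buried"
    INTERMEDIATE = "intermediate"


@dataclass
class SasaParams:
    """Parameters of the SASA calculation and exposure classification."""

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_set: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    exposed_threshold: float = 70.0
    buried_threshold: float = 30.0
    miller_max: dict[str, float] = field(default_factory=lambda: dict(MILLER_MAX_SASA))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.buried_threshold >= self.exposed_threshold:
            raise ValueError("buried_threshold must be below exposed_threshold")

    def radius_of(self, element: str, atom_label: str = "") -> float:
        el = element.strip().upper()
        r = self.radii_set.get(el)
        if r is None:
            warnings.warn(
                f"no vdW radius for element {el or '?'} (atom {atom_label}); "
                f"using fallback {_FALLBACK_RADIUS} A",
                stacklevel=2,
            )
            return _FALLBACK_RADIUS
        return r


@dataclass
class SasaProfile:
    """Per-residue accessibility: absolute (A^2), Miller-relative (%), class."""

    per_residue_abs: dict[ResidueId, float]
    per_residue_rel: dict[ResidueId, float]
    exposure_class: dict[ResidueId, ExposureClass]
    params: SasaParams

    def residues_of_class(self, cls: ExposureClass) -> set[ResidueId]:
        return {rid for rid, c in self.exposure_class.items() if c is cls}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral), (n, 3)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(
    s: ChainStructure, p: SasaParams | None = None
) -> dict[tuple[ResidueId, str], float]:
    """Per-atom SASA (A^2), keyed by (residue id, atom name)."""
    p = p or SasaParams()
    keys: list[tuple[ResidueId, str]] = []
    coords: list[np.ndarray] = []
    radii: list[float] = []
    for res, atom in s.atoms():
        keys.append((res.id, atom.name))
        coords.append(atom.coord)
        radii.append(p.radius_of(atom.element, f"{res.id}/{atom.name}"))
    if not keys:
        raise ValueError("structure has no atoms")
    xyz = np.asarray(coords)
    rad = np.asarray(radii) + p.probe_radius  # expanded radii
    unit = sphere_points(p.n_sphere_points)
    tree = cKDTree(xyz)
    max_rad = rad.max()
    out: dict[tuple[ResidueId, str], float] = {}
    all_neigh = tree.query_ball_point(xyz, rad + max_rad)
    for i, key in enumerate(keys):
        pts = xyz[i] + rad[i] * unit
        # occluders: expanded spheres whose centre is within rad_i + rad_j
        neigh = np.array([j for j in all_neigh[i] if j != i], dtype=int)
        if len(neigh):
            dc = np.linalg.norm(xyz[neigh] - xyz[i], axis=1)
            mask = dc < rad[i] + rad[neigh]
            # nearest occluders first: they eliminate most test points early
            order = np.argsort(dc[mask])
            neigh = neigh[mask][order]
            alive = np.ones(len(pts), dtype=bool)
            for start in range(0, len(neigh), 8):
                if not alive.any():
                    break
                chunk = neigh[start : start + 8]
                idx = np.flatnonzero(alive)
                d2 = ((pts[idx, None, :] - xyz[chunk][None, :, :]) ** 2).sum(axis=2)
                blocked = np.any(d2 <= (rad[chunk] ** 2)[None, :], axis=1)
                alive[idx[blocked]] = False
            frac = alive.mean()
        else:
            frac = 1.0
        out[key] = float(4.0 * np.pi * rad[i] ** 2 * frac)
    return out


def residue_absolute_sasa(
    per_atom: dict[tuple[ResidueId, str], float]
) -> dict[ResidueId, float]:
    """Sum atom SASA within each residue."""
    abs_sasa: dict[ResidueId, float] = {}
    for (rid, _name), area in per_atom.items():
        abs_sasa[rid] = abs_sasa.get(rid, 0.0) + area
    return abs_sasa


def residue_relative_sasa(
    abs_sasa: dict[ResidueId, float],
    res_names: dict[ResidueId, str],
    p: SasaParams | None = None,
) -> dict[ResidueId, float]:
    """Miller-relative accessibility (%) per residue.

    Residue types absent from the reference table are skipped with a
    warning rather than raising; values above 100% are kept.
    """
    p = p or SasaParams()
    rel: dict[ResidueId, float] = {}
    skipped: list[str] = []
    for rid, area in abs_sasa.items():
        name = res_names.get(rid, "")
        ref = p.miller_max.get(name)
        if ref is None or ref <= 0:
            skipped.append(f"{rid}({name})")
            continue
        rel[rid] = 100.0 * area / ref
    if skipped:
        warnings.warn(
            f"{len(skipped)} residue(s) without a reference maximum skipped: "
            + ", ".join(skipped[:5]) + ("..." if len(skipped) > 5 else ""),
            stacklevel=2,
        )
    return rel


def classify_exposure(
    rel: dict[ResidueId, float], p: SasaParams | None = None
) -> dict[ResidueId, ExposureClass]:
    """Strictly above the exposed threshold -> exposed; strictly below the
    buried threshold -> buried; otherwise intermediate."""
    p = p or SasaParams()
    out: dict[ResidueId, ExposureClass] = {}
    for rid, v in rel.items():
        if v > p.exposed_threshold:
            out[rid] = ExposureClass.EXPOSED
        elif v < p.buried_threshold:
            out[rid] = ExposureClass.BURIED
        else:
            out[rid] = ExposureClass.INTERMEDIATE
    return out


def sasa_profile(s: ChainStructure, p: SasaParams | None = None) -> SasaProfile:
    """Full per-residue accessibility profile of a chain."""
    p = p or SasaParams()
    per_atom = shrake_rupley(s, p)
    abs_sasa = residue_absolute_sasa(per_atom)
    names = {r.id: r.res_name for r in s.residues}
    rel = residue_relative_sasa(abs_sasa, names, p)
    cls = classify_exposure(rel, p)
    return SasaProfile(
        per_residue_abs=abs_sasa, per_residue_rel=rel, exposure_class=cls, params=p
    )
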