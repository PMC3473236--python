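"""Seeded synthetic fixtures and decoy ladders of controlled GDT-TS.

This module stands in for a homology-search + comparative-modelling stage:
instead of building models from templates, it perturbs a known native
structure with a smooth, low-frequency displacement field and searches the
field amplitude until the perturbed model's GDT-TS falls in a requested
bin.  Smooth fields (a sum of a few sinusoidal modes over the residue
index, wavelengths bounded below by a correlation length) are used rather
than independent atomic noise so that decoys resemble comparative-model
error — a largely correct core with coherently displaced segments — which
is the regime the benchmarks are meant to probe.

Fixtures:

* :func:`make_helix_fixture` — an ideal alpha-helix (1.5 A rise and 100
  degrees of twist per residue, Ca ring radius 2.3 A) with N, CA, C, O,
  CB pseudo-atoms; the standard elongated single-chain test body.
* :func:`make_pocket_fixture` — pseudo-residues tiling concentric
  spherical shells that enclose an empty void of prescribed radius: a
  body with an exposed outer surface, a buried middle layer and a
  detectable internal cavity.

Everything is deterministic given its seed; ladder sub-seeds are derived
from (root seed, bin index, replicate index) via ``numpy`` seed
sequences, so bins and replicates are independent and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from decoybench.annotations import DecoyMeta, DecoySet
from decoybench.structure_io import AtomRecord, ChainStructure, Residue, ResidueId
from decoybench.superposition import gdt_ts, kabsch_superpose
from decoybench.structure_io import ca_trace

__all__ = [
    "PerturbationParams",
    "LadderSpec",
    "make_helix_fixture",
    "make_pocket_fixture",
    "perturb_structure",
    "generate_decoy_ladder",
]

_HELIX_RISE = 1.5  # A per residue
_HELIX_TWIST = np.deg2rad(100.0)  # per residue
_HELIX_CA_RADIUS = 2.3  # A

# (atom name, element, radial offset A, angular offset rad, axial offset A)
_HELIX_ATOMS = (
    ("N", "N", 1.60, np.deg2rad(-26.0), -0.90),
    ("CA", "C", _HELIX_CA_RADIUS, 0.0, 0.0),
    ("C", "C", 2.00, np.deg2rad(27.0), 0.55),
    ("O", "O", 2.10, np.deg2rad(30.0), 1.70),
    ("CB", "C", 3.40, np.deg2rad(-5.0), -0.75),
)

_AMPLITUDE_BRACKET = (0.0, 30.0)  # A, search range for ladder generation


@dataclass
class PerturbationParams:
    """Smooth displacement field applied to a structure.

    ``amplitude`` is the RMS per-residue displacement (A);
    ``correlation_length`` bounds mode wavelengths from below (residues);
    ``segment_jitter`` optionally adds an independent rigid translation
    per contiguous segment of ``correlation_length`` residues.
    """

    amplitude: float
    correlation_length: int = 6
    n_modes: int = 6
    segment_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1")


@dataclass
class LadderSpec:
    """Target GDT-TS bins for decoy generation.

    ``correlation_length`` / ``n_modes`` shape the displacement field of
    the generated decoys.  The defaults (3 modes, wavelengths of 25
    residues and up) produce coherent, segment-scale error — a largely
    intact core with smoothly displaced regions, the signature of
    template-based models — rather than residue-level noise.
    """

    target_bins: list[tuple[float, float]]
    decoys_per_bin: int = 3
    tolerance: float = 2.0
    max_iterations: int = 40
    seed: int = 0
    correlation_length: int = 25
    n_modes: int = 3

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        spans = sorted(self.target_bins)
        for (_, hi), (lo2, _) in zip(spans, spans[1:]):
            if lo2 < hi:
                raise ValueError("target bins must be disjoint")


def make_helix_fixture(
    n_residues: int, res_names: list[str] | None = None
) -> ChainStructure:
    """Ideal alpha-helix with N/CA/C/O/CB pseudo-atoms, chain A, all-ALA by default."""
    if n_residues < 4:
        raise ValueError("helix fixture requires at least 4 residues")
    if res_names is not None and len(res_names) != n_residues:
        raise ValueError("res_names length must equal n_residues")
    residues = []
    serial = 1
    for i in range(n_residues):
        theta = i * _HELIX_TWIST
        z = i * _HELIX_RISE
        name = res_names[i] if res_names else "ALA"
        atoms = []
        for atom_name, element, radius, dtheta, dz in _HELIX_ATOMS:
            if atom_name == "CB" and name == "GLY":
                continue
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=atom_name,
                    element=element,
                    coord=np.array(
                        [
                            radius * np.cos(theta + dtheta),
                            radius * np.sin(theta + dtheta),
                            z + dz,
                        ]
                    ),
                )
            )
            serial += 1
        residues.append(
            Residue(id=ResidueId("A", i + 1), res_name=name, atoms=atoms)
        )
    return ChainStructure(residues=residues, source_id=f"helix{n_residues}")


def _fibonacci_shell(n: int, radius: float, rotation: np.ndarray) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius * pts @ rotation.T


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-fixed to a proper rotation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_pocket_fixture(
    void_radius: float,
    shell_radius: float,
    n_shell_atoms: int | None = None,
    seed: int = 0,
    atoms_per_residue: int = 4,
    occlusion_radius: float = 3.1,  # C vdW 1.7 + probe 1.4
) -> ChainStructure:
    """Spherical-shell pseudo-protein enclosing an empty central void.

    Atom centres tile concentric spheres from ``void_radius +
    occlusion_radius`` (so the solvent-excluded void has the nominal
    radius) out to ``shell_radius``.  Consecutive atoms are grouped into
    pseudo-residues of ``atoms_per_residue`` atoms whose first atom is
    named CA, giving the fixture a Ca trace, an exposed outer surface, a
    buried interior layer and one enclosed cavity.
    """
    if void_radius <= 0:
        raise ValueError("void_radius must be positive")
    if void_radius + 3.0 > shell_radius:
        raise ValueError("shell_radius must exceed void_radius by at least 3 A")
    rng = np.random.default_rng(seed)
    r_inner = void_radius + occlusion_radius
    n_layers = max(2, int(round((shell_radius - r_inner) / 0.95)) + 1)
    layer_radii = np.linspace(r_inner, shell_radius, n_layers)
    areas = 4.0 * np.pi * layer_radii**2
    if n_shell_atoms is None:
        # inner/middle layers dense enough to stay solvent-tight at 1 A grid
        # (expanded radius ~3.1 A); the outermost layer sparser so its
        # residues keep an exposed outer surface
        spacing2 = np.full(n_layers, 4.8)  # ~2.2 A point spacing
        spacing2[-1] = 16.0  # ~4 A on the surface layer
        counts = np.ceil(areas / spacing2).astype(int)
    else:
        counts = np.maximum(4, np.round(n_shell_atoms * areas / areas.sum())).astype(int)
    coords = np.vstack(
        [
            _fibonacci_shell(c, r, _random_rotation(rng))
            for c, r in zip(counts, layer_radii)
        ]
    )
    atom_names = ["CA", "CB", "CG", "CD", "CE", "CZ"]
    residues = []
    for ri, start in enumerate(range(0, len(coords), atoms_per_residue)):
        block = coords[start : start + atoms_per_residue]
        atoms = [
            AtomRecord(
                serial=start + j + 1,
                name=atom_names[j % len(atom_names)],
                element="C",
                coord=block[j],
            )
            for j in range(len(block))
        ]
        residues.append(
            Residue(id=ResidueId("A", ri + 1), res_name="ALA", atoms=atoms)
        )
    return ChainStructure(residues=residues, source_id=f"pocket_v{void_radius:g}")


def _unit_field(n_residues: int, p: PerturbationParams) -> np.ndarray:
    """Unit-RMS smooth displacement field over residue index, (n, 3).

    Depends only on (n_residues, correlation_length, n_modes, seed): the
    amplitude is a pure scale factor, so an amplitude search re-uses one
    field shape.
    """
    rng = np.random.default_rng(p.seed)
    lam = np.exp(
        rng.uniform(
            np.log(max(p.correlation_length, 1)),
            np.log(max(n_residues, p.correlation_length + 1)),
            size=p.n_modes,
        )
    )
    phases = rng.uniform(0, 2 * np.pi, size=p.n_modes)
    dirs = rng.normal(size=(p.n_modes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    idx = np.arange(n_residues)[:, None]
    waves = np.sin(2 * np.pi * idx / lam[None, :] + phases[None, :])  # (n, m)
    disp = waves @ dirs  # (n, 3)
    rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    if rms < 1e-12:
        disp = rng.normal(size=disp.shape)
        rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    return disp / rms


def _segment_jitter_field(n_residues: int, p: PerturbationParams) -> np.ndarray:
    """Per-segment rigid translations, RMS = segment_jitter, (n, 3)."""
    rng = np.random.default_rng([p.seed, 7919])
    seg = np.arange(n_residues) // p.correlation_length
    n_seg = int(seg.max()) + 1
    jit = rng.normal(size=(n_seg, 3))
    rms = np.sqrt(np.mean(np.sum(jit[seg] ** 2, axis=1)))
    return p.segment_jitter * jit[seg] / max(rms, 1e-12)


def _displace(native: ChainStructure, disp: np.ndarray) -> ChainStructure:
    residues = []
    for i, res in enumerate(native.residues):
        atoms = [
            AtomRecord(
                serial=a.serial,
                name=a.name,
                element=a.element,
                coord=a.coord + disp[i],
                occupancy=a.occupancy,
                b_factor=a.b_factor,
                alt_loc=a.alt_loc,
            )
            for a in res.atoms
        ]
        residues.append(Residue(id=res.id, res_name=res.res_name, atoms=atoms))
    return ChainStructure(
        residues=residues,
        resolution=native.resolution,
        r_factor=native.r_factor,
        source_id=native.source_id + "_decoy",
    )


def perturb_structure(
    native: ChainStructure, p: PerturbationParams
) -> ChainStructure:
    """Displace each residue (all its atoms rigidly) by a smooth random field.

    The field is a sum of ``n_modes`` sinusoids over the residue index
    with wavelengths at or above ``correlation_length``, scaled so the
    RMS per-residue displacement equals ``amplitude``.  Residue identity
    and atom composition are untouched; amplitude 0 returns an identical
    copy.  Deterministic per seed.
    """
    if not native.residues:
        raise ValueError("native structure is empty")
    n = len(native.residues)
    disp = np.zeros((n, 3))
    if p.amplitude > 0:
        disp = disp + p.amplitude * _unit_field(n, p)
    if p.segment_jitter > 0:
        disp = disp + _segment_jitter_field(n, p)
    return _displace(native, disp)


def _sub_seed(root: int, bin_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence([int(root), int(bin_index), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_decoy_ladder(native: ChainStructure, spec: LadderSpec) -> DecoySet:
    """Generate decoys whose verified GDT-TS falls in each requested bin.

    For each bin and replicate, the amplitude of a fixed-shape smooth
    perturbation is bisected over [0, 30] A until the decoy's GDT-TS
    (computed with :func:`~decoybench.superposition.gdt_ts`, which is
    also the value stored in the metadata) lands inside the bin; if
    ``max_iterations`` is exhausted the nearest result within the bin
    widened by ``tolerance`` is accepted, otherwise the replicate is
    reported missing with a warning — never fabricated.
    """
    nat_trace = ca_trace(native)
    nat_ca = dict(nat_trace)
    decoys: list[ChainStructure] = []
    metas: list[DecoyMeta] = []
    for b_idx, (lo, hi) in enumerate(spec.target_bins):
        for rep in range(spec.decoys_per_bin):
            seed = _sub_seed(spec.seed, b_idx, rep)
            if lo >= 100.0:
                decoy = perturb_structure(
                    native,
                    PerturbationParams(
                        amplitude=0.0,
                        correlation_length=spec.correlation_length,
                        n_modes=spec.n_modes,
                        seed=seed,
                    ),
                )
                achieved = gdt_ts(native, decoy).gdt_ts
                decoys.append(decoy)
                metas.append(
                    DecoyMeta(
                        decoy_id=f"bin{lo:g}-{hi:g}_rep{rep}",
                        gdt_ts=achieved,
                        rmsd=0.0,
                    )
                )
                continue
            lo_amp, hi_amp = _AMPLITUDE_BRACKET
            best: tuple[float, ChainStructure, float] | None = None  # (gap, decoy, gdt)
            accepted = None
            for _ in range(spec.max_iterations):
                amp = 0.5 * (lo_amp + hi_amp)
                decoy = perturb_structure(
                    native,
                    PerturbationParams(
                        amplitude=amp,
                        correlation_length=spec.correlation_length,
                        n_modes=spec.n_modes,
                        seed=seed,
                    ),
                )
                achieved = gdt_ts(native, decoy).gdt_ts
                if lo <= achieved <= hi:
                    accepted = (decoy, achieved)
                    break
                gap = lo - achieved if achieved < lo else achieved - hi
                if best is None or gap < best[0]:
                    best = (gap, decoy, achieved)
                if achieved > hi:
                    lo_amp = amp  # too accurate: push harder
                else:
                    hi_amp = amp
            if accepted is None and best is not None and best[0] <= spec.tolerance:
                accepted = (best[1], best[2])
            if accepted is None:
                warnings.warn(
                    f"bin [{lo:g},{hi:g}] replicate {rep}: GDT-TS target not "
                    f"reached within {spec.max_iterations} iterations; skipped",
                    stacklevel=2,
                )
                continue
            decoy, achieved = accepted
            mod_ca = dict(ca_trace(decoy))
            common = [rid for rid, _ in nat_trace if rid in mod_ca]
            ref = np.array([nat_ca[r] for r in common])
            mov = np.array([mod_ca[r] for r in common])
            rmsd = kabsch_superpose(ref, mov).rmsd
            decoys.append(decoy)
            metas.append(
                DecoyMeta(
                    decoy_id=f"bin{lo:g}-{hi:g}_rep{rep}",
                    gdt_ts=achieved,
                    rmsd=rmsd,
                )
            )
    return DecoySet(native=native, decoys=decoys, meta=metas)
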