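"""Catalytic-site annotations, decoy metadata, and protrusion/burial indexes.

Catalytic sites are consumed from a local tab-separated file in a
CSA-like schema (``site_id  chain  seq_num  icode  res_name``); sites
with fewer than two residues are parsed but flagged ineligible for the
distance analysis.  Decoy metadata mirrors the statistics a homology
search/modelling pipeline attaches to each model (template, probability,
E-value, score, coverage) plus the quality scores computed here, and can
be sorted on any of these fields.

The protrusion index follows the CX method: for each atom,
count the non-hydrogen atoms within a 10 A sphere, convert to an internal
volume with a mean atom volume of 20.1 A^3, and report the ratio of the
external (empty) to internal sphere volume.  Protruding atoms have large
CX; the companion burial index is mapped to 1/(1+CX) in (0, 1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from decoybench.structure_io import ChainStructure, ResidueId

__all__ = [
    "CatalyticSite",
    "DecoyMeta",
    "DecoySet",
    "read_sites",
    "write_sites",
    "sort_decoys",
    "protrusion_index",
    "burial_index",
    "SITE_COLUMNS",
    "DEFAULT_MIN_COVERAGE",
    "DEFAULT_MAX_E_VALUE",
]

SITE_COLUMNS = ["site_id", "chain", "seq_num", "icode", "res_name"]

# template-admission defaults of the comparative-modelling stage
DEFAULT_MIN_COVERAGE = 0.80
DEFAULT_MAX_E_VALUE = 1e-1

# sort direction per metadata key: True = descending (higher is better)
_SORT_DESCENDING = {
    "gdt_ts": True,
    "probability": True,
    "score": True,
    "coverage": True,
    "rmsd": False,
    "E_value": False,
}


@dataclass
class CatalyticSite:
    site_id: str
    residues: list[tuple[ResidueId, str]]  # (residue id, 3-letter code)

    @property
    def eligible_for_distance_analysis(self) -> bool:
        """Distance analysis needs two or more residues."""
        return len(self.residues) >= 2

    @property
    def residue_ids(self) -> list[ResidueId]:
        return [rid for rid, _ in self.residues]


@dataclass
class DecoyMeta:
    """Per-decoy search/modelling statistics and quality scores.

    Fields that a synthetic decoy has no counterpart for (template id,
    homology-search statistics) stay ``None``.
    """

    decoy_id: str = ""
    template_id: str | None = None
    probability: float | None = None  # percent
    E_value: float | None = None
    score: float | None = None
    coverage: float | None = None  # fraction of the target covered
    gdt_ts: float | None = None
    rmsd: float | None = None

    def __post_init__(self) -> None:
        if self.coverage is not None and not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must be in [0, 1]")
        if self.E_value is not None and self.E_value < 0:
            raise ValueError("E_value must be non-negative")


@dataclass
class DecoySet:
    """A native chain together with its decoy models and their metadata."""

    native: ChainStructure
    decoys: list[ChainStructure] = field(default_factory=list)
    meta: list[DecoyMeta] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.decoys)

    def sorted_indices(self, key: str = "gdt_ts") -> list[int]:
        return sort_decoys(self.meta, key)


def read_sites(text: str) -> list[CatalyticSite]:
    """Parse a CSA-like TSV site file into catalytic sites.

    Rows sharing a ``site_id`` form one site, residue order preserved.
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site file missing column(s): {', '.join(missing)}")
    sites: dict[str, CatalyticSite] = {}
    for i, row in df.iterrows():
        try:
            seq_num = int(row["seq_num"])
        except ValueError:
            raise ValueError(
                f"site file line {i + 2}: non-integer seq_num {row['seq_num']!r}"
            ) from None
        rid = ResidueId(row["chain"], seq_num, row["icode"].strip())
        site = sites.setdefault(row["site_id"], CatalyticSite(row["site_id"], []))
        site.residues.append((rid, row["res_name"]))
    return list(sites.values())


def write_sites(sites: list[CatalyticSite]) -> str:
    """Serialise sites back to the TSV schema (inverse of :func:`read_sites`)."""
    rows = [
        {
            "site_id": s.site_id,
            "chain": rid.chain_id,
            "seq_num": rid.seq_num,
            "icode": rid.insertion_code,
            "res_name": name,
        }
        for s in sites
        for rid, name in s.residues
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(sep="\t", index=False)


def sort_decoys(metas: list[DecoyMeta], key: str = "gdt_ts") -> list[int]:
    """Stable sort permutation of decoy indices by a metadata key.

    Better values come first (descending for gdt_ts / probability / score /
    coverage, ascending for rmsd / E-value); entries missing the key are
    placed last in input order.
    """
    if key not in _SORT_DESCENDING:
        raise KeyError(
            f"unknown sort key {key!r}; valid: {sorted(_SORT_DESCENDING)}"
        )
    descending = _SORT_DESCENDING[key]

    def sort_value(i: int) -> tuple[int, float]:
        v = getattr(metas[i], key)
        if v is None:
            return (1, 0.0)
        return (0, -v if descending else v)

    return sorted(range(len(metas)), key=sort_value)


def protrusion_index(
    s: ChainStructure, sphere_radius: float = 10.0, mean_atom_volume: float = 20.1
) -> dict[tuple[ResidueId, str], float]:
    """CX protrusion index per atom, keyed by (residue id, atom name).

    V_int = (number of non-hydrogen atoms within ``sphere_radius``) x
    ``mean_atom_volume`` (floored at one atom: the atom itself);
    V_ext = sphere volume - V_int; CX = V_ext / V_int.
    """
    keys = []
    coords = []
    for res, atom in s.atoms():
        keys.append((res.id, atom.name))
        coords.append(atom.coord)
    if not keys:
        raise ValueError("structure has no atoms")
    xyz = np.asarray(coords)
    tree = cKDTree(xyz)
    counts = tree.query_ball_point(xyz, sphere_radius, return_length=True)
    sphere_volume = 4.0 / 3.0 * np.pi * sphere_radius**3
    v_int = np.maximum(counts, 1) * mean_atom_volume
    v_int = np.minimum(v_int, sphere_volume - mean_atom_volume)  # keep CX > 0
    cx = (sphere_volume - v_int) / v_int
    return dict(zip(keys, cx.tolist()))


def burial_index(
    s: ChainStructure, sphere_radius: float = 10.0, mean_atom_volume: float = 20.1
) -> dict[tuple[ResidueId, str], float]:
    """Burial companion of the protrusion index: 1 / (1 + CX), in (0, 1)."""
    cx = protrusion_index(s, sphere_radius, mean_atom_volume)
    return {k: 1.0 / (1.0 + v) for k, v in cx.items()}
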