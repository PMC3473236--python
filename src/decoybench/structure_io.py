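"""Reading, writing and filtering of single-chain PDB structures.

The in-memory model is deliberately small: a chain is an ordered list of
residues, each residue an ordered list of non-hydrogen atoms.  Residues are
addressed by :class:`ResidueId` (chain id, sequence number, insertion code)
so that a model that omits residues can still be put in correspondence with
its native structure.  Parsing and serialisation are delegated to gemmi;
this module adds the altloc/hydrogen/HETATM policy and the dataset-level
quality filters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueId",
    "Residue",
    "ChainStructure",
    "FilterCriteria",
    "FilterResult",
    "PdbParseError",
    "read_pdb",
    "write_pdb",
    "filter_dataset",
    "ca_trace",
]

# PDB coordinate fields are fixed-width %8.3f: representable range.
_COORD_MIN = -999.999
_COORD_MAX = 9999.999

_R_FACTOR_RE = re.compile(
    r"^REMARK\s+3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9]*\.?[0-9]+)",
)
_R_FACTOR_FALLBACK_RE = re.compile(
    r"^REMARK\s+3\s+R VALUE\s*(?:\(WORKING SET, NO CUTOFF\))?\s*:\s*([0-9]*\.?[0-9]+)"
)


class PdbParseError(ValueError):
    """Raised when PDB content cannot be interpreted."""


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identity of a residue within a chain: chain id, number, insertion code."""

    chain_id: str
    seq_num: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}{self.seq_num}{self.insertion_code}"


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")


@dataclass
class Residue:
    id: ResidueId
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def get_atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ChainStructure:
    """One protein chain: ordered residues plus header metadata."""

    residues: list[Residue]
    resolution: float | None = None
    r_factor: float | None = None
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def residue_map(self) -> dict[ResidueId, Residue]:
        return {r.id: r for r in self.residues}

    def atom_coords(self) -> np.ndarray:
        """(n_atoms, 3) array over all residues, file order."""
        return np.array([a.coord for r in self.residues for a in r.atoms], dtype=float)

    def atoms(self):
        for r in self.residues:
            for a in r.atoms:
                yield r, a


@dataclass
class FilterCriteria:
    """Dataset-level quality rules for experimental chains.

    Defaults reproduce a curated high-resolution X-ray selection:
    resolution at most 2 A, R-factor at most 0.3, 20-10000 residues,
    chains consisting only of Ca atoms rejected.
    """

    max_resolution: float = 2.0
    max_r_factor: float = 0.3
    min_length: int = 20
    max_length: int = 10000
    reject_ca_only: bool = True

    def __post_init__(self) -> None:
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be < max_length")
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")


@dataclass
class FilterResult:
    passed: bool
    violations: list[str]


def _is_hydrogen(element: str, name: str) -> bool:
    el = element.strip().upper()
    if el in ("H", "D", "T"):
        return True
    if not el:
        # infer from atom name: strip leading digits, first letter H
        stripped = name.strip().lstrip("0123456789")
        return stripped[:1].upper() == "H"
    return False


def _validate_atom_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PdbParseError(f"line {lineno}: ATOM record shorter than coordinate fields")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PdbParseError(
                    f"line {lineno}: malformed {what} coordinate field {line[lo:hi]!r}"
                ) from None


def _parse_r_factor(text: str) -> float | None:
    for line in text.splitlines():
        if not line.startswith("REMARK   3"):
            continue
        m = _R_FACTOR_RE.match(line) or _R_FACTOR_FALLBACK_RE.match(line)
        if m:
            return float(m.group(1))
    return None


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties -> first in file."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def read_pdb(text: str, source_id: str = "") -> list[ChainStructure]:
    """Parse PDB-format content into one :class:`ChainStructure` per chain.

    Hydrogens are dropped, HETATM records are excluded from residues, and
    where a residue carries alternate conformations only the
    highest-occupancy conformer of each atom is kept (ties resolved in
    favour of the earlier record).  Resolution and R-factor are taken from
    REMARK 2 / REMARK 3 where present.
    """
    if "ATOM" not in text:
        raise PdbParseError("no ATOM records found")
    _validate_atom_lines(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PdbParseError("no ATOM records found")
    resolution = st.resolution if st.resolution > 0 else None
    r_factor = _parse_r_factor(text)

    chains: list[ChainStructure] = []
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.het_flag == "H":
                continue
            icode = res.seqid.icode.strip()
            rid = ResidueId(chain.name, res.seqid.num, icode)
            kept = [
                AtomRecord(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    b_factor=a.b_iso,
                    alt_loc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in res
                if not _is_hydrogen(a.element.name, a.name)
            ]
            kept = _resolve_altlocs(kept)
            if kept:
                residues.append(Residue(id=rid, res_name=res.name, atoms=kept))
        if residues:
            chains.append(
                ChainStructure(
                    residues=residues,
                    resolution=resolution,
                    r_factor=r_factor,
                    source_id=f"{source_id or st.name or 'struct'}_{chain.name}",
                )
            )
    if not chains:
        raise PdbParseError("no ATOM records define any residue")
    return chains


def write_pdb(s: ChainStructure) -> str:
    """Serialise a chain to PDB-format text (round-trips ids, names, coords)."""
    if not s.residues:
        raise ValueError("cannot write an empty structure")
    st = gemmi.Structure()
    st.name = s.source_id or "chain"
    if s.resolution is not None:
        st.resolution = s.resolution
    model = gemmi.Model("1")
    by_chain: dict[str, gemmi.Chain] = {}
    for res in s.residues:
        coords = np.array([a.coord for a in res.atoms])
        if coords.min() < _COORD_MIN or coords.max() > _COORD_MAX:
            raise ValueError(
                f"residue {res.id}: coordinate outside PDB fixed-width range"
            )
        ch = by_chain.get(res.id.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.id.chain_id)
            by_chain[res.id.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.id.seq_num, res.id.insertion_code or " ")
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element or "X")
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            gres.add_atom(ga)
        ch.add_residue(gres)
    for ch in by_chain.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def filter_dataset(s: ChainStructure, c: FilterCriteria | None = None) -> FilterResult:
    """Apply the dataset quality rules; returns pass/fail plus every violated rule.

    A chain with no recorded resolution or R-factor is not assessable on
    that rule and passes it (synthetic fixtures carry no crystallographic
    header).
    """
    c = c or FilterCriteria()
    violations: list[str] = []
    if s.resolution is not None and s.resolution > c.max_resolution:
        violations.append("resolution")
    if s.r_factor is not None and s.r_factor > c.max_r_factor:
        violations.append("r_factor")
    n = len(s.residues)
    if n < c.min_length:
        violations.append("too_short")
    if n > c.max_length:
        violations.append("too_long")
    if c.reject_ca_only and s.residues:
        if all(a.name == "CA" for r in s.residues for a in r.atoms):
            violations.append("ca_only")
    return FilterResult(passed=not violations, violations=violations)


def ca_trace(s: ChainStructure) -> list[tuple[ResidueId, np.ndarray]]:
    """Ordered (ResidueId, Ca coordinate) pairs; residues lacking a Ca are skipped."""
    trace = [
        (r.id, a.coord)
        for r in s.residues
        if (a := r.get_atom("CA")) is not None
    ]
    if not trace:
        raise ValueError("structure contains no CA atoms")
    return trace
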