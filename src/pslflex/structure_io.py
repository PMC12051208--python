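"""Protein structure and secondary-structure input.

Reads PDB files into the lightweight containers the flexibility pipeline
uses: an ordered C-alpha skeleton (the point cloud all topology is built
on), the heavy-atom cloud (for packing densities) and the global metadata
(R-value, resolution, heavy-atom count). STRIDE per-residue records are
read from STRIDE's plain-text output; STRIDE itself is never invoked.

Only the first coordinate MODEL is used. Alternate locations are resolved
to the highest-occupancy conformer (ties broken by the lexicographically
smallest alt-loc id). HETATM records and hydrogens are excluded.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .errors import FormatError, JoinError, StructureError

logger = logging.getLogger(__name__)

#: STRIDE one-letter secondary structure classes:
#: H alpha-helix, G 3-10 helix, I pi-helix, E strand, B isolated bridge,
#: T turn, C coil.
SS_CODES = ("H", "G", "I", "E", "B", "T", "C")

#: Sentinel STRIDE emits for undefined dihedrals at chain termini.
STRIDE_TORSION_SENTINEL = 360.0


@dataclass
class AtomRecord:
    """One atom parsed from a coordinate file.

    ``b_factor`` is the crystallographic temperature factor in A^2; it is
    the prediction target for C-alpha atoms.
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coordinates: np.ndarray
    occupancy: float
    b_factor: float
    element: str

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError(f"non-finite coordinates for atom {self.serial}")
        if not np.isfinite(self.b_factor):
            raise StructureError(f"non-finite B-factor for atom {self.serial}")
        if not 0.0 <= self.occupancy <= 1.0:
            warnings.warn(
                f"occupancy {self.occupancy} outside [0, 1] for atom "
                f"{self.serial}; clamping",
                stacklevel=2,
            )
            self.occupancy = min(1.0, max(0.0, self.occupancy))

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass
class GlobalFeatures:
    """Per-structure metadata. Missing header fields stay ``None``."""

    r_value: Optional[float] = None
    resolution: Optional[float] = None
    n_heavy_atoms: int = 0


@dataclass
class ProteinStructure:
    """A parsed protein: ordered C-alpha records plus the heavy-atom cloud."""

    id: str
    calpha: list[AtomRecord] = field(default_factory=list)
    heavy_atoms: list[AtomRecord] = field(default_factory=list)
    global_features: GlobalFeatures = field(default_factory=GlobalFeatures)

    @property
    def ca_coordinates(self) -> np.ndarray:
        """(n, 3) array of C-alpha coordinates in file order."""
        if not self.calpha:
            return np.zeros((0, 3))
        return np.array([a.coordinates for a in self.calpha])

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([a.b_factor for a in self.calpha])


@dataclass
class StrideRecord:
    """One per-residue line (ASG record) of STRIDE output."""

    chain_id: str
    residue_seq: int
    residue_name: str
    ss_code: str
    phi: float
    psi: float
    solvent_area: float


def _resolve_altlocs(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    """Pick the highest-occupancy conformer; ties -> smallest alt-loc id."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc or ""))


def parse_pdb(path) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Uses the first MODEL only; excludes HETATM records and hydrogens.
    Raises :class:`StructureError` if no C-alpha atom survives filtering.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no coordinate model")
    model = st[0]

    heavy: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A":  # HETATM excluded
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            for name, conformers in by_name.items():
                atom = _resolve_altlocs(conformers)
                heavy.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=name,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        residue_seq=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        coordinates=np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        ),
                        occupancy=float(atom.occ),
                        b_factor=float(atom.b_iso),
                        element=atom.element.name,
                    )
                )

    calpha = [a for a in heavy if a.name == "CA"]
    if not calpha:
        raise StructureError(f"{path}: no C-alpha atoms")
    # one CA per residue is guaranteed by alt-loc resolution; order by
    # (chain, residue number, insertion code) for a stable skeleton
    calpha.sort(key=lambda a: (a.chain_id, a.residue_seq, a.insertion_code))

    globals_ = parse_global_header(path)
    globals_.n_heavy_atoms = len(heavy)
    return ProteinStructure(
        id=st.name or str(path),
        calpha=calpha,
        heavy_atoms=heavy,
        global_features=globals_,
    )


_RESOLUTION_RE = re.compile(
    r"^REMARK\s+2\s+RESOLUTION\.\s+(\S+)\s+ANGSTROM", re.IGNORECASE
)
_RVALUE_RE = re.compile(
    r"^REMARK\s+3\s+R VALUE\s*(?:\([^)]*\))?\s*:\s*(\S+)", re.IGNORECASE
)


def parse_global_header(path) -> GlobalFeatures:
    """Extract resolution (REMARK 2) and R-value (REMARK 3) from a PDB header.

    Missing or malformed records yield ``None`` (never zero); a malformed
    numeric field additionally logs a warning.
    """
    resolution = None
    r_value = None
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            if resolution is None:
                m = _RESOLUTION_RE.match(line)
                if m:
                    resolution = _parse_header_number(m.group(1), "resolution", path)
                    continue
            if r_value is None:
                m = _RVALUE_RE.match(line)
                if m:
                    r_value = _parse_header_number(m.group(1), "R-value", path)
    if resolution is not None and resolution <= 0:
        logger.warning("%s: non-positive resolution %s treated as missing", path, resolution)
        resolution = None
    if r_value is not None and not 0.0 <= r_value <= 1.0:
        logger.warning("%s: R-value %s outside [0, 1] treated as missing", path, r_value)
        r_value = None
    return GlobalFeatures(r_value=r_value, resolution=resolution)


def _parse_header_number(token: str, what: str, path) -> Optional[float]:
    try:
        return float(token)
    except ValueError:
        logger.warning("%s: malformed %s field %r treated as missing", path, what, token)
        return None


def parse_stride(path) -> list[StrideRecord]:
    """Parse the ASG (per-residue assignment) lines of STRIDE output.

    Lowercase ``b`` (STRIDE's alternate bridge code) is normalized to ``B``;
    unknown codes map to coil ``C`` with a warning.
    """
    records: list[StrideRecord] = []
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ASG"):
                continue
            parts = line.split()
            if len(parts) < 10:
                raise FormatError(f"{path}:{lineno}: short ASG line")
            try:
                residue_seq = int(re.sub(r"[^-0-9]", "", parts[3]))
                phi, psi, area = (float(parts[7]), float(parts[8]), float(parts[9]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable ASG field") from exc
            code = parts[5]
            if code == "b":
                code = "B"
            if code not in SS_CODES:
                warnings.warn(
                    f"{path}:{lineno}: unknown secondary-structure code "
                    f"{code!r} mapped to coil",
                    stacklevel=2,
                )
                code = "C"
            records.append(
                StrideRecord(
                    chain_id=parts[2],
                    residue_seq=residue_seq,
                    residue_name=parts[1],
                    ss_code=code,
                    phi=phi,
                    psi=psi,
                    solvent_area=area,
                )
            )
    if not records:
        raise FormatError(f"{path}: no ASG records")
    return records


@dataclass
class JoinResult:
    """Alignment of STRIDE records to the C-alpha skeleton.

    ``aligned[i]`` is the record for ``structure.calpha[i]`` or ``None``.
    ``flagged`` marks structures whose match rate is below 100% (these are
    the inconsistent STRIDE/PDB cases a benchmark set should exclude).
    """

    aligned: list[Optional[StrideRecord]]
    unmatched: set[tuple]
    flagged: bool


def join_stride(structure: ProteinStructure, records: Sequence[StrideRecord]) -> JoinResult:
    """Match STRIDE records to C-alpha atoms by (chain id, residue number)."""
    if not structure.calpha or not records:
        raise JoinError("empty structure or record list")
    by_key = {(r.chain_id, r.residue_seq): r for r in records}
    aligned: list[Optional[StrideRecord]] = []
    unmatched: set[tuple] = set()
    for atom in structure.calpha:
        rec = by_key.get((atom.chain_id, atom.residue_seq))
        aligned.append(rec)
        if rec is None:
            unmatched.add((atom.chain_id, atom.residue_seq))
    n_matched = sum(r is not None for r in aligned)
    if n_matched == 0:
        raise JoinError("no STRIDE record matches any C-alpha atom")
    if unmatched:
        logger.warning(
            "%s: %d of %d residues lack STRIDE records",
            structure.id,
            len(unmatched),
            len(structure.calpha),
        )
    return JoinResult(aligned=aligned, unmatched=unmatched, flagged=bool(unmatched))


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write heavy atoms back out as fixed-column PDB ATOM records.

    Round-trips coordinates, occupancies and B-factors through
    :func:`parse_pdb` (used by the synthetic generator and for debugging).
    """
    with open(path, "w", encoding="utf-8") as fh:
        if structure.global_features.resolution is not None:
            fh.write(
                "REMARK   2 RESOLUTION.    "
                f"{structure.global_features.resolution:.2f} ANGSTROMS.\n"
            )
        if structure.global_features.r_value is not None:
            fh.write(
                "REMARK   3   R VALUE            (WORKING SET) : "
                f"{structure.global_features.r_value:.3f}\n"
            )
        for atom in structure.heavy_atoms:
            x, y, z = atom.coordinates
            fh.write(
                "ATOM  {serial:>5d} {name:^4s}{alt}{res:>3s} {chain:1s}"
                "{seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
                "{b:6.2f}          {el:>2s}\n".format(
                    serial=atom.serial % 100000,
                    name=atom.name if len(atom.name) >= 4 else f" {atom.name}",
                    alt=" ",
                    res=atom.residue_name,
                    chain=atom.chain_id[:1] or "A",
                    seq=atom.residue_seq,
                    icode=atom.insertion_code or " ",
                    x=x,
                    y=y,
                    z=z,
                    occ=atom.occupancy,
                    b=atom.b_factor,
                    el=atom.element,
                )
            )
        fh.write("END\n")
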