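"""Per-residue feature construction and feature-table persistence.

Each C-alpha atom gets a PSL spectral block (five statistics per filtration
radius), heavy-atom packing densities in three distance shells, residue and
secondary-structure one-hot encodings, backbone dihedrals, solvent area,
occupancy and the structure-level metadata, joined to the experimental
B-factor target.

Two presets mirror the two prediction pipelines: ``PslConfig.regression()``
(L0 spectra at radii 6/9/12 A, median as the fifth statistic; used with
per-protein linear fits) and ``PslConfig.blind()`` (L1 spectra at radii
7/10/13 A, standard deviation; used as blind machine-learning features).
The neighborhood cutoff always equals the filtration radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, PslflexError
from .filtration import build_alpha_complex, select_neighborhood
from .sheaf_spectra import build_sheaf, sheaf_laplacian, spectrum, summarize
from .structure_io import (
    SS_CODES,
    STRIDE_TORSION_SENTINEL,
    ProteinStructure,
    StrideRecord,
    join_stride,
)

logger = logging.getLogger(__name__)

#: the 20 standard amino acids (alphabetical three-letter codes) + "X" for
#: anything nonstandard
AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "X",
)

#: packing-density shells in angstroms: short d < 3, medium 3 <= d < 5,
#: long 5 <= d
PACKING_SHELLS = (3.0, 5.0)


@dataclass(frozen=True)
class PslConfig:
    """Which Laplacian order, radii and fifth statistic to featurize with."""

    laplacian_order: int = 0
    radii: tuple = (6.0, 9.0, 12.0)
    fourth_stat: str = "median"

    def __post_init__(self) -> None:
        if self.laplacian_order not in (0, 1):
            raise ValueError("laplacian_order must be 0 or 1")
        radii = tuple(float(r) for r in self.radii)
        if any(r <= 0 for r in radii) or list(radii) != sorted(set(radii)):
            raise ValueError("radii must be strictly increasing and positive")
        object.__setattr__(self, "radii", radii)
        if self.fourth_stat not in ("median", "std"):
            raise ValueError("fourth_stat must be 'median' or 'std'")

    @classmethod
    def regression(cls) -> "PslConfig":
        """L0 / radii 6, 9, 12 A / median: the per-protein regression preset."""
        return cls(laplacian_order=0, radii=(6.0, 9.0, 12.0), fourth_stat="median")

    @classmethod
    def blind(cls) -> "PslConfig":
        """L1 / radii 7, 10, 13 A / std: the blind machine-learning preset."""
        return cls(laplacian_order=1, radii=(7.0, 10.0, 13.0), fourth_stat="std")

    @property
    def n_features(self) -> int:
        return 5 * len(self.radii)

    @property
    def feature_names(self) -> list[str]:
        names = []
        for r in self.radii:
            tag = f"psl_r{r:g}"
            names += [
                f"{tag}_nzero",
                f"{tag}_max",
                f"{tag}_min",
                f"{tag}_mean",
                f"{tag}_{self.fourth_stat}",
            ]
        return names


def psl_spectral_block(
    structure: ProteinStructure, atom_index: int, config: PslConfig
) -> np.ndarray:
    """The PSL feature block of one C-alpha: 5 statistics per radius."""
    block = np.zeros(config.n_features)
    for r_idx, radius in enumerate(config.radii):
        cloud = select_neighborhood(structure, atom_index, cutoff=radius)
        complex_ = build_alpha_complex(cloud, radius)
        sheaf = build_sheaf(complex_, cloud)
        lap = sheaf_laplacian(sheaf, q=config.laplacian_order)
        summary = summarize(spectrum(lap), fourth_stat=config.fourth_stat)
        block[5 * r_idx : 5 * r_idx + 5] = summary.as_vector()
    return block


def psl_features(structure: ProteinStructure, config: PslConfig) -> np.ndarray:
    """(n_residues, 5 * n_radii) PSL feature matrix for the whole structure."""
    if not structure.calpha:
        raise PslflexError("structure has no C-alpha atoms")
    return np.array(
        [
            psl_spectral_block(structure, i, config)
            for i in range(len(structure.calpha))
        ]
    )


def packing_density(
    structure: ProteinStructure, calpha_index: int
) -> tuple[float, float, float]:
    """Shell-normalized heavy-atom neighbor counts around one C-alpha.

    Counts heavy atoms (excluding the focal C-alpha record itself) at
    distances d < 3, 3 <= d < 5 and 5 <= d from the focal atom, each
    divided by the total heavy-atom count N of the protein.
    """
    if not structure.heavy_atoms:
        raise PslflexError("structure has no heavy atoms")
    focal = structure.calpha[calpha_index]
    others = [
        a
        for a in structure.heavy_atoms
        if not (a.residue_key == focal.residue_key and a.name == focal.name)
    ]
    n_total = structure.global_features.n_heavy_atoms or len(structure.heavy_atoms)
    if not others:
        return (0.0, 0.0, 0.0)
    dist = np.linalg.norm(
        np.array([a.coordinates for a in others]) - focal.coordinates, axis=1
    )
    short, medium = PACKING_SHELLS
    return (
        float((dist < short).sum()) / n_total,
        float(((dist >= short) & (dist < medium)).sum()) / n_total,
        float((dist >= medium).sum()) / n_total,
    )


def residue_onehot(residue_name: str) -> np.ndarray:
    """21-way one-hot over the standard amino acids; nonstandard -> "X"."""
    vec = np.zeros(len(AMINO_ACIDS))
    name = residue_name.strip().upper()
    idx = AMINO_ACIDS.index(name) if name in AMINO_ACIDS[:-1] else len(AMINO_ACIDS) - 1
    vec[idx] = 1.0
    return vec


def secondary_features(record: StrideRecord) -> np.ndarray:
    """7-way secondary-structure one-hot + (phi, psi, solvent area).

    The 360.0 terminus sentinel used for undefined dihedrals is replaced
    by 0.0.
    """
    vec = np.zeros(len(SS_CODES) + 3)
    vec[SS_CODES.index(record.ss_code)] = 1.0
    phi = 0.0 if record.phi == STRIDE_TORSION_SENTINEL else record.phi
    psi = 0.0 if record.psi == STRIDE_TORSION_SENTINEL else record.psi
    vec[-3:] = (phi, psi, record.solvent_area)
    return vec


def feature_columns(config: PslConfig) -> list[str]:
    """The fixed column order of a feature table."""
    return (
        ["protein_id", "chain_id", "residue_seq"]
        + config.feature_names
        + ["packing_short", "packing_medium", "packing_long"]
        + [f"aa_{a}" for a in AMINO_ACIDS]
        + [f"ss_{c}" for c in SS_CODES]
        + ["phi", "psi", "solvent_area", "occupancy"]
        + ["r_value", "resolution", "n_heavy_atoms"]
        + ["b_factor"]
    )


def assemble_feature_table(
    structure: ProteinStructure,
    stride_records: Sequence[StrideRecord],
    config: Optional[PslConfig] = None,
) -> pd.DataFrame:
    """One feature row per C-alpha matched to a STRIDE record.

    Unmatched residues are dropped with a logged count; missing global
    metadata stays NaN (imputed only by downstream training splits).
    """
    config = config or PslConfig.blind()
    join = join_stride(structure, stride_records)
    psl = psl_features(structure, config)
    g = structure.global_features

    rows = []
    n_dropped = 0
    for i, (atom, rec) in enumerate(zip(structure.calpha, join.aligned)):
        if rec is None:
            n_dropped += 1
            continue
        row = (
            [structure.id, atom.chain_id, atom.residue_seq]
            + list(psl[i])
            + list(packing_density(structure, i))
            + list(residue_onehot(atom.residue_name))
            + list(secondary_features(rec))
            + [atom.occupancy]
            + [
                np.nan if g.r_value is None else g.r_value,
                np.nan if g.resolution is None else g.resolution,
                g.n_heavy_atoms,
            ]
            + [atom.b_factor]
        )
        rows.append(row)
    if not rows:
        raise PslflexError(f"{structure.id}: no residue matched a STRIDE record")
    if n_dropped:
        logger.warning("%s: dropped %d unmatched residues", structure.id, n_dropped)
    return pd.DataFrame(rows, columns=feature_columns(config))


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Persist a feature table as comma-separated text with a fixed header."""
    table.to_csv(path, index=False)


def read_feature_table(path, config: Optional[PslConfig] = None) -> pd.DataFrame:
    """Read a feature table back, validating the header."""
    config = config or PslConfig.blind()
    table = pd.read_csv(path)
    expected = feature_columns(config)
    if list(table.columns) != expected:
        raise FormatError(f"{path}: header does not match the expected columns")
    return table
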