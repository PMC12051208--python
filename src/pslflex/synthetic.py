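"""Synthetic protein structures with known generative parameters.

The generator emulates the statistical structure the flexibility pipeline
assumes — a C-alpha trace with ~3.8 A spacing (ideal alpha-helix, random
coil, or gently curved chain), a heavy-atom environment around each
residue, per-residue B-factors that are exactly linear in the L0 PSL
spectral features plus Gaussian noise, and STRIDE-like secondary-structure
records — so every pipeline stage is testable without downloading real
structures, and parameter-recovery tests are sharp: at zero noise a
per-protein linear fit must reproduce the B-factors exactly.

An alternative GNM-profile-based B-factor model is included so baseline
comparisons are not circular in the PSL features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import PslflexError
from .featurize import PslConfig, psl_features
from .predict import GNM_CUTOFF, kirchhoff_matrix
from .sheaf_spectra import ZERO_EIG_RTOL
from .structure_io import (
    AtomRecord,
    GlobalFeatures,
    ProteinStructure,
    StrideRecord,
)
from .filtration import LabeledPointCloud

#: ideal alpha-helix geometry: rise per residue (A), helix radius (A),
#: rotation per residue (degrees); yields ~3.8 A C-alpha spacing
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST_DEG = 100.0

#: minimum allowed separation (A) between non-consecutive coil residues
COIL_MIN_SEPARATION = 3.0

#: default linear B-factor model over the 15 L0 PSL features + intercept;
#: weights emphasize the zero-eigenvalue counts and the mean spectra, the
#: statistics that actually vary along a chain
DEFAULT_B_MODEL = np.array(
    [
        4.0, -2.0, 6.0, 3.0, 1.0,
        3.0, -1.5, 4.0, 2.0, 0.5,
        2.0, -1.0, 3.0, 1.5, 0.25,
        20.0,  # intercept
    ]
)


@dataclass
class SyntheticSpec:
    """Generation parameters for one synthetic protein."""

    n_residues: int = 50
    geometry: str = "helix"  # "helix" | "coil" | "chain"
    ca_spacing: float = 3.8
    heavy_per_residue: int = 4
    b_model: np.ndarray = field(default_factory=lambda: DEFAULT_B_MODEL.copy())
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.ca_spacing <= 0:
            raise ValueError("ca_spacing must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.geometry not in ("helix", "coil", "chain"):
            raise ValueError("geometry must be helix, coil or chain")
        self.b_model = np.asarray(self.b_model, dtype=float)
        if self.b_model.shape != (16,):
            raise ValueError("b_model must have 15 coefficients + intercept")


@dataclass
class SyntheticProtein:
    """A generated structure together with its generative ground truth."""

    structure: ProteinStructure
    features: np.ndarray  # the L0 PSL features the B-factors are linear in
    b_noiseless: np.ndarray
    spec: SyntheticSpec


def _helix_trace(n: int) -> np.ndarray:
    theta = np.deg2rad(HELIX_TWIST_DEG) * np.arange(n)
    return np.stack(
        [
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * np.arange(n, dtype=float),
        ],
        axis=1,
    )


def _chain_trace(n: int, spacing: float) -> np.ndarray:
    """A gently helical chain: close to extended but never degenerate."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        phase = 0.35 * i
        direction = np.array([1.0, 0.25 * np.sin(phase), 0.25 * np.cos(phase)])
        coords[i] = coords[i - 1] + spacing * direction / np.linalg.norm(direction)
    return coords


def _coil_trace(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded self-avoiding random walk with fixed step length."""
    max_restarts = 50
    for _ in range(max_restarts):
        coords = [np.zeros(3)]
        direction = np.array([1.0, 0.0, 0.0])
        failed = False
        for _ in range(n - 1):
            placed = False
            for _ in range(100):
                proposal = direction + 0.8 * rng.normal(size=3)
                proposal /= np.linalg.norm(proposal)
                candidate = coords[-1] + spacing * proposal
                prior = np.array(coords[:-1]) if len(coords) > 1 else None
                if prior is None or np.all(
                    np.linalg.norm(prior - candidate, axis=1) >= COIL_MIN_SEPARATION
                ):
                    coords.append(candidate)
                    direction = proposal
                    placed = True
                    break
            if not placed:
                failed = True
                break
        if not failed:
            return np.array(coords)
    raise PslflexError(f"self-avoiding walk failed after {max_restarts} restarts")


def synth_structure(spec: SyntheticSpec) -> SyntheticProtein:
    """Generate a structure whose B-factors follow a known linear model.

    B = b_model . psl_features(L0, radii 6/9/12, median) + N(0, noise_sigma),
    deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "helix":
        coords = _helix_trace(spec.n_residues)
    elif spec.geometry == "chain":
        coords = _chain_trace(spec.n_residues, spec.ca_spacing)
    else:
        coords = _coil_trace(spec.n_residues, spec.ca_spacing, rng)

    residue_names = ("ALA", "GLY", "SER", "LEU", "VAL")
    calpha: list[AtomRecord] = []
    heavy: list[AtomRecord] = []
    serial = 1
    for i, xyz in enumerate(coords):
        ca = AtomRecord(
            serial=serial,
            name="CA",
            residue_name=residue_names[i % len(residue_names)],
            chain_id="A",
            residue_seq=i + 1,
            insertion_code="",
            coordinates=xyz,
            occupancy=1.0,
            b_factor=0.0,
            element="C",
        )
        serial += 1
        calpha.append(ca)
        heavy.append(ca)
        for j in range(spec.heavy_per_residue - 1):
            offset = rng.normal(size=3)
            offset *= rng.uniform(1.2, 2.4) / np.linalg.norm(offset)
            heavy.append(
                AtomRecord(
                    serial=serial,
                    name=("CB", "N", "O", "C", "CG")[j % 5],
                    residue_name=ca.residue_name,
                    chain_id="A",
                    residue_seq=i + 1,
                    insertion_code="",
                    coordinates=xyz + offset,
                    occupancy=1.0,
                    b_factor=0.0,
                    element=("C", "N", "O", "C", "C")[j % 5],
                )
            )
            serial += 1

    structure = ProteinStructure(
        id=f"SYN{spec.seed:04d}",
        calpha=calpha,
        heavy_atoms=heavy,
        global_features=GlobalFeatures(
            r_value=0.2, resolution=1.8, n_heavy_atoms=len(heavy)
        ),
    )
    features = psl_features(structure, PslConfig.regression())
    b_clean = features @ spec.b_model[:15] + spec.b_model[15]
    noise = rng.normal(scale=spec.noise_sigma, size=len(b_clean)) if spec.noise_sigma else 0.0
    b_noisy = b_clean + noise
    for atom, b in zip(calpha, b_noisy):
        atom.b_factor = float(b)
    for atom in heavy:
        if atom.name != "CA":
            atom.b_factor = float(b_noisy[atom.residue_seq - 1])
    return SyntheticProtein(
        structure=structure,
        features=features,
        b_noiseless=b_clean,
        spec=spec,
    )


def gnm_based_bfactors(
    structure: ProteinStructure,
    scale: float = 30.0,
    offset: float = 10.0,
    cutoff: float = GNM_CUTOFF,
) -> np.ndarray:
    """Alternative ground truth: B-factors proportional to the GNM profile.

    Used to decouple baseline comparisons from the PSL feature map.
    """
    gamma = kirchhoff_matrix(structure.ca_coordinates, cutoff)
    eigvals, eigvecs = np.linalg.eigh(gamma)
    tol = ZERO_EIG_RTOL * max(1.0, float(eigvals[-1]))
    keep = eigvals >= tol
    profile = np.einsum(
        "ik,k,ik->i", eigvecs[:, keep], 1.0 / eigvals[keep], eigvecs[:, keep]
    )
    return offset + scale * profile


def synth_stride(
    structure: ProteinStructure,
    geometry: str = "helix",
    seed: int = 0,
) -> list[StrideRecord]:
    """STRIDE-like records aligned 1:1 with the C-alpha skeleton.

    Helix geometry gets code H with dihedrals near (-60, -45); everything
    else is coil with wrapped random dihedrals. Chain termini carry the
    360.0 sentinel, as STRIDE emits.
    """
    rng = np.random.default_rng(seed)
    records = []
    n = len(structure.calpha)
    for i, atom in enumerate(structure.calpha):
        if geometry == "helix":
            code, phi, psi = "H", -60.0 + rng.normal(scale=3.0), -45.0 + rng.normal(scale=3.0)
        else:
            code = "C"
            phi = float(((rng.uniform(-180, 180) + 180) % 360) - 180)
            psi = float(((rng.uniform(-180, 180) + 180) % 360) - 180)
        if i == 0:
            phi = 360.0
        if i == n - 1:
            psi = 360.0
        records.append(
            StrideRecord(
                chain_id=atom.chain_id,
                residue_seq=atom.residue_seq,
                residue_name=atom.residue_name,
                ss_code=code,
                phi=float(phi),
                psi=float(psi),
                solvent_area=float(rng.uniform(0.0, 120.0)),
            )
        )
    return records


def synth_blind_dataset(
    n_proteins: int,
    n_residues: int = 30,
    seed: int = 0,
    geometry: str = "coil",
    coeff_jitter: float = 0.0,
    intercept_sd: float = 0.0,
    noise_sigma: float = 1.0,
    config: Optional[PslConfig] = None,
):
    """Feature tables for a synthetic blind-prediction study.

    Each protein's B-factors follow the linear L0-feature model with
    per-protein coefficient perturbations (``coeff_jitter``) and intercept
    shifts (``intercept_sd``). Nonzero perturbations create within-protein
    target structure that does not generalize across proteins — the
    regime in which atom-level cross-validation leaks and protein-level
    cross-validation does not.

    Returns (tables, proteins): blind-preset feature tables and the
    underlying :class:`SyntheticProtein` objects.
    """
    from .featurize import assemble_feature_table  # local: avoids cycle at import

    config = config or PslConfig.blind()
    root = np.random.default_rng(seed)
    tables = []
    proteins = []
    for p in range(n_proteins):
        child = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(child)
        model = DEFAULT_B_MODEL.copy()
        if coeff_jitter:
            model[:15] += rng.normal(scale=coeff_jitter, size=15) * np.abs(model[:15])
        if intercept_sd:
            model[15] += rng.normal(scale=intercept_sd)
        spec = SyntheticSpec(
            n_residues=int(rng.integers(max(3, n_residues * 4 // 5), n_residues * 6 // 5 + 1)),
            geometry=geometry,
            b_model=model,
            noise_sigma=noise_sigma,
            seed=child,
        )
        protein = synth_structure(spec)
        # per-protein structure-determination metadata, as real depositions vary
        protein.structure.global_features.r_value = float(rng.uniform(0.15, 0.25))
        protein.structure.global_features.resolution = float(rng.uniform(1.2, 2.8))
        records = synth_stride(protein.structure, geometry=geometry, seed=child)
        tables.append(assemble_feature_table(protein.structure, records, config))
        proteins.append(protein)
    return tables, proteins


def write_stride(records, path) -> None:
    """Write records in STRIDE's ASG plain-text layout."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("REM  Synthetic STRIDE-like output\n")
        names = {
            "H": "AlphaHelix", "G": "310Helix", "I": "PiHelix",
            "E": "Strand", "B": "Bridge", "T": "Turn", "C": "Coil",
        }
        for i, r in enumerate(records, start=1):
            fh.write(
                f"ASG  {r.residue_name:3s} {r.chain_id:1s} {r.residue_seq:4d} "
                f"{i:4d}    {r.ss_code:1s}   {names[r.ss_code]:<11s}  "
                f"{r.phi:7.2f} {r.psi:7.2f} {r.solvent_area:7.1f}\n"
            )


def fixture_clouds() -> dict[str, LabeledPointCloud]:
    """The small worked fixtures used throughout the test suite.

    Expected spectra (hand-derived):

    * ``two_point``: labels (0, 1), separation 2 -> L0 eigenvalues {0, 1/4}
    * ``right_345``: 3-4-5 right triangle, focal at the right angle,
      labels (0, 1, 1) -> L0 eigenvalues {0, 2/25, 25/144}
    * ``equilateral``: unit side, constant labels -> L1 spectrum {3, 3, 3}
      once the triangle is present
    * ``two_cluster``: two well-separated pairs -> two L0 zero modes at
      small radius
    * ``tetrahedron``: regular unit tetrahedron (oracle fixture)
    """
    clouds = {
        "two_point": LabeledPointCloud(
            points=np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]),
            labels=np.array([0.0, 1.0]),
            focal_index=0,
        ),
        "right_345": LabeledPointCloud(
            points=np.array(
                [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0]]
            ),
            labels=np.array([0.0, 1.0, 1.0]),
            focal_index=0,
        ),
        "equilateral": LabeledPointCloud(
            points=np.array(
                [
                    [0.0, 0.0, 0.0],
                    [1.0, 0.0, 0.0],
                    [0.5, np.sqrt(3.0) / 2.0, 0.0],
                ]
            ),
            labels=np.ones(3),
        ),
        "two_cluster": LabeledPointCloud(
            points=np.array(
                [
                    [0.0, 0.0, 0.0],
                    [1.0, 0.2, 0.1],
                    [10.0, 0.0, 0.0],
                    [11.0, 0.3, -0.2],
                ]
            ),
            labels=np.ones(4),
        ),
        "tetrahedron": LabeledPointCloud(
            points=np.array(
                [
                    [1.0, 1.0, 1.0],
                    [1.0, -1.0, -1.0],
                    [-1.0, 1.0, -1.0],
                    [-1.0, -1.0, 1.0],
                ]
            )
            / np.sqrt(8.0),  # unit edge length
            labels=np.ones(4),
        ),
    }
    return clouds
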