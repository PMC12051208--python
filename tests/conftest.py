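"""Shared fixtures: text PDB/STRIDE fixtures and synthetic proteins."""

import numpy as np
import pytest
from hypothesis import settings

import pslflex as pf

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def atom_line(
    serial,
    name,
    resname,
    chain,
    resseq,
    x,
    y,
    z,
    occ=1.0,
    b=0.0,
    element="C",
    altloc=" ",
    record="ATOM",
    icode=" ",
):
    """Format one fixed-column PDB coordinate line."""
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field:4s}{altloc:1s}{resname:>3s} "
        f"{chain:1s}{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


THREE_RESIDUE_PDB = "\n".join(
    [
        "REMARK   2 RESOLUTION.    1.70 ANGSTROMS.",
        "REMARK   3   R VALUE            (WORKING SET) : 0.190",
        atom_line(1, "N", "ALA", "A", 1, 0.0, 1.0, 0.0, b=9.0, element="N"),
        atom_line(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, b=10.0),
        atom_line(3, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0, b=20.0),
        atom_line(4, "CA", "SER", "A", 3, 7.6, 0.5, 0.0, b=30.0),
        atom_line(5, "O", "SER", "A", 3, 8.0, 1.5, 0.5, b=12.0, element="O"),
        "END",
    ]
)


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB + "\n")
    return path


@pytest.fixture
def clouds():
    return pf.fixture_clouds()


def structure_from_points(points, b_factors=None):
    """Wrap bare C-alpha coordinates in a ProteinStructure."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    b = np.zeros(len(points)) if b_factors is None else np.asarray(b_factors)
    atoms = [
        pf.AtomRecord(
            serial=i + 1,
            name="CA",
            residue_name="ALA",
            chain_id="A",
            residue_seq=i + 1,
            insertion_code="",
            coordinates=p,
            occupancy=1.0,
            b_factor=float(b[i]),
            element="C",
        )
        for i, p in enumerate(points)
    ]
    return pf.ProteinStructure(
        id="FIX",
        calpha=atoms,
        heavy_atoms=list(atoms),
        global_features=pf.GlobalFeatures(n_heavy_atoms=len(atoms)),
    )


@pytest.fixture(scope="session")
def coil_protein():
    """A 40-residue zero-noise coil with B-factors linear in the PSL features."""
    return pf.synth_structure(
        pf.SyntheticSpec(n_residues=40, geometry="coil", noise_sigma=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def blind_tables():
    """Eight-protein blind dataset with within-protein target structure."""
    tables, proteins = pf.synth_blind_dataset(
        8,
        n_residues=25,
        seed=42,
        coeff_jitter=0.8,
        intercept_sd=15.0,
        noise_sigma=2.0,
    )
    return tables, proteins


@pytest.fixture(scope="session")
def fast_gbdt():
    """Scaled-down GBDT configuration for cross-validation tests."""
    return pf.ModelConfig(
        "GBDT", {"n_estimators": 60, "max_depth": 3, "learning_rate": 0.15}
    )
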