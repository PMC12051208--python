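"""Per-protein B-factor fitting, evaluation metrics, and the GNM baseline.

The per-protein model regresses the experimental C-alpha B-factors on the
15 PSL spectral features by ordinary least squares (with intercept); the
reported quantity is the Pearson correlation between fitted and
experimental values, averaged over proteins without weighting.

The Gaussian network model baseline builds the Kirchhoff (contact)
matrix at a 7 A cutoff, takes the diagonal of its Moore-Penrose
pseudoinverse as the raw flexibility profile, and calibrates it to the
experimental B-factors with a least-squares slope and intercept (Pearson
correlation is calibration-invariant; the RMSE requires the calibration).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import PslflexError
from .featurize import PslConfig, psl_features
from .sheaf_spectra import ZERO_EIG_RTOL
from .structure_io import ProteinStructure

logger = logging.getLogger(__name__)

#: default GNM contact cutoff in angstroms
GNM_CUTOFF = 7.0

#: minimum residue count for a plain OLS fit of 15 features + intercept
MIN_OLS_RESIDUES = 17


def pearson_cc(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Pearson correlation coefficient between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("inputs must be equal-length with at least 2 entries")
    dp = pred - pred.mean()
    do = obs - obs.mean()
    var_p, var_o = float(dp @ dp), float(do @ do)
    # relative guard: numerically-constant vectors count as zero variance
    if var_p <= 1e-24 * max(1.0, float(pred @ pred)) or var_o <= 1e-24 * max(
        1.0, float(obs @ obs)
    ):
        raise PslflexError("undefined correlation: zero variance input")
    return float((dp @ do) / np.sqrt(var_p * var_o))


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root-mean-square error."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 1:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


@dataclass
class FitResult:
    """Per-protein OLS fit: coefficients (features + intercept last),
    in-sample fitted B-factors, and fit quality."""

    coefficients: np.ndarray
    fitted_b: np.ndarray
    pcc: float
    rmse: float


def fit_protein(features: np.ndarray, b_exp: Sequence[float]) -> FitResult:
    """Ordinary least squares of experimental B-factors on PSL features.

    In-sample fitted values, as is conventional for per-protein flexibility
    comparisons. Rank-deficient designs are solved by minimum-norm least
    squares; proteins with fewer residues than features fall back to a tiny
    ridge penalty with a warning.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    b_exp = np.asarray(b_exp, dtype=float)
    if features.shape[0] != b_exp.size:
        raise ValueError("feature rows must match target length")
    if not np.all(np.isfinite(features)) or not np.all(np.isfinite(b_exp)):
        raise ValueError("non-finite inputs")
    design = np.hstack([features, np.ones((features.shape[0], 1))])
    if b_exp.size >= MIN_OLS_RESIDUES:
        coef, *_ = np.linalg.lstsq(design, b_exp, rcond=None)
    else:
        warnings.warn(
            f"only {b_exp.size} residues; using ridge fallback", stacklevel=2
        )
        penalty = 1e-8 * np.eye(design.shape[1])
        coef = np.linalg.solve(design.T @ design + penalty, design.T @ b_exp)
    fitted = design @ coef
    return FitResult(
        coefficients=coef,
        fitted_b=fitted,
        pcc=pearson_cc(fitted, b_exp),
        rmse=rmse(fitted, b_exp),
    )


@dataclass
class GnmResult:
    """GNM flexibility profile and its calibrated B-factor prediction."""

    kirchhoff: np.ndarray
    raw_profile: np.ndarray
    fitted_b: np.ndarray
    pcc: float
    rmse: float


def kirchhoff_matrix(coords: np.ndarray, cutoff: float = GNM_CUTOFF) -> np.ndarray:
    """GNM contact matrix: -1 for pairs within the cutoff, row sums zero."""
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    gamma = -((dist > 0) & (dist <= cutoff)).astype(float)
    np.fill_diagonal(gamma, 0.0)
    np.fill_diagonal(gamma, -gamma.sum(axis=1))
    return gamma


def gnm_bfactors(structure: ProteinStructure, cutoff: float = GNM_CUTOFF) -> GnmResult:
    """GNM B-factor prediction from the pseudoinverse of the Kirchhoff matrix.

    Zero modes are dropped at the relative spectral tolerance; a
    disconnected contact graph (more than one zero mode) proceeds with a
    warning.
    """
    coords = structure.ca_coordinates
    if len(coords) < 3:
        raise PslflexError("GNM needs at least 3 C-alpha atoms")
    gamma = kirchhoff_matrix(coords, cutoff)
    eigvals, eigvecs = np.linalg.eigh(gamma)
    tol = ZERO_EIG_RTOL * max(1.0, float(eigvals[-1]))
    nonzero = eigvals >= tol
    n_zero = int((~nonzero).sum())
    if n_zero != 1:
        warnings.warn(
            f"contact graph has {n_zero} zero modes (disconnected or empty)",
            stacklevel=2,
        )
    if nonzero.any():
        raw = np.einsum(
            "ik,k,ik->i", eigvecs[:, nonzero], 1.0 / eigvals[nonzero], eigvecs[:, nonzero]
        )
    else:
        raw = np.zeros(len(coords))
    b_exp = structure.b_factors
    design = np.stack([raw, np.ones_like(raw)], axis=1)
    slope_intercept, *_ = np.linalg.lstsq(design, b_exp, rcond=None)
    fitted = design @ slope_intercept
    try:
        pcc = pearson_cc(fitted, b_exp)
    except PslflexError:
        pcc = float("nan")
    return GnmResult(
        kirchhoff=gamma,
        raw_profile=raw,
        fitted_b=fitted,
        pcc=pcc,
        rmse=rmse(fitted, b_exp),
    )


@dataclass
class DatasetEvaluation:
    """Per-protein metrics plus the unweighted mean Pearson correlation."""

    per_protein: list[dict] = field(default_factory=list)
    mean_pcc: float = float("nan")
    excluded: list[str] = field(default_factory=list)


def evaluate_dataset(
    structures: Sequence[ProteinStructure],
    psl_config: Optional[PslConfig] = None,
    model: str = "psl",
    gnm_cutoff: float = GNM_CUTOFF,
) -> DatasetEvaluation:
    """Per-protein PCC/RMSE for the PSL regression or the GNM baseline.

    Per-protein failures are logged and excluded from the unweighted mean.
    """
    if model not in ("psl", "gnm"):
        raise ValueError("model must be 'psl' or 'gnm'")
    if not structures:
        raise ValueError("empty structure list")
    config = psl_config or PslConfig.regression()
    result = DatasetEvaluation()
    for structure in structures:
        try:
            if model == "psl":
                fit = fit_protein(psl_features(structure, config), structure.b_factors)
                pcc, err = fit.pcc, fit.rmse
            else:
                gnm = gnm_bfactors(structure, cutoff=gnm_cutoff)
                pcc, err = gnm.pcc, gnm.rmse
            if not np.isfinite(pcc):
                raise PslflexError("non-finite correlation")
        except (PslflexError, ValueError) as exc:
            logger.warning("%s: excluded from evaluation (%s)", structure.id, exc)
            result.excluded.append(structure.id)
            continue
        result.per_protein.append(
            {
                "protein_id": structure.id,
                "n_residues": len(structure.calpha),
                "pcc": pcc,
                "rmse": err,
            }
        )
    if result.per_protein:
        result.mean_pcc = float(np.mean([p["pcc"] for p in result.per_protein]))
    return result
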