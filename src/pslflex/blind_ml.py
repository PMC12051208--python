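"""Blind B-factor prediction with tree-ensemble regressors.

Feature tables from many proteins are pooled into one design matrix and a
gradient-boosted decision tree (GBDT) or random forest (RF) regressor is
trained to predict B-factors of proteins it has never seen. Three
validation protocols are provided:

* leave-one-protein-out,
* protein-level k-fold (entire proteins held out together), and
* C-alpha-level k-fold (rows split irrespective of protein identity).

The last protocol leaks within-protein correlation between train and test
rows, which is why its correlations are structurally higher than the
protein-level ones — a directional effect worth measuring, not a bug in
either protocol.

Missing global metadata (R-value, resolution) is imputed with the mean of
the *training* rows of each split, never from test rows.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

from .errors import PslflexError

#: default hyperparameters of the two regressors. The RF leaf size is 1
#: (a fractional min_samples_leaf would degenerate every tree).
GBDT_DEFAULTS = {
    "n_estimators": 1000,
    "max_depth": 7,
    "min_samples_split": 5,
    "subsample": 0.8,
    "learning_rate": 0.002,
}
RF_DEFAULTS = {
    "n_estimators": 1000,
    "max_depth": 8,
    "min_samples_split": 4,
    "max_features": "sqrt",
    "min_samples_leaf": 1,
}

#: columns allowed to contain missing values, imputed per training split
IMPUTABLE_COLUMNS = ("r_value", "resolution")

#: identity columns that are never fed to the regressor
ID_COLUMNS = ("protein_id", "chain_id", "residue_seq")


def blind_exclusions() -> tuple:
    """PDB IDs excluded from the 364-protein superset for blind prediction
    (STRIDE failures, unphysical B-factors, STRIDE/PDB inconsistencies),
    leaving the 346-protein blind set."""
    text = (
        importlib.resources.files("pslflex")
        .joinpath("data/blind_exclusions.txt")
        .read_text()
    )
    return tuple(line.strip() for line in text.splitlines() if line.strip())


@dataclass
class ModelConfig:
    """Algorithm choice, hyperparameter overrides, and the random seed."""

    algorithm: str = "GBDT"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("GBDT", "RF"):
            raise ValueError("algorithm must be 'GBDT' or 'RF'")

    def resolved(self) -> dict:
        base = dict(GBDT_DEFAULTS if self.algorithm == "GBDT" else RF_DEFAULTS)
        base.update(self.hyperparameters)
        return base


@dataclass
class ValidationReport:
    """Seed-averaged cross-validation outcome.

    ``per_unit_pcc`` holds one seed-averaged correlation per evaluation
    unit (protein or fold); ``mean_pcc`` is the unweighted mean of the
    per-seed means.
    """

    protocol: str
    per_unit_pcc: list
    mean_pcc: float
    seeds_used: list
    n_excluded: int
    pooled_pcc: Optional[float] = None


def build_design_matrix(
    tables: Sequence[pd.DataFrame],
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Stack per-protein feature tables into (X, y, protein index).

    Missing values are retained (NaN) so each validation split can impute
    from its own training rows.
    """
    if not tables:
        raise ValueError("no feature tables")
    columns = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != columns:
            raise PslflexError("feature tables have mismatched columns")
    stacked = pd.concat(tables, ignore_index=True)
    y = stacked["b_factor"].to_numpy(dtype=float)
    groups = stacked["protein_id"].astype(str).to_numpy()
    X = stacked.drop(columns=list(ID_COLUMNS) + ["b_factor"])
    return X, y, groups


def impute_split(
    X_train: pd.DataFrame, X_test: Optional[pd.DataFrame] = None
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Fill missing metadata with the training-split mean (never test rows).

    A column that is entirely missing in the training rows falls back to 0.
    """
    X_train = X_train.copy()
    fill = {}
    for col in IMPUTABLE_COLUMNS:
        if col in X_train.columns:
            mean = X_train[col].mean()
            fill[col] = 0.0 if pd.isna(mean) else float(mean)
    X_train = X_train.fillna(fill)
    train = X_train.to_numpy(dtype=float)
    if X_test is None:
        return train, None
    test = X_test.fillna(fill).to_numpy(dtype=float)
    return train, test


def train_model(config: ModelConfig, X: np.ndarray, y: np.ndarray):
    """Fit the configured regressor; deterministic given (seed, X, y)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y) or len(y) < 10:
        raise ValueError("need matched X/y with at least 10 rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise PslflexError("non-finite entries in the design matrix or target")
    params = config.resolved()
    if config.algorithm == "GBDT":
        model = GradientBoostingRegressor(random_state=config.seed, **params)
    else:
        model = RandomForestRegressor(random_state=config.seed, **params)
    model.fit(X, y)
    return model


def _pcc(pred: np.ndarray, obs: np.ndarray) -> Optional[float]:
    """Pearson correlation, or None when either side has zero variance."""
    if len(pred) < 2 or np.std(pred) == 0.0 or np.std(obs) == 0.0:
        return None
    dp = pred - pred.mean()
    do = obs - obs.mean()
    return float((dp @ do) / np.sqrt((dp @ dp) * (do @ do)))


def loo_protein_validation(
    dataset: tuple,
    config: Optional[ModelConfig] = None,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> ValidationReport:
    """Leave-one-protein-out: train on all other proteins, score the held-out
    protein by Pearson correlation; average over proteins, then over seeds."""
    X, y, groups = dataset
    config = config or ModelConfig()
    proteins = list(dict.fromkeys(groups))
    if len(proteins) < 2:
        raise ValueError("leave-one-out needs at least 2 proteins")

    per_seed_means = []
    per_protein_across_seeds = {p: [] for p in proteins}
    n_excluded = 0
    for seed in seeds:
        seeded = ModelConfig(config.algorithm, dict(config.hyperparameters), seed)
        pccs = []
        for protein in proteins:
            test_mask = groups == protein
            if np.std(y[test_mask]) == 0.0:
                n_excluded += 1
                continue
            Xtr, Xte = impute_split(X[~test_mask], X[test_mask])
            model = train_model(seeded, Xtr, y[~test_mask])
            pcc = _pcc(model.predict(Xte), y[test_mask])
            if pcc is None:
                n_excluded += 1
                continue
            pccs.append(pcc)
            per_protein_across_seeds[protein].append(pcc)
        per_seed_means.append(float(np.mean(pccs)))
    per_unit = [
        float(np.mean(v)) for v in per_protein_across_seeds.values() if v
    ]
    return ValidationReport(
        protocol="loo",
        per_unit_pcc=per_unit,
        mean_pcc=float(np.mean(per_seed_means)),
        seeds_used=list(seeds),
        n_excluded=n_excluded,
    )


def kfold_protein_validation(
    dataset: tuple,
    k: int = 10,
    config: Optional[ModelConfig] = None,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> ValidationReport:
    """Protein-level k-fold: proteins are partitioned into folds (seeded
    shuffle); each test protein is scored individually; averaged over
    proteins, then over seeds."""
    X, y, groups = dataset
    config = config or ModelConfig()
    proteins = np.array(list(dict.fromkeys(groups)))
    if k > len(proteins):
        raise ValueError(f"k={k} exceeds protein count {len(proteins)}")

    per_seed_means = []
    all_unit_pccs = []
    n_excluded = 0
    for seed in seeds:
        seeded = ModelConfig(config.algorithm, dict(config.hyperparameters), seed)
        order = np.random.default_rng(seed).permutation(len(proteins))
        folds = np.array_split(proteins[order], k)
        pccs = []
        for fold in folds:
            test_mask = np.isin(groups, fold)
            Xtr, Xte = impute_split(X[~test_mask], X[test_mask])
            model = train_model(seeded, Xtr, y[~test_mask])
            pred = model.predict(Xte)
            for protein in fold:
                sub = groups[test_mask] == protein
                pcc = _pcc(pred[sub], y[test_mask][sub])
                if pcc is None:
                    n_excluded += 1
                    continue
                pccs.append(pcc)
        per_seed_means.append(float(np.mean(pccs)))
        all_unit_pccs.extend(pccs)
    return ValidationReport(
        protocol="kfold_protein",
        per_unit_pcc=all_unit_pccs,
        mean_pcc=float(np.mean(per_seed_means)),
        seeds_used=list(seeds),
        n_excluded=n_excluded,
    )


def kfold_atom_validation(
    dataset: tuple,
    k: int = 10,
    config: Optional[ModelConfig] = None,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> ValidationReport:
    """C-alpha-level k-fold: rows split ignoring protein boundaries.

    The Pearson correlation is computed on the pooled test predictions of
    each fold, averaged over folds, then over seeds; the correlation pooled
    over all folds is additionally reported.
    """
    X, y, groups = dataset
    config = config or ModelConfig()
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds row count {n}")

    per_seed_means = []
    all_fold_pccs = []
    n_excluded = 0
    pooled_pred = np.zeros(n)
    for seed in seeds:
        seeded = ModelConfig(config.algorithm, dict(config.hyperparameters), seed)
        order = np.random.default_rng(seed).permutation(n)
        folds = np.array_split(order, k)
        pccs = []
        for fold in folds:
            test_mask = np.zeros(n, dtype=bool)
            test_mask[fold] = True
            Xtr, Xte = impute_split(X[~test_mask], X[test_mask])
            model = train_model(seeded, Xtr, y[~test_mask])
            pred = model.predict(Xte)  # rows in ascending original order
            pooled_pred[test_mask] = pred
            pcc = _pcc(pred, y[test_mask])
            if pcc is None:
                n_excluded += 1
                continue
            pccs.append(pcc)
        per_seed_means.append(float(np.mean(pccs)))
        all_fold_pccs.extend(pccs)
    pooled = _pcc(pooled_pred, y)  # predictions of the last seed
    return ValidationReport(
        protocol="kfold_atom",
        per_unit_pcc=all_fold_pccs,
        mean_pcc=float(np.mean(per_seed_means)),
        seeds_used=list(seeds),
        n_excluded=n_excluded,
        pooled_pcc=pooled,
    )
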