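"""Reproduce the published benchmark numbers from locally stored PDB files.

Given a directory of PDB files (and optionally STRIDE output files named
<id>.stride), this script computes:

* the per-protein PSL correlation (L0 spectra at radii 6/9/12 A, median
  statistic, per-protein ordinary least squares) and its unweighted mean
  over the set — the Table-1-style average;
* the GNM baseline (7 A cutoff) correlation and RMSE per protein, and the
  percentage improvement of the PSL average over the GNM average;
* optionally, blind cross-validated GBDT/RF predictions with the full
  published hyperparameters (only when STRIDE files are present).

No data is downloaded: protein structures must be fetched beforehand,
e.g. from the RCSB PDB, and STRIDE output generated with the stride tool.

Example:
    python scripts/reproduce_benchmark.py --pdb-dir pdbs/ --out table1.csv
    python scripts/reproduce_benchmark.py --pdb-dir pdbs/ --stride-dir strides/ \
        --blind loo --out blind.json
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import pslflex as pf


def per_protein_metrics(pdb_paths, gnm_cutoff=7.0):
    rows = []
    for path in pdb_paths:
        try:
            structure = pf.parse_pdb(path)
            fit = pf.fit_protein(
                pf.psl_features(structure, pf.PslConfig.regression()),
                structure.b_factors,
            )
            gnm = pf.gnm_bfactors(structure, cutoff=gnm_cutoff)
        except pf.PslflexError as exc:
            print(f"excluded {path.stem}: {exc}", file=sys.stderr)
            continue
        rows.append(
            {
                "protein_id": path.stem.upper(),
                "n_residues": len(structure.calpha),
                "psl_pcc": fit.pcc,
                "psl_rmse": fit.rmse,
                "gnm_pcc": gnm.pcc,
                "gnm_rmse": gnm.rmse,
            }
        )
    return pd.DataFrame(rows)


def blind_validation(pdb_paths, stride_dir, protocol, algorithm, seeds):
    excluded = set(pf.blind_exclusions())
    tables = []
    for path in pdb_paths:
        pid = path.stem.upper()
        if pid in excluded:
            print(f"excluded {pid}: on the blind-set exclusion list", file=sys.stderr)
            continue
        stride_path = Path(stride_dir) / f"{path.stem}.stride"
        if not stride_path.exists():
            print(f"excluded {pid}: no STRIDE file", file=sys.stderr)
            continue
        structure = pf.parse_pdb(path)
        records = pf.parse_stride(stride_path)
        join = pf.join_stride(structure, records)
        if join.flagged:
            print(f"excluded {pid}: STRIDE/PDB mismatch", file=sys.stderr)
            continue
        if np.std(structure.b_factors) == 0.0:
            print(f"excluded {pid}: unphysical B-factors", file=sys.stderr)
            continue
        tables.append(
            pf.assemble_feature_table(structure, records, pf.PslConfig.blind())
        )
    dataset = pf.build_design_matrix(tables)
    config = pf.ModelConfig(algorithm)
    if protocol == "loo":
        return pf.loo_protein_validation(dataset, config, seeds)
    if protocol == "kfold-protein":
        return pf.kfold_protein_validation(dataset, 10, config, seeds)
    return pf.kfold_atom_validation(dataset, 10, config, seeds)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pdb-dir", type=Path, required=True)
    parser.add_argument("--stride-dir", type=Path, default=None)
    parser.add_argument("--gnm-cutoff", type=float, default=7.0)
    parser.add_argument(
        "--blind", choices=["loo", "kfold-protein", "kfold-atom"], default=None
    )
    parser.add_argument("--algo", choices=["GBDT", "RF"], default="GBDT")
    parser.add_argument("--seeds", default="0,1,2,3,4")
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    pdb_paths = sorted(
        list(args.pdb_dir.glob("*.pdb")) + list(args.pdb_dir.glob("*.ent"))
    )
    if not pdb_paths:
        sys.exit(f"no PDB files in {args.pdb_dir}")

    if args.blind:
        if args.stride_dir is None:
            sys.exit("--blind requires --stride-dir")
        seeds = [int(s) for s in args.seeds.split(",")]
        report = blind_validation(
            pdb_paths, args.stride_dir, args.blind, args.algo, seeds
        )
        print(f"{report.protocol} ({args.algo}) mean PCC: {report.mean_pcc:.3f}")
        if args.out:
            with open(args.out, "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "protocol": report.protocol,
                        "algorithm": args.algo,
                        "mean_pcc": report.mean_pcc,
                        "pooled_pcc": report.pooled_pcc,
                        "n_excluded": report.n_excluded,
                        "seeds": seeds,
                    },
                    fh,
                    indent=2,
                )
        return

    table = per_protein_metrics(pdb_paths, args.gnm_cutoff)
    psl_avg = table["psl_pcc"].mean()
    gnm_avg = table["gnm_pcc"].mean()
    print(f"proteins evaluated:  {len(table)}")
    print(f"PSL average PCC:     {psl_avg:.3f}")
    print(f"GNM average PCC:     {gnm_avg:.3f}")
    print(f"PSL over GNM:        {100.0 * (psl_avg - gnm_avg) / abs(gnm_avg):.1f}%")
    for pid in ("1CLL", "2HQK", "1V70", "1WHI"):
        row = table[table["protein_id"] == pid]
        if len(row):
            print(
                f"{pid}: PSL RMSE {row.psl_rmse.iloc[0]:.2f}  "
                f"GNM RMSE {row.gnm_rmse.iloc[0]:.2f}"
            )
    if args.out:
        table.to_csv(args.out, index=False)


if __name__ == "__main__":
    main()
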