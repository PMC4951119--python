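#!/usr/bin/env python
"""Trace cross-individual IFS accuracy curves and locate inflection points.

For every training individual, classifiers are trained on growing prefixes of
its mRMR list (from 02_rank_features.py) and scored on the other five
individuals.  Writes all 30 curves and the inflection table under
results/ifs/, and prints, per curve, the selected k, its accuracy, and the
max-accuracy point for comparison.
"""

import argparse
from pathlib import Path

from brainmarkers.io import (
    read_expression_dataset,
    read_feature_list,
    write_curve,
    write_inflections,
)
from brainmarkers.ifs import find_inflection_point, max_accuracy_point, run_ifs
from brainmarkers.simulate import DEFAULT_INDIVIDUALS

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "data")
    parser.add_argument("--rank-dir", type=Path,
                        default=ROOT / "results" / "rankings")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "ifs")
    parser.add_argument("--k-min", type=int, default=4)
    parser.add_argument("--k-max", type=int, default=50)
    args = parser.parse_args()

    datasets = {
        ind: read_expression_dataset(
            args.data_dir / f"{ind}.matrix.tsv",
            args.data_dir / f"{ind}.annotation.tsv",
            ind,
        )
        for ind in DEFAULT_INDIVIDUALS
    }
    args.out_dir.mkdir(parents=True, exist_ok=True)

    records = []
    print("train\ttest\tinflection_k\tacc_at_k\tmax_acc_k\tmax_acc\tfallback")
    for ind, training in datasets.items():
        flist = read_feature_list(args.rank_dir / f"{ind}.mrmr.tsv")
        tests = [d for i, d in datasets.items() if i != ind]
        curves = run_ifs(training, tests, flist, n_max=len(flist))
        for curve in curves:
            write_curve(
                curve,
                args.out_dir
                / f"curve.{curve.training_individual}.vs.{curve.test_individual}.tsv",
            )
            pt = find_inflection_point(
                curve, k_min=args.k_min, k_max=min(args.k_max, len(curve) - 1)
            )
            mk, macc = max_accuracy_point(curve)
            records.append((curve.training_individual, curve.test_individual, pt))
            print(
                f"{curve.training_individual}\t{curve.test_individual}\t{pt.k}"
                f"\t{float(pt.total_accuracy):.4f}\t{mk}\t{float(macc):.4f}"
                f"\t{int(pt.fallback_used)}"
            )
    write_inflections(records, args.out_dir / "inflection_points.tsv")
    print(f"curves and inflection table written to {args.out_dir}")


if __name__ == "__main__":
    main()
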