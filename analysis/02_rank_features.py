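#!/usr/bin/env python
"""Rank genes per individual: MaxRel (relevance only) and mRMR lists.

Reads the cohort written by 01_simulate.py, discretizes each individual's
matrix to three states (mean +- 1 sd), and writes both feature lists per
individual under results/rankings/.  Reports how many planted markers reach
the top of each list.
"""

import argparse
from pathlib import Path

from brainmarkers.io import read_expression_dataset, write_feature_list
from brainmarkers.mrmr import discretize, maxrel_ranking, mrmr_ranking
from brainmarkers.simulate import DEFAULT_INDIVIDUALS

ROOT = Path(__file__).resolve().parent.parent


def read_truth(path: Path) -> set[str]:
    genes = set()
    for line in path.read_text(encoding="utf-8").splitlines()[1:]:
        genes.add(line.split("\t")[0])
    return genes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "data")
    parser.add_argument("--out-dir", type=Path,
                        default=ROOT / "results" / "rankings")
    parser.add_argument("--n", type=int, default=64,
                        help="list length; the inflection range never uses >51")
    parser.add_argument("--criterion", default="difference",
                        choices=["difference", "quotient"])
    args = parser.parse_args()

    planted = read_truth(args.data_dir / "ground_truth.tsv")
    args.out_dir.mkdir(parents=True, exist_ok=True)
    print("individual\tplanted_in_top30_maxrel\tplanted_in_top30_mrmr")
    for ind in DEFAULT_INDIVIDUALS:
        ds = read_expression_dataset(
            args.data_dir / f"{ind}.matrix.tsv",
            args.data_dir / f"{ind}.annotation.tsv",
            ind,
        )
        disc = discretize(ds)
        maxrel = maxrel_ranking(disc, args.n)
        mrmr = mrmr_ranking(disc, args.n, criterion=args.criterion)
        write_feature_list(maxrel, args.out_dir / f"{ind}.maxrel.tsv")
        write_feature_list(mrmr, args.out_dir / f"{ind}.mrmr.tsv")
        hit_maxrel = len(planted & set(maxrel.prefix(30)))
        hit_mrmr = len(planted & set(mrmr.prefix(30)))
        print(f"{ind}\t{hit_maxrel}/{len(planted)}\t{hit_mrmr}/{len(planted)}")
    print(f"lists written to {args.out_dir}")


if __name__ == "__main__":
    main()
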