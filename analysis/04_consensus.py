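#!/usr/bin/env python
"""Intersect inflection prefixes per training individual and build the
cross-individual consensus gene table.

Reads the mRMR lists (02) and inflection table (03), forms each training
individual's important-feature set (the shortest inflection prefix), counts
per-gene frequencies across the six sets, writes results/consensus.tsv, and
compares the consensus against the planted ground truth.
"""

import argparse
import csv
from fractions import Fraction
from pathlib import Path

from brainmarkers.ifs import InflectionPoint, consensus_frequency, important_features
from brainmarkers.io import read_feature_list, write_consensus
from brainmarkers.simulate import DEFAULT_INDIVIDUALS

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "data")
    parser.add_argument("--rank-dir", type=Path,
                        default=ROOT / "results" / "rankings")
    parser.add_argument("--ifs-dir", type=Path, default=ROOT / "results" / "ifs")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "consensus.tsv")
    args = parser.parse_args()

    inflections: dict[str, list[InflectionPoint]] = {}
    with open(args.ifs_dir / "inflection_points.tsv", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            inflections.setdefault(row["train"], []).append(
                InflectionPoint(
                    k=int(row["k"]),
                    total_accuracy=Fraction(float(row["total_acc"])),
                    fallback_used=bool(int(row["fallback"])),
                )
            )

    important = []
    for ind in DEFAULT_INDIVIDUALS:
        flist = read_feature_list(args.rank_dir / f"{ind}.mrmr.tsv")
        genes = important_features(flist, inflections[ind])
        important.append((ind, genes))
        print(f"{ind}: important set of {len(genes)} genes "
              f"(min inflection k = {min(p.k for p in inflections[ind])})")

    table = consensus_frequency(important)
    write_consensus(table, args.out)

    truth_path = args.data_dir / "ground_truth.tsv"
    planted = {
        line.split("\t")[0]
        for line in truth_path.read_text(encoding="utf-8").splitlines()[1:]
    }
    print(f"\nconsensus table: {len(table.rows)} genes -> {args.out}")
    print("gene_id\tfrequency\tplanted")
    for row in table.rows:
        print(f"{row.gene_id}\t{row.frequency}\t{'yes' if row.gene_id in planted else 'NO'}")
    unplanted = sum(1 for r in table.rows if r.gene_id not in planted)
    print(f"\n{len(table.rows) - unplanted} of {len(table.rows)} consensus genes "
          f"are planted markers; {unplanted} are background genes")


if __name__ == "__main__":
    main()
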