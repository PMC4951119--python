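"""Readers and writers for the pipeline's tab-separated file formats.

All files are TSV, UTF-8, ``.`` decimal separator, no quoting:

* expression matrix — header ``gene_id<TAB><sample ids...>``, one row per gene;
* sample annotation — header ``sample_id<TAB>individual_id<TAB>region``;
* feature list     — header ``rank<TAB>gene_id<TAB>score``;
* IFS curve        — header ``k<TAB>total_acc<TAB>acc_BS<TAB>acc_CB<TAB>acc_CC``;
* inflection table — header ``train<TAB>test<TAB>k<TAB>total_acc<TAB>fallback``;
* consensus table  — header ``gene_id<TAB>frequency<TAB>training_ids``.

Scores survive a write/read round trip to 12 significant digits.
"""

from __future__ import annotations

import csv
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    REGIONS,
    ConsistencyError,
    ExpressionDataset,
    FeatureList,
    FormatError,
)

_FLOAT_FMT = "%.12g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# expression matrices and annotations
# ---------------------------------------------------------------------------

def read_expression_dataset(
    matrix_path: str | Path,
    annotation_path: str | Path,
    individual_id: str,
) -> ExpressionDataset:
    """Load one individual's validated dataset from matrix + annotation TSVs.

    The annotation file may cover several individuals; only rows whose
    ``individual_id`` matches are used, and the dataset's columns follow the
    annotation file's row order.  The matrix must contain exactly those
    samples.
    """
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    expected = {"sample_id", "individual_id", "region"}
    if not expected.issubset(ann.columns):
        raise FormatError(
            f"annotation file must have columns {sorted(expected)}, "
            f"found {list(ann.columns)}"
        )
    ann = ann[ann["individual_id"] == individual_id]
    for _, row in ann.iterrows():
        if row["region"] not in REGIONS:
            raise FormatError(
                f"unknown region label {row['region']!r} for sample "
                f"{row['sample_id']!r}"
            )

    mat = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if mat.columns[0] != "gene_id":
        raise FormatError("matrix file must start with a 'gene_id' column")
    gene_ids = mat["gene_id"].tolist()
    matrix_samples = list(mat.columns[1:])

    ann_samples = ann["sample_id"].tolist()
    missing_in_matrix = [s for s in ann_samples if s not in set(matrix_samples)]
    if missing_in_matrix:
        raise ConsistencyError(
            f"annotated sample {missing_in_matrix[0]!r} of individual "
            f"{individual_id!r} is missing from the matrix"
        )
    extra_in_matrix = [s for s in matrix_samples if s not in set(ann_samples)]
    if extra_in_matrix:
        raise ConsistencyError(
            f"matrix sample {extra_in_matrix[0]!r} has no annotation row for "
            f"individual {individual_id!r}"
        )

    raw = mat[ann_samples]  # annotation order
    values = np.empty((len(gene_ids), len(ann_samples)), dtype=float)
    for j, col in enumerate(ann_samples):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = np.nonzero(converted.isna().to_numpy() & raw[col].notna().to_numpy())[0]
        if bad.size:
            i = int(bad[0])
            raise FormatError(
                f"non-numeric value {raw[col].iloc[i]!r} at gene "
                f"{gene_ids[i]!r} (row {i + 2}), sample {col!r}"
            )
        if converted.isna().any():
            i = int(np.nonzero(converted.isna().to_numpy())[0][0])
            raise FormatError(
                f"empty cell at gene {gene_ids[i]!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)

    return ExpressionDataset(
        individual_id=individual_id,
        gene_ids=gene_ids,
        sample_ids=ann_samples,
        values=values,
        region_labels=ann["region"].tolist(),
    )


def write_expression_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    annotation_path: str | Path,
    append_annotation: bool = False,
) -> None:
    """Write the matrix and annotation TSVs for one individual."""
    with open(matrix_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", *dataset.sample_ids])
        for i, g in enumerate(dataset.gene_ids):
            w.writerow([g, *(_fmt(v) for v in dataset.values[i])])
    mode = "a" if append_annotation else "w"
    write_header = not (append_annotation and Path(annotation_path).exists()
                        and Path(annotation_path).stat().st_size > 0)
    with open(annotation_path, mode, encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if write_header:
            w.writerow(["sample_id", "individual_id", "region"])
        for s, r in zip(dataset.sample_ids, dataset.region_labels):
            w.writerow([s, dataset.individual_id, r])


# ---------------------------------------------------------------------------
# feature lists
# ---------------------------------------------------------------------------

def write_feature_list(feature_list: FeatureList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["rank", "gene_id", "score"])
        for rank, (gene, score) in enumerate(feature_list.entries, start=1):
            w.writerow([rank, gene, _fmt(score)])


def read_feature_list(path: str | Path, flavor: str = "mRMR") -> FeatureList:
    entries: list[tuple[str, float]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["rank", "gene_id", "score"]:
            raise FormatError(f"bad feature-list header {header!r} in {path}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise FormatError(f"line {lineno} of {path}: expected 3 columns")
            rank_s, gene, score_s = row
            if int(rank_s) != lineno - 1:
                raise FormatError(f"line {lineno} of {path}: rank out of order")
            if gene in seen:
                raise FormatError(f"duplicate gene {gene!r} in {path}")
            seen.add(gene)
            entries.append((gene, float(score_s)))
    return FeatureList(flavor=flavor, entries=entries)


# ---------------------------------------------------------------------------
# IFS curves, inflection points, consensus tables
# ---------------------------------------------------------------------------

def write_curve(curve, path: str | Path) -> None:
    """Write one (train, test) accuracy curve; NA for empty classes."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["k", "total_acc", "acc_BS", "acc_CB", "acc_CC"])
        for pt in curve.points:
            row = [pt.k, _fmt(pt.total)]
            for r in REGIONS:
                acc = pt.per_class.get(r)
                row.append("NA" if acc is None else _fmt(acc))
            w.writerow(row)


def read_curve(path: str | Path, training_individual: str = "",
               test_individual: str = ""):
    from .ifs import CurvePoint, IFSCurve  # local import to avoid a cycle

    points = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["k", "total_acc", "acc_BS", "acc_CB", "acc_CC"]:
            raise FormatError(f"bad curve header {header!r} in {path}")
        for row in reader:
            k = int(row[0])
            total = Fraction(row[1]) if "/" in row[1] else Fraction(float(row[1]))
            per_class = {}
            for r, cell in zip(REGIONS, row[2:5]):
                per_class[r] = None if cell == "NA" else Fraction(float(cell))
            points.append(CurvePoint(k=k, total=total, per_class=per_class))
    return IFSCurve(training_individual=training_individual,
                    test_individual=test_individual, points=points)


def write_inflections(records: Iterable[tuple], path: str | Path) -> None:
    """``records``: iterable of (train, test, InflectionPoint)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["train", "test", "k", "total_acc", "fallback"])
        for train, test, pt in records:
            w.writerow([train, test, pt.k, _fmt(pt.total_accuracy),
                        int(pt.fallback_used)])


def write_consensus(table, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "frequency", "training_ids"])
        for row in table.rows:
            w.writerow([row.gene_id, row.frequency, ",".join(row.contributors)])


def read_consensus(path: str | Path):
    from .ifs import ConsensusGeneTable, ConsensusRow

    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["gene_id", "frequency", "training_ids"]:
            raise FormatError(f"bad consensus header {header!r} in {path}")
        for gene, freq, ids in reader:
            rows.append(ConsensusRow(gene_id=gene, frequency=int(freq),
                                     contributors=tuple(ids.split(","))))
    return ConsensusGeneTable(rows=rows)
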