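"""Revised incremental feature selection across individuals.

The classical IFS procedure evaluates classifiers on growing prefixes
``F_1 ⊂ F_2 ⊂ ... ⊂ F_N`` of a ranked feature list, all within one dataset.
The revised variant trains on one individual's samples and evaluates every
prefix on the *other* individuals, yielding one accuracy-vs-k curve per
(training, test) pair; robust region markers are then distilled by

1. picking an inflection point on each curve — the first k whose accuracy is
   >= its predecessor's and > its successor's;
2. intersecting the prefix sets at the chosen k's for one training
   individual (prefixes are nested, so this equals the shortest prefix);
3. counting, across training individuals, how often each gene appears in the
   intersected "important" sets (the consensus frequency).

Accuracy comparisons use exact rational counts (correct/total), so the
``>= / >`` inflection conditions are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .datamodel import REGIONS, ExpressionDataset, FeatureList
from .smo import ScoreResult, predict_multiclass, score_predictions, train_multiclass


@dataclass
class CurvePoint:
    """Accuracy at prefix length ``k``; values are exact fractions."""

    k: int
    total: Fraction
    per_class: "dict[str, Fraction | None]"


@dataclass
class IFSCurve:
    """Accuracy vs number of top features, for one (train, test) pair."""

    training_individual: str
    test_individual: str
    points: list[CurvePoint]

    def __post_init__(self) -> None:
        ks = [p.k for p in self.points]
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError("curve k values must be exactly 1..N")
        for p in self.points:
            if not 0 <= p.total <= 1:
                raise ValueError(f"accuracy {p.total} outside [0, 1] at k={p.k}")

    def __len__(self) -> int:
        return len(self.points)

    def accuracy(self, k: int) -> Fraction:
        return self.points[k - 1].total

    def total_accuracies(self) -> list[Fraction]:
        return [p.total for p in self.points]


@dataclass
class InflectionPoint:
    """The selected prefix length on a curve.

    ``fallback_used`` marks curves with no point satisfying the
    rise-then-drop condition, where the (smallest) argmax in the search range
    is reported instead.
    """

    k: int
    total_accuracy: Fraction
    fallback_used: bool


@dataclass
class ConsensusRow:
    gene_id: str
    frequency: int
    contributors: tuple[str, ...]


@dataclass
class ConsensusGeneTable:
    """Gene -> number of training individuals whose important set contains it,
    sorted by frequency descending then gene id ascending."""

    rows: list[ConsensusRow]

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.frequency != len(row.contributors):
                raise ValueError(
                    f"{row.gene_id}: frequency {row.frequency} != "
                    f"{len(row.contributors)} contributors"
                )
            if row.frequency < 1:
                raise ValueError("frequencies must be >= 1")
        keys = [(-r.frequency, r.gene_id) for r in self.rows]
        if keys != sorted(keys):
            raise ValueError("rows must be sorted by frequency desc, gene asc")

    def frequency_of(self, gene_id: str) -> int:
        for row in self.rows:
            if row.gene_id == gene_id:
                return row.frequency
        return 0

    def top(self, n: int) -> list[ConsensusRow]:
        return self.rows[:n]


def _score_to_point(k: int, score: ScoreResult) -> CurvePoint:
    per_class: dict[str, Fraction | None] = {}
    for r in REGIONS:
        correct, count = score.per_class[r]
        per_class[r] = None if count == 0 else Fraction(correct, count)
    return CurvePoint(
        k=k, total=Fraction(score.n_correct, score.n_total), per_class=per_class
    )


def run_ifs(
    training: ExpressionDataset,
    tests: Sequence[ExpressionDataset],
    mrmr_list: FeatureList,
    n_max: int,
    C: float = 1.0,
    tol: float = 1e-3,
) -> list[IFSCurve]:
    """Train on prefixes F_1..F_{n_max} of the ranked list and score each
    test individual, producing one curve per test dataset.

    The classifier consumes raw expression values (discretization is only an
    ingredient of the mutual-information ranking).  A ranked gene missing
    from any dataset raises an error naming the gene.
    """
    if n_max < 1 or n_max > len(mrmr_list):
        raise ValueError(
            f"n_max must be in [1, {len(mrmr_list)}] (list length)"
        )
    genes = mrmr_list.prefix(n_max)
    # restrict_genes validates presence and fixes the row order = list order
    Xtr_full = training.restrict_genes(genes).T  # samples x features
    ytr = np.asarray(training.region_labels, dtype=object)
    test_matrices = [(ds, ds.restrict_genes(genes).T) for ds in tests]

    curves_points: list[list[CurvePoint]] = [[] for _ in tests]
    for k in range(1, n_max + 1):
        model = train_multiclass(Xtr_full[:, :k], ytr, C=C, tol=tol)
        for t_idx, (ds, Xte) in enumerate(test_matrices):
            pred = predict_multiclass(model, Xte[:, :k])
            score = score_predictions(ds.region_labels, pred)
            curves_points[t_idx].append(_score_to_point(k, score))

    return [
        IFSCurve(
            training_individual=training.individual_id,
            test_individual=ds.individual_id,
            points=pts,
        )
        for (ds, _), pts in zip(test_matrices, curves_points)
    ]


def find_inflection_point(
    curve: IFSCurve, k_min: int = 4, k_max: int = 50
) -> InflectionPoint:
    """First k in [k_min, k_max] with acc(k) >= acc(k-1) and acc(k) > acc(k+1).

    If no such point exists, fall back to the smallest k attaining the
    maximum accuracy in the range, flagged via ``fallback_used``.
    """
    n = len(curve)
    if n < 3:
        raise ValueError("inflection search needs a curve of >= 3 points")
    if not (2 <= k_min <= k_max <= n - 1):
        raise ValueError(
            f"require 2 <= k_min <= k_max <= N-1 (N={n}); "
            f"got k_min={k_min}, k_max={k_max}"
        )
    acc = curve.total_accuracies()
    for k in range(k_min, k_max + 1):
        if acc[k - 1] >= acc[k - 2] and acc[k - 1] > acc[k]:
            return InflectionPoint(k=k, total_accuracy=acc[k - 1],
                                   fallback_used=False)
    window = acc[k_min - 1:k_max]
    best = max(window)
    k_best = k_min + window.index(best)
    return InflectionPoint(k=k_best, total_accuracy=best, fallback_used=True)


def max_accuracy_point(curve: IFSCurve) -> tuple[int, Fraction]:
    """Smallest k attaining the curve's maximum total accuracy."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    acc = curve.total_accuracies()
    best = max(acc)
    return acc.index(best) + 1, best


def important_features(
    mrmr_list: FeatureList, inflections: Sequence[InflectionPoint]
) -> set[str]:
    """Intersect the prefix sets at the given inflection points.

    Because the sets are nested prefixes of one list, the intersection equals
    the prefix of length min(k); both computations are performed and checked
    against each other.
    """
    if len(inflections) == 0:
        raise ValueError("at least one inflection point is required")
    prefix_sets = [set(mrmr_list.prefix(pt.k)) for pt in inflections]
    literal = set.intersection(*prefix_sets)
    shortest = set(mrmr_list.prefix(min(pt.k for pt in inflections)))
    assert literal == shortest, "nested-prefix law violated"
    return literal


def consensus_frequency(
    important_sets: Iterable[tuple[str, "set[str] | Sequence[str]"]],
) -> ConsensusGeneTable:
    """Count, per gene, the training individuals whose important set holds it."""
    sets = [(tid, set(genes)) for tid, genes in important_sets]
    ids = [tid for tid, _ in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("training ids must be distinct")
    contributors: dict[str, list[str]] = {}
    for tid, genes in sets:
        for g in genes:
            contributors.setdefault(g, []).append(tid)
    rows = [
        ConsensusRow(gene_id=g, frequency=len(tids), contributors=tuple(sorted(tids)))
        for g, tids in contributors.items()
    ]
    rows.sort(key=lambda r: (-r.frequency, r.gene_id))
    return ConsensusGeneTable(rows=rows)
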