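"""Core containers for expression cohorts and ranked gene lists.

The analysis operates on per-individual expression matrices (genes x samples)
whose samples each carry one of three brain-region labels: brain stem (BS),
cerebellum (CB) or cerebral cortex (CC).  Feature selection produces ordered
gene rankings whose prefixes form the nested feature sets used by incremental
feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: The three admissible sample classes, in canonical (tie-break) order.
REGIONS: tuple[str, str, str] = ("BS", "CB", "CC")


class FormatError(ValueError):
    """A file or label violates the expected format."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (matrix vs annotation, list vs data) do not."""


@dataclass
class ExpressionDataset:
    """One individual's expression matrix with per-sample region labels.

    Parameters
    ----------
    individual_id
        Donor identifier, e.g. ``"H0351.1009"``.
    gene_ids
        Ordered, unique gene identifiers (rows), length ``G``.
    sample_ids
        Ordered, unique sample identifiers (columns), length ``S``.
    values
        ``G x S`` float matrix of expression intensities (arbitrary units).
    region_labels
        Length-``S`` sequence of labels, each one of ``REGIONS``.
    """

    individual_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.region_labels = list(map(str, self.region_labels))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D matrix")
        g, s = self.values.shape
        if g != len(self.gene_ids) or s != len(self.sample_ids):
            raise ConsistencyError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.region_labels) != s:
            raise ConsistencyError("one region label per sample is required")
        if len(set(self.gene_ids)) != g:
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != s:
            raise FormatError("duplicate sample ids")
        bad = [l for l in self.region_labels if l not in REGIONS]
        if bad:
            raise FormatError(
                f"unknown region label {bad[0]!r} (admissible: {', '.join(REGIONS)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        """Map gene id -> row index."""
        return {g: i for i, g in enumerate(self.gene_ids)}

    def region_counts(self) -> dict[str, int]:
        """Sample tally per region, all three regions always present."""
        counts = {r: 0 for r in REGIONS}
        for l in self.region_labels:
            counts[l] += 1
        return counts

    def restrict_genes(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Return the ``len(gene_ids) x S`` sub-matrix in the given gene order.

        Raises :class:`ConsistencyError` naming the first missing gene.
        """
        index = self.gene_index()
        rows = []
        for g in gene_ids:
            if g not in index:
                raise ConsistencyError(
                    f"gene {g!r} absent from dataset {self.individual_id!r}"
                )
            rows.append(index[g])
        return self.values[rows, :]


@dataclass
class CohortSummary:
    """Per-individual, per-region sample counts (the cohort's design table)."""

    counts: dict[str, dict[str, int]]  # individual -> region -> count

    def __post_init__(self) -> None:
        for ind, per_region in self.counts.items():
            for r, c in per_region.items():
                if r not in REGIONS:
                    raise FormatError(f"unknown region {r!r} for {ind!r}")
                if c < 0:
                    raise FormatError("counts must be non-negative")

    def total(self, individual_id: str) -> int:
        return sum(self.counts[individual_id].values())

    def totals(self) -> dict[str, int]:
        return {ind: self.total(ind) for ind in self.counts}


def summarize_cohort(datasets: Iterable[ExpressionDataset]) -> CohortSummary:
    """Tally samples per region for each individual.

    An empty input yields an empty summary; duplicate individual ids are
    rejected.
    """
    counts: dict[str, dict[str, int]] = {}
    for ds in datasets:
        if ds.individual_id in counts:
            raise ConsistencyError(f"duplicate individual id {ds.individual_id!r}")
        counts[ds.individual_id] = ds.region_counts()
    return CohortSummary(counts)


@dataclass
class FeatureList:
    """An ordered, scored gene ranking.

    ``flavor`` is ``"MaxRel"`` (ranking by class relevance alone; scores must
    be non-increasing) or ``"mRMR"`` (greedy relevance-minus-redundancy order;
    scores are the greedy objective at selection time and need not be
    monotone).  Prefixes of the list are the nested feature sets
    ``F_1 ⊂ F_2 ⊂ ...`` consumed by incremental feature selection.
    """

    flavor: str
    entries: list[tuple[str, float]]

    _SCORE_TOL = 1e-9  # slack for the MaxRel monotonicity check

    def __post_init__(self) -> None:
        if self.flavor not in ("MaxRel", "mRMR"):
            raise FormatError(f"unknown feature-list flavor {self.flavor!r}")
        self.entries = [(str(g), float(s)) for g, s in self.entries]
        ids = [g for g, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate gene id in feature list")
        if self.flavor == "MaxRel":
            scores = [s for _, s in self.entries]
            for a, b in zip(scores, scores[1:]):
                if b > a + self._SCORE_TOL:
                    raise FormatError("MaxRel scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def prefix(self, k: int) -> list[str]:
        """First ``k`` gene ids (the nested feature set ``F_k``)."""
        if not 0 <= k <= len(self.entries):
            raise ValueError(f"prefix length {k} outside [0, {len(self.entries)}]")
        return [g for g, _ in self.entries[:k]]
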