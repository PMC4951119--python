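"""Discretization, mutual information, and MaxRel / mRMR gene rankings.

Expression intensities are reduced to three states per gene (below / within /
above a band of ``threshold`` standard deviations around the gene's mean),
the convention commonly paired with minimum-redundancy-maximum-relevance
selection on microarray data.  Mutual information is the plug-in estimate in
bits.  Two rankings are produced:

* MaxRel — genes sorted by relevance I(gene; region) alone;
* mRMR   — greedy: each step adds the gene maximizing relevance minus (or
  divided by, for the quotient criterion) its mean redundancy
  ``(1/|S|) sum_{s in S} I(gene; s)`` with the already-selected set ``S``.

Ties are broken by ascending gene id so lists are reproducible everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import REGIONS, ExpressionDataset, FeatureList

_STATES = (-1, 0, 1)
_QUOTIENT_EPS = 1e-12


@dataclass
class DiscretizedDataset:
    """Three-state (−1/0/+1) version of an expression dataset.

    ``states`` is G x S int8; ``gene_means`` / ``gene_sds`` record the
    per-gene thresholds actually used (sample standard deviation, ddof=1).
    """

    individual_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    states: np.ndarray
    class_labels: list[str]
    gene_means: np.ndarray
    gene_sds: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("states shape must be (n_genes, n_samples)")
        if not np.isin(self.states, _STATES).all():
            raise ValueError("states must be in {-1, 0, +1}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def class_codes(self) -> np.ndarray:
        order = {r: i for i, r in enumerate(REGIONS)}
        return np.array([order[l] for l in self.class_labels], dtype=np.int64)


def discretize(dataset: ExpressionDataset, threshold: float = 1.0) -> DiscretizedDataset:
    """Map each gene's values to {-1, 0, +1} around mean ± threshold·sd.

    The mean and (sample, ddof=1) standard deviation are computed on this
    dataset only.  Constant genes (sd = 0, including single-sample datasets)
    map to all-zero states.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0 (sd units)")
    values = dataset.values
    means = values.mean(axis=1)
    if values.shape[1] > 1:
        sds = values.std(axis=1, ddof=1)
    else:
        sds = np.zeros(values.shape[0])
    lo = means - threshold * sds
    hi = means + threshold * sds
    states = np.zeros(values.shape, dtype=np.int8)
    nondegenerate = (sds > 0)[:, None]
    states[(values < lo[:, None]) & nondegenerate] = -1
    states[(values > hi[:, None]) & nondegenerate] = 1
    return DiscretizedDataset(
        individual_id=dataset.individual_id,
        gene_ids=list(dataset.gene_ids),
        sample_ids=list(dataset.sample_ids),
        states=states,
        class_labels=list(dataset.region_labels),
        gene_means=means,
        gene_sds=sds,
        threshold=float(threshold),
    )


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """Plug-in mutual information (bits) from joint-count tables.

    ``counts``: (..., A, B) non-negative tables; zero cells contribute zero.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n
        px = p.sum(axis=-1, keepdims=True)
        py = p.sum(axis=-2, keepdims=True)
        terms = p * (np.log2(p) - np.log2(px * py))
    terms = np.where(counts > 0, terms, 0.0)
    mi = terms.sum(axis=(-2, -1))
    # the plug-in estimate is non-negative; clip float round-off
    return np.maximum(mi, 0.0)


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(x; y) in bits between discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size == 0:
        raise ValueError("vectors must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    counts = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(counts, (xi, yi), 1)
    return float(_mi_from_counts(counts))


def _mi_all_genes(states: np.ndarray, other: np.ndarray, n_symbols: int) -> np.ndarray:
    """I(states[g]; other) for every gene g, vectorized.

    ``states``: G x S in {-1,0,1}; ``other``: length-S integer codes in
    [0, n_symbols).
    """
    S = states.shape[1]
    onehot = (other[None, :] == np.arange(n_symbols)[:, None]).astype(np.float64)  # n_sym x S
    counts = np.empty((states.shape[0], 3, n_symbols))
    for a, state in enumerate(_STATES):
        counts[:, a, :] = (states == state).astype(np.float64) @ onehot.T
    return _mi_from_counts(counts)


def relevance(data: DiscretizedDataset) -> np.ndarray:
    """I(gene; region class) for every gene, in bits."""
    return _mi_all_genes(data.states, data.class_codes(), len(REGIONS))


def _ordered_by_score(gene_ids: list[str], scores: np.ndarray) -> list[int]:
    """Indices sorted by score descending, ties by ascending gene id."""
    return sorted(range(len(gene_ids)), key=lambda i: (-scores[i], gene_ids[i]))


def maxrel_ranking(data: DiscretizedDataset, n_features: int) -> FeatureList:
    """Rank genes by relevance alone (MaxRel list), truncated to n_features."""
    if not 1 <= n_features <= data.n_genes:
        raise ValueError("n_features must be in [1, n_genes]")
    rel = relevance(data)
    if len(set(data.class_labels)) < 2:
        import warnings

        warnings.warn("single-class labels: all relevances are zero")
    order = _ordered_by_score(data.gene_ids, rel)[:n_features]
    return FeatureList(
        flavor="MaxRel",
        entries=[(data.gene_ids[i], float(rel[i])) for i in order],
    )


def mrmr_ranking(
    data: DiscretizedDataset,
    n_features: int,
    criterion: str = "difference",
) -> FeatureList:
    """Greedy minimum-redundancy-maximum-relevance ranking.

    The first gene is the most relevant; each subsequent step adds the gene
    maximizing ``relevance - mean_redundancy`` (``difference``) or
    ``relevance / max(mean_redundancy, eps)`` (``quotient``) against the
    selected set.  The score stored for each entry is the greedy objective at
    the moment of selection (relevance itself for the first entry).
    """
    if criterion not in ("difference", "quotient"):
        raise ValueError("criterion must be 'difference' or 'quotient'")
    if not 1 <= n_features <= data.n_genes:
        raise ValueError("n_features must be in [1, n_genes]")

    gene_ids = data.gene_ids
    rel = relevance(data)
    if len(set(data.class_labels)) < 2:
        import warnings

        warnings.warn("single-class labels: all relevances are zero")

    remaining = set(range(len(gene_ids)))
    red_sum = np.zeros(len(gene_ids))  # sum of I(g; s) over selected s
    entries: list[tuple[str, float]] = []
    selected: list[int] = []

    first = _ordered_by_score(gene_ids, rel)[0]
    entries.append((gene_ids[first], float(rel[first])))
    selected.append(first)
    remaining.discard(first)

    while len(entries) < n_features:
        # accumulate redundancy against the most recently selected gene
        last = selected[-1]
        red_sum += _mi_all_genes(
            data.states, (data.states[last] + 1).astype(np.int64), 3
        )
        m = len(selected)
        if criterion == "difference":
            scores = rel - red_sum / m
        else:
            scores = rel / np.maximum(red_sum / m, _QUOTIENT_EPS)
        best = min(remaining, key=lambda i: (-scores[i], gene_ids[i]))
        entries.append((gene_ids[best], float(scores[best])))
        selected.append(best)
        remaining.discard(best)

    return FeatureList(flavor="mRMR", entries=entries)
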