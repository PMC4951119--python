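"""Soft-margin linear SVMs trained by sequential minimal optimization (SMO),
extended to the three region classes by one-vs-one pairwise voting.

The binary trainer solves the dual problem

    min_a  (1/2) a' Q a - 1' a,   Q_ij = y_i y_j <x_i, x_j>,
    s.t.   y' a = 0,  0 <= a_i <= C,

by repeatedly optimizing the two-variable subproblem chosen by the
maximal-violating-pair rule: at each iteration the pair (i, j) with the
largest KKT violation ``m - M`` is updated analytically, where

    m = max_{i in I_up} -y_i g_i,   M = min_{j in I_low} -y_j g_j,

``g = Q a - 1`` is the dual gradient and I_up / I_low are the index sets
whose multipliers can still move up / down.  Training stops when
``m - M <= tol``; the bias is ``b = (m + M) / 2``.  Features are standardized
to training mean and population standard deviation (constant features pass
through unscaled); with a linear kernel the model reduces to a weight vector
in standardized coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import REGIONS, FormatError

ALPHA_BOUND_EPS = 1e-8  # below/above this distance an alpha counts as at-bound
_TAU = 1e-12            # curvature floor for degenerate working pairs


@dataclass
class BinarySVMModel:
    """A trained binary soft-margin linear SVM.

    ``class_pair = (pos, neg)``: samples of ``pos`` were trained as y=+1 and
    a non-negative decision value predicts ``pos`` (zero maps to the first
    label of the pair).  ``weights``/``bias`` act on standardized
    coordinates ``(x - mean) / scale``.
    """

    class_pair: tuple[str, str]
    alpha: np.ndarray
    y: np.ndarray
    bias: float
    weights: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    C: float
    tol: float
    n_iter: int = 0

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-matrix'}"
            )
        Z = (X - self.mean) / self.scale
        return Z @ self.weights + self.bias


@dataclass
class _ConstantBinary:
    """Degenerate pair model used when one class of a pair has no samples."""

    class_pair: tuple[str, str]
    present: str  # the label to always predict

    @property
    def n_features(self) -> int:  # matches any width
        return -1

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sign = 1.0 if self.present == self.class_pair[0] else -1.0
        return np.full(X.shape[0], sign)


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)  # population sd, so a symmetric +-1 pair keeps scale 1
    scale = np.where(scale > 0, scale, 1.0)  # constant features pass through
    return mean, scale


def _smo_solve(
    K: np.ndarray, y: np.ndarray, C: float, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int]:
    """Maximal-violating-pair SMO on a precomputed kernel matrix."""
    n = y.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)  # Q a - 1 at a = 0
    yK = y[None, :] * K  # row i of Q is y_i * yK[i]

    it = 0
    while it < max_iter:
        ya = -y * grad
        up = ((y > 0) & (alpha < C - ALPHA_BOUND_EPS)) | (
            (y < 0) & (alpha > ALPHA_BOUND_EPS)
        )
        low = ((y < 0) & (alpha < C - ALPHA_BOUND_EPS)) | (
            (y > 0) & (alpha > ALPHA_BOUND_EPS)
        )
        if not up.any() or not low.any():
            break
        i = int(np.flatnonzero(up)[np.argmax(ya[up])])
        m = ya[i]
        low_idx = np.flatnonzero(low)
        M = ya[low_idx].min()
        if m - M <= tol:
            break
        # second-order choice of j: maximal objective decrease for the pair
        cand = low_idx[ya[low_idx] < m]
        gap = m - ya[cand]
        curv = np.maximum(K[i, i] + K[cand, cand] - 2.0 * K[i, cand], _TAU)
        j = int(cand[np.argmax(gap * gap / curv)])

        a_curv = K[i, i] + K[j, j] - 2.0 * K[i, j]
        t = (m - ya[j]) / max(a_curv, _TAU)
        # step: alpha_i += y_i t, alpha_j -= y_j t keeps y'a constant
        if y[i] > 0:
            t = min(t, C - alpha[i])
        else:
            t = min(t, alpha[i])
        if y[j] > 0:
            t = min(t, alpha[j])
        else:
            t = min(t, C - alpha[j])
        if t <= 0:
            break  # numerically stuck; KKT gap is within round-off of tol
        d_i = y[i] * t
        d_j = -y[j] * t
        alpha[i] += d_i
        alpha[j] += d_j
        grad += d_i * (y[i] * yK[i]) + d_j * (y[j] * yK[j])
        it += 1

    ya = -y * grad
    up = ((y > 0) & (alpha < C - ALPHA_BOUND_EPS)) | ((y < 0) & (alpha > ALPHA_BOUND_EPS))
    low = ((y < 0) & (alpha < C - ALPHA_BOUND_EPS)) | ((y > 0) & (alpha > ALPHA_BOUND_EPS))
    m = ya[up].max() if up.any() else 0.0
    M = ya[low].min() if low.any() else 0.0
    bias = (m + M) / 2.0
    return alpha, float(bias), it


def train_binary(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-3,
    class_pair: tuple[str, str] = ("+1", "-1"),
    max_iter: int = 200_000,
) -> BinarySVMModel:
    """Train a binary linear SVM with SMO.

    ``y`` holds +1/-1 labels; both classes must be present and all values
    finite.  Standardization statistics come from this training set only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be samples x features with one label per row")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if not set(np.unique(y)) == {-1.0, 1.0}:
        raise ValueError("y must contain both classes, coded -1/+1")
    if C <= 0 or tol <= 0:
        raise ValueError("C and tol must be positive")

    mean, scale = _standardize_fit(X)
    Z = (X - mean) / scale
    K = Z @ Z.T
    alpha, bias, n_iter = _smo_solve(K, y, C, tol, max_iter)
    weights = Z.T @ (alpha * y)
    return BinarySVMModel(
        class_pair=class_pair,
        alpha=alpha,
        y=y,
        bias=bias,
        weights=weights,
        mean=mean,
        scale=scale,
        C=C,
        tol=tol,
        n_iter=n_iter,
    )


def predict_binary(model: BinarySVMModel, X: np.ndarray):
    """Decision values and pair labels; a zero decision value maps to the
    pair's first label."""
    f = model.decision_function(np.asarray(X, dtype=float))
    labels = np.where(f >= 0, model.class_pair[0], model.class_pair[1])
    return f, labels


def dual_objective(model: BinarySVMModel) -> float:
    """The dual objective sum(a) - (1/2) a' Q a of a trained model."""
    a, y, w = model.alpha, model.y, model.weights
    return float(a.sum() - 0.5 * (w @ w))


# ---------------------------------------------------------------------------
# one-vs-one multiclass
# ---------------------------------------------------------------------------

CLASS_PAIRS: tuple[tuple[str, str], ...] = (
    ("BS", "CB"), ("BS", "CC"), ("CB", "CC"),
)


@dataclass
class MulticlassModel:
    """Three pairwise binary SVMs combined by majority vote.

    Two-way (or three-way) vote ties are broken by the larger sum of absolute
    decision values accumulated by the tied classes, then by label order
    BS < CB < CC.
    """

    models: dict[tuple[str, str], object]
    classes: tuple[str, ...]
    tie_break: str = "margin-sum,label-order"


def train_multiclass(
    X: np.ndarray,
    y: "np.ndarray | list[str]",
    C: float = 1.0,
    tol: float = 1e-3,
) -> MulticlassModel:
    """Train one binary SVM per region pair on that pair's samples.

    A pair with one class absent from ``y`` gets a constant predictor for the
    present class; if fewer than two classes are present overall, training
    fails.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    present = [r for r in REGIONS if (y == r).any()]
    if len(present) < 2:
        raise ValueError("at least two region classes are required")
    unknown = set(y) - set(REGIONS)
    if unknown:
        raise FormatError(f"unknown region label {sorted(unknown)[0]!r}")

    models: dict[tuple[str, str], object] = {}
    for pos, neg in CLASS_PAIRS:
        mask = (y == pos) | (y == neg)
        has_pos = (y == pos).any()
        has_neg = (y == neg).any()
        if has_pos and has_neg:
            yy = np.where(y[mask] == pos, 1.0, -1.0)
            models[(pos, neg)] = train_binary(
                X[mask], yy, C=C, tol=tol, class_pair=(pos, neg)
            )
        else:
            present_label = pos if has_pos else neg
            models[(pos, neg)] = _ConstantBinary(
                class_pair=(pos, neg), present=present_label
            )
    return MulticlassModel(models=models, classes=tuple(present))


def _combine_votes(decisions: dict[tuple[str, str], np.ndarray]) -> np.ndarray:
    """Majority vote over pairwise decision values with the margin-sum /
    label-order tie policy.  Exposed for direct testing of the tie rules."""
    pairs = list(decisions)
    n = len(next(iter(decisions.values()))) if pairs else 0
    labels = np.empty(n, dtype=object)
    order = {r: i for i, r in enumerate(REGIONS)}
    for s in range(n):
        votes = {r: 0 for r in REGIONS}
        margin = {r: 0.0 for r in REGIONS}
        for (pos, neg) in pairs:
            f = float(decisions[(pos, neg)][s])
            winner = pos if f >= 0 else neg
            votes[winner] += 1
            margin[winner] += abs(f)
        top = max(votes.values())
        tied = [r for r in REGIONS if votes[r] == top]
        if len(tied) > 1:
            best = max(margin[r] for r in tied)
            tied = [r for r in tied if margin[r] == best]
        labels[s] = min(tied, key=lambda r: order[r])
    return labels


def predict_multiclass(model: MulticlassModel, X: np.ndarray) -> np.ndarray:
    """Region labels for each row of X (empty X gives an empty array)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0, dtype=object)
    decisions = {
        pair: m.decision_function(X) for pair, m in model.models.items()
    }
    return _combine_votes(decisions)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoreResult:
    """Exact correct/total tallies; accuracies derive from integer counts."""

    n_correct: int
    n_total: int
    per_class: dict[str, tuple[int, int]]  # region -> (correct, count)

    @property
    def total_accuracy(self) -> float:
        return self.n_correct / self.n_total

    def class_accuracy(self, region: str) -> "float | None":
        correct, count = self.per_class[region]
        return None if count == 0 else correct / count


def score_predictions(true_labels, predicted_labels) -> ScoreResult:
    """Total and per-class accuracy tallies.

    Per-class accuracy for region ``c`` counts only samples whose true label
    is ``c``; a region with no samples is reported as not applicable.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    if len(true_labels) == 0:
        raise ValueError("at least one sample is required")
    per_class = {r: [0, 0] for r in REGIONS}
    correct = 0
    for t, p in zip(true_labels, predicted_labels):
        per_class[t][1] += 1
        if t == p:
            per_class[t][0] += 1
            correct += 1
    return ScoreResult(
        n_correct=correct,
        n_total=len(true_labels),
        per_class={r: (c[0], c[1]) for r, c in per_class.items()},
    )


# ---------------------------------------------------------------------------
# serialization (TSV-based, for reproducibility)
# ---------------------------------------------------------------------------

def save_binary_model(model: BinarySVMModel, path: "str | Path") -> None:
    """Write alphas, labels, bias, weights and standardization vectors."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"class_pair\t{model.class_pair[0]}\t{model.class_pair[1]}\n")
        fh.write(f"C\t{model.C:.12g}\n")
        fh.write(f"tol\t{model.tol:.12g}\n")
        fh.write(f"bias\t{model.bias:.17g}\n")
        fh.write("alpha\t" + "\t".join(f"{a:.17g}" for a in model.alpha) + "\n")
        fh.write("y\t" + "\t".join(f"{v:.0f}" for v in model.y) + "\n")
        fh.write("weights\t" + "\t".join(f"{w:.17g}" for w in model.weights) + "\n")
        fh.write("mean\t" + "\t".join(f"{m:.17g}" for m in model.mean) + "\n")
        fh.write("scale\t" + "\t".join(f"{s:.17g}" for s in model.scale) + "\n")


def load_binary_model(path: "str | Path") -> BinarySVMModel:
    fields: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            fields[parts[0]] = parts[1:]
    return BinarySVMModel(
        class_pair=(fields["class_pair"][0], fields["class_pair"][1]),
        alpha=np.array([float(v) for v in fields["alpha"]]),
        y=np.array([float(v) for v in fields["y"]]),
        bias=float(fields["bias"][0]),
        weights=np.array([float(v) for v in fields["weights"]]),
        mean=np.array([float(v) for v in fields["mean"]]),
        scale=np.array([float(v) for v in fields["scale"]]),
        C=float(fields["C"][0]),
        tol=float(fields["tol"][0]),
    )
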