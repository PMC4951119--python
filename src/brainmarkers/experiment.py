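"""The cross-individual marker-recovery experiment on a synthetic cohort.

Runs the full pipeline in memory — generate a planted cohort, rank genes per
individual, trace cross-individual accuracy curves, select inflection points,
intersect, and build the consensus table — and summarizes how well the
consensus recovers the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ifs import (
    ConsensusGeneTable,
    IFSCurve,
    InflectionPoint,
    consensus_frequency,
    find_inflection_point,
    important_features,
    max_accuracy_point,
    run_ifs,
)
from .mrmr import discretize, mrmr_ranking
from .simulate import GeneratorConfig, GroundTruth, generate_cohort


@dataclass
class RecoveryResult:
    """Everything one pipeline run produced, plus recovery metrics."""

    truth: GroundTruth
    consensus: ConsensusGeneTable
    inflections: list[tuple[str, str, InflectionPoint]]
    important_sizes: dict[str, int]
    curves: list[IFSCurve] = field(repr=False, default_factory=list)

    @property
    def n_planted(self) -> int:
        return len(self.truth.all_planted)

    def planted_frequency_fraction(self, min_frequency: int = 4) -> float:
        """Fraction of planted genes reaching the given consensus frequency."""
        planted = self.truth.all_planted
        hits = sum(
            1 for g in planted if self.consensus.frequency_of(g) >= min_frequency
        )
        return hits / len(planted) if planted else 0.0

    def top_unplanted_fraction(self, n_top: int = 30) -> float:
        """Fraction of the top consensus rows that are not planted genes."""
        top = self.consensus.top(n_top)
        if not top:
            return 0.0
        return sum(1 for r in top if r.gene_id not in self.truth.all_planted) / len(top)


def run_recovery_experiment(
    config: "GeneratorConfig | None" = None,
    n_features: int = 64,
    k_min: int = 4,
    k_max: int = 50,
    C: float = 1.0,
    tol: float = 1e-3,
    keep_curves: bool = False,
) -> RecoveryResult:
    """Full leave-one-individual-as-training pipeline on a generated cohort.

    ``n_features`` defaults to 64: the inflection search range caps every
    selected prefix at ``k_max`` (50), so ranking beyond ``k_max + 1`` genes
    cannot change the consensus.
    """
    if config is None:
        config = GeneratorConfig()
    datasets, truth = generate_cohort(config)
    n_features = min(n_features, config.n_genes)
    k_max = min(k_max, n_features - 1)

    important: list[tuple[str, set[str]]] = []
    inflections: list[tuple[str, str, InflectionPoint]] = []
    important_sizes: dict[str, int] = {}
    all_curves: list[IFSCurve] = []
    for training in datasets:
        disc = discretize(training)
        mrmr = mrmr_ranking(disc, n_features)
        tests = [d for d in datasets if d.individual_id != training.individual_id]
        curves = run_ifs(training, tests, mrmr, n_max=n_features, C=C, tol=tol)
        if keep_curves:
            all_curves.extend(curves)
        points = []
        for curve in curves:
            pt = find_inflection_point(curve, k_min=k_min, k_max=k_max)
            points.append(pt)
            inflections.append(
                (curve.training_individual, curve.test_individual, pt)
            )
        genes = important_features(mrmr, points)
        important.append((training.individual_id, genes))
        important_sizes[training.individual_id] = len(genes)

    return RecoveryResult(
        truth=truth,
        consensus=consensus_frequency(important),
        inflections=inflections,
        important_sizes=important_sizes,
        curves=all_curves,
    )
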