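"""Synthetic multi-individual expression cohorts with planted marker genes.

The generator emulates the structure of a six-donor brain microarray cohort:
each individual contributes one genes x samples matrix whose samples come from
three regions (BS, CB, CC) with strongly imbalanced counts.  A small set of
"planted" genes carries a region-specific mean shift shared across all
individuals — these are the ground-truth region-discriminative genes the
pipeline is expected to recover.

Generative model, per gene ``g``, individual ``d``, sample ``s`` of region ``r``::

    x = mu_g + b_{d,g} + delta_{g,r} + eps
    mu_g     ~ Normal(0, 1)            shared across individuals
    b_{d,g}  ~ Normal(0, batch_sd^2)   individual-level batch offset
    delta    = effect_size * noise_sd  if g planted for region r, else 0
    eps      ~ Normal(0, noise_sd^2)

A fixed seed gives bit-identical cohorts; per-individual sub-streams are
derived from the seed so the output does not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .datamodel import REGIONS, ExpressionDataset

#: Per-individual (BS, CB, CC) sample counts of the emulated six-donor cohort.
DEFAULT_INDIVIDUALS: tuple[str, ...] = (
    "H0351.1009", "H0351.1012", "H0351.1015",
    "H0351.1016", "H0351.2001", "H0351.2002",
)
DEFAULT_COUNTS: tuple[tuple[int, int, int], ...] = (
    (26, 42, 295),
    (80, 48, 401),
    (79, 62, 329),
    (59, 80, 362),
    (154, 53, 739),
    (188, 83, 622),
)


@dataclass
class GeneratorConfig:
    """Cohort generator settings.

    ``n_genes`` defaults to 2,000 (test scale); a full-scale emulation uses
    20,782.  ``effect_size`` is expressed in units of the within-region
    standard deviation ``noise_sd``.  ``shared_planting=False`` plants a
    private marker set per individual instead of one shared set, emulating
    genes that discriminate regions in only some individuals.
    """

    n_genes: int = 2000
    per_individual_counts: tuple[tuple[int, int, int], ...] = DEFAULT_COUNTS
    individual_ids: tuple[str, ...] = DEFAULT_INDIVIDUALS
    n_planted_per_region: int = 10
    effect_size: float = 2.0
    batch_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0
    shared_planting: bool = True

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_planted_per_region < 0:
            raise ValueError("n_planted_per_region must be non-negative")
        if 3 * self.n_planted_per_region > self.n_genes:
            raise ValueError(
                "3 * n_planted_per_region must not exceed n_genes"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.per_individual_counts) == 0:
            raise ValueError("at least one individual is required")
        if len(self.individual_ids) != len(self.per_individual_counts):
            raise ValueError("one id per per_individual_counts row is required")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be distinct")
        for ind, row in zip(self.individual_ids, self.per_individual_counts):
            if len(row) != 3 or any(c < 0 for c in row):
                raise ValueError(f"counts for {ind!r} must be 3 non-negative ints")
            if sum(row) == 0:
                raise ValueError(f"individual {ind!r} has no samples")


@dataclass
class GroundTruth:
    """Which genes were planted for which region, and their mean shifts."""

    planted: dict[str, list[str]]          # region -> gene ids
    deltas: dict[tuple[str, str], float]   # (gene_id, region) -> shift
    private: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    # individual -> region -> gene ids (only for shared_planting=False)

    def __post_init__(self) -> None:
        sets = [set(v) for v in self.planted.values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("planted sets must be pairwise disjoint")

    @property
    def all_planted(self) -> set[str]:
        return set().union(*self.planted.values()) if self.planted else set()


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Draw one cohort from the generative model.

    Returns the per-individual datasets (order and ids as configured) and the
    ground truth of planted genes.
    """
    config.validate()
    gene_ids = _gene_ids(config.n_genes)

    root = np.random.SeedSequence(config.seed)
    # child 0 drives global quantities; children 1.. drive individuals, so the
    # cohort is identical however the individuals are iterated.
    children = root.spawn(1 + len(config.individual_ids))
    g_rng = np.random.default_rng(children[0])

    mu = g_rng.normal(0.0, 1.0, size=config.n_genes)
    delta_value = config.effect_size * config.noise_sd

    def draw_planting(rng: np.random.Generator) -> dict[str, list[str]]:
        chosen = rng.choice(
            config.n_genes, size=3 * config.n_planted_per_region, replace=False
        )
        return {
            r: sorted(gene_ids[i] for i in chosen[
                j * config.n_planted_per_region:(j + 1) * config.n_planted_per_region
            ])
            for j, r in enumerate(REGIONS)
        }

    shared = draw_planting(g_rng)
    deltas: dict[tuple[str, str], float] = {}
    private: dict[str, dict[str, list[str]]] = {}

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    datasets: list[ExpressionDataset] = []
    for d_idx, (ind, counts) in enumerate(
        zip(config.individual_ids, config.per_individual_counts)
    ):
        rng = np.random.default_rng(children[1 + d_idx])
        planting = shared if config.shared_planting else draw_planting(rng)
        if not config.shared_planting:
            private[ind] = planting

        s_total = sum(counts)
        labels = [r for r, c in zip(REGIONS, counts) for _ in range(c)]
        sample_ids = [f"{ind}_s{i:04d}" for i in range(1, s_total + 1)]

        batch = rng.normal(0.0, config.batch_sd, size=config.n_genes)
        values = (
            mu[:, None]
            + batch[:, None]
            + rng.normal(0.0, config.noise_sd, size=(config.n_genes, s_total))
        )
        col = 0
        for r, c in zip(REGIONS, counts):
            for g in planting[r]:
                values[gene_pos[g], col:col + c] += delta_value
                deltas[(g, r)] = delta_value
            col += c

        datasets.append(
            ExpressionDataset(
                individual_id=ind,
                gene_ids=gene_ids,
                sample_ids=sample_ids,
                values=values,
                region_labels=labels,
            )
        )

    truth = GroundTruth(
        planted=shared if config.shared_planting else {r: [] for r in REGIONS},
        deltas=deltas,
        private=private,
    )
    return datasets, truth


def make_curve_fixture(accuracies: list[float]):
    """Wrap raw accuracies as an IFS curve (k = 1..len), for testing the
    inflection detector without running a classifier.

    Per-class accuracies are placeholders equal to the total.
    """
    from .ifs import CurvePoint, IFSCurve

    if len(accuracies) == 0:
        raise ValueError("at least one accuracy is required")
    points = []
    for k, a in enumerate(accuracies, start=1):
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"accuracy {a} outside [0, 1]")
        frac = Fraction(a)
        points.append(
            CurvePoint(k=k, total=frac, per_class={r: frac for r in REGIONS})
        )
    return IFSCurve(training_individual="fixture", test_individual="fixture",
                    points=points)
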