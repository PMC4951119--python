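"""End-to-end orchestration: simulate/load -> rank -> IFS -> inflect -> consensus.

The cross-design is fixed: each individual serves once as the training
dataset, with every other individual as a test dataset.  One run therefore
produces, for D individuals, D MaxRel + D mRMR lists, D*(D-1) accuracy
curves and inflection records, D important-feature sets, and one consensus
table.  Every artifact is a TSV under the output directory, enumerated with
a SHA-256 digest in ``manifest.json``; runs with the same configuration and
seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as bio
from .datamodel import ExpressionDataset, summarize_cohort
from .ifs import (
    consensus_frequency,
    find_inflection_point,
    important_features,
    max_accuracy_point,
    run_ifs,
)
from .mrmr import discretize, maxrel_ranking, mrmr_ranking
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger("brainmarkers")


@dataclass
class RunConfig:
    """One pipeline run: either a generator config or paths to existing data.

    ``inputs`` maps individual id -> (matrix TSV, annotation TSV).  The
    inflection search range follows the curve-reading convention of zooming
    into k in [4, 50]; ``k_max`` is clipped to ``n_features - 1`` so the
    successor point needed by the inflection rule always exists.
    """

    out_dir: Path
    generator: "GeneratorConfig | None" = None
    inputs: "dict[str, tuple[Path, Path]] | None" = None
    n_features: int = 500
    criterion: str = "difference"
    threshold_sd: float = 1.0
    C: float = 1.0
    tol: float = 1e-3
    k_min: int = 4
    k_max: int = 50

    def validate(self) -> None:
        if (self.generator is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of generator config or input paths is required"
            )
        if self.generator is not None:
            self.generator.validate()
        if self.n_features < 3:
            raise ValueError("n_features must be >= 3")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("require 2 <= k_min <= k_max")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_echo(config: RunConfig) -> dict:
    echo: dict = {
        "n_features": config.n_features,
        "criterion": config.criterion,
        "threshold_sd": config.threshold_sd,
        "C": config.C,
        "tol": config.tol,
        "k_min": config.k_min,
        "k_max": config.k_max,
    }
    if config.generator is not None:
        echo["generator"] = asdict(config.generator)
    else:
        echo["inputs"] = sorted(config.inputs)
    return echo


def load_inputs(config: RunConfig) -> list[ExpressionDataset]:
    """Materialize the cohort, either from disk or from the generator."""
    if config.inputs is not None:
        return [
            bio.read_expression_dataset(matrix, annotation, ind)
            for ind, (matrix, annotation) in sorted(config.inputs.items())
        ]
    datasets, _ = generate_cohort(config.generator)
    return datasets


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    stage = "simulate/load"
    try:
        if config.generator is not None:
            datasets, truth = generate_cohort(config.generator)
            data_dir = out / "data"
            data_dir.mkdir(exist_ok=True)
            for ds in datasets:
                mpath = data_dir / f"{ds.individual_id}.matrix.tsv"
                apath = data_dir / f"{ds.individual_id}.annotation.tsv"
                bio.write_expression_dataset(ds, mpath, apath)
                emit(mpath)
                emit(apath)
            tpath = data_dir / "ground_truth.tsv"
            with open(tpath, "w", encoding="utf-8") as fh:
                fh.write("gene_id\tregion\tdelta\n")
                for (gene, region), delta in sorted(truth.deltas.items()):
                    fh.write(f"{gene}\t{region}\t{delta:.12g}\n")
            emit(tpath)
        else:
            datasets = load_inputs(config)

        summary = summarize_cohort(datasets)
        spath = out / "cohort_summary.tsv"
        with open(spath, "w", encoding="utf-8") as fh:
            fh.write("individual_id\tBS\tCB\tCC\ttotal\n")
            for ind in sorted(summary.counts):
                c = summary.counts[ind]
                fh.write(
                    f"{ind}\t{c['BS']}\t{c['CB']}\t{c['CC']}\t{summary.total(ind)}\n"
                )
        emit(spath)

        n_features = min(config.n_features, datasets[0].n_genes)
        k_max = min(config.k_max, n_features - 1)
        if not 2 <= config.k_min <= k_max:
            raise ValueError(
                f"inflection range [{config.k_min}, {k_max}] is empty for "
                f"n_features={n_features}"
            )

        important: list[tuple[str, set[str]]] = []
        inflection_records: list[tuple[str, str, object]] = []
        for training in datasets:
            stage = f"rank[{training.individual_id}]"
            logger.info("ranking features for %s", training.individual_id)
            disc = discretize(training, threshold=config.threshold_sd)
            maxrel = maxrel_ranking(disc, n_features)
            mrmr = mrmr_ranking(disc, n_features, criterion=config.criterion)
            for flavor, flist in (("maxrel", maxrel), ("mrmr", mrmr)):
                path = out / f"{training.individual_id}.{flavor}.tsv"
                bio.write_feature_list(flist, path)
                emit(path)

            stage = f"ifs[{training.individual_id}]"
            tests = [d for d in datasets if d.individual_id != training.individual_id]
            curves = run_ifs(
                training, tests, mrmr, n_max=n_features, C=config.C, tol=config.tol
            )
            inflections = []
            for curve in curves:
                cpath = out / (
                    f"curve.{curve.training_individual}.vs."
                    f"{curve.test_individual}.tsv"
                )
                bio.write_curve(curve, cpath)
                emit(cpath)
                pt = find_inflection_point(curve, k_min=config.k_min, k_max=k_max)
                inflections.append(pt)
                inflection_records.append(
                    (curve.training_individual, curve.test_individual, pt)
                )
            important.append(
                (training.individual_id, important_features(mrmr, inflections))
            )

        stage = "inflect"
        ipath = out / "inflection_points.tsv"
        bio.write_inflections(inflection_records, ipath)
        emit(ipath)
        for tid, genes in important:
            gpath = out / f"{tid}.important.tsv"
            with open(gpath, "w", encoding="utf-8") as fh:
                fh.write("gene_id\n")
                for g in sorted(genes):
                    fh.write(g + "\n")
            emit(gpath)

        stage = "consensus"
        table = consensus_frequency(important)
        cpath = out / "consensus.tsv"
        bio.write_consensus(table, cpath)
        emit(cpath)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": _config_echo(config),
        "files": [
            {"path": str(p.relative_to(out)), "sha256": _digest(p),
             "bytes": p.stat().st_size}
            for p in sorted(written)
        ],
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                     encoding="utf-8")
    logger.info("wrote %d artifacts to %s", len(written) + 1, out)
    return manifest
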