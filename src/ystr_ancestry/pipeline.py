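"""End-to-end reproducible runs: simulate/load -> preprocess -> train
(one-vs-rest and/or one-vs-one) -> evaluate -> compare.

A run is driven by one :class:`RunConfig`; identical configs produce
identical reports (all randomness flows from the config seeds, and the
report contains no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np

from . import __version__
from .base import BinaryClassifierSpec
from .data import HaplotypeTable, read_haplotype_table, write_haplotype_table
from .evaluate import confusion, misclassification_summary, report
from .features import build_vocabulary
from .metanet import MetaNetworkConfig
from .ovo import OvOStackingModel
from .ovr import OvRAttentionModel, count_classifiers
from .panel import DEFAULT_PANEL, MarkerPanel
from .preprocess import downsample_to_min, filter_complete, stratified_split
from .simulate import (
    PopulationModel,
    SimulationConfig,
    generate_table,
    mix_populations,
    sample_population_model,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """One experiment: exactly one input source plus pipeline options."""

    # input: either a table on disk...
    table_path: str | None = None
    panel_path: str | None = None
    # ...or a simulation recipe
    simulate: dict | None = None

    train_fraction: float = 0.8
    balance: bool = True
    feature_mode: str = "full"            # "full" | "one-per-marker"
    architectures: tuple[str, ...] = ("ovr",)
    expert_algorithm: str = "logistic_regression"
    tune: bool = False
    tune_budget: int = 8
    calibration_folds: int = 3
    temperature: float = 1.0
    meta: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.table_path is None) == (self.simulate is None):
            raise ConfigError("exactly one of table_path / simulate must be given")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        bad = set(self.architectures) - {"ovr", "ovo"}
        if bad:
            raise ConfigError(f"unknown architectures: {sorted(bad)}")
        self.architectures = tuple(self.architectures)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["architectures"] = list(self.architectures)
        return d


def build_simulated_table(sim: dict, seed: int) -> tuple[HaplotypeTable, list[PopulationModel]]:
    """Materialize a simulation recipe dict into a labeled table.

    Recipe keys: ``n_populations``, ``n_per_population``,
    ``alleles_per_locus``, ``concentration``, ``missing_rate``,
    ``microvariant_prob``, optional ``overlap`` = [popA, popB, alpha]
    replacing popA by an admixture blend of the two base models, and an
    optional explicit ``panel`` dict.
    """
    panel = MarkerPanel.from_dict(sim["panel"]) if "panel" in sim else DEFAULT_PANEL
    n_pops = int(sim.get("n_populations", 7))
    names = [f"POP{i + 1}" for i in range(n_pops)]
    models = [
        sample_population_model(
            panel,
            int(sim.get("alleles_per_locus", 6)),
            float(sim.get("concentration", 1.0)),
            seed=seed * 1000 + i,
            name=names[i],
            microvariant_prob=float(sim.get("microvariant_prob", 0.1)),
        )
        for i in range(n_pops)
    ]
    if "overlap" in sim and sim["overlap"]:
        a_name, b_name, alpha = sim["overlap"]
        idx = {m.name: i for i, m in enumerate(models)}
        a, b = models[idx[a_name]], models[idx[b_name]]
        models[idx[a_name]] = mix_populations(b, a, float(alpha), a_name)
    n_per = sim.get("n_per_population", 220)
    if isinstance(n_per, int):
        n_per = {name: n_per for name in names}
    cfg = SimulationConfig(
        panel=panel,
        populations=models,
        n_per_population={k: int(v) for k, v in n_per.items()},
        missing_rate=float(sim.get("missing_rate", 0.0)),
        seed=seed,
    )
    return generate_table(cfg), models


def _evaluate(results, test: HaplotypeTable) -> dict:
    predicted = results.predict(test)
    cm = confusion(test.populations, predicted, results.encoding)
    rep = report(cm)
    return {
        "n_classifiers": results.n_classifiers,
        "accuracy": rep.accuracy,
        "report": rep.to_dict(),
        "confusion": {
            "classes": list(cm.classes),
            "counts": cm.counts.tolist(),
        },
        "misclassification_summary": [
            list(c) for c in misclassification_summary(cm, top_n=5)
        ],
    }


def run_experiment(config: RunConfig):
    """Execute the configured pipeline end-to-end.

    Returns (report dict, artifacts dict); the artifacts hold the fitted
    Results objects and the split tables for further inspection. With
    ``config.output_dir`` set, the report, manifest, split tables and
    fitted models are also written there.
    """
    if config.table_path is not None:
        panel = (MarkerPanel.from_json(config.panel_path)
                 if config.panel_path else DEFAULT_PANEL)
        table = read_haplotype_table(config.table_path, panel)
        models = None
    else:
        table, models = build_simulated_table(config.simulate, config.seed)

    logger.info("input table: %d profiles", len(table))
    complete = filter_complete(table)
    # feature space fixed on the pre-split complete table (encode-then-
    # split order), so held-out profiles never carry unseen alleles
    vocab = build_vocabulary(complete)
    logger.info("after missing-call filter: %d profiles", len(complete))
    split = stratified_split(complete, config.train_fraction, config.seed)
    train = downsample_to_min(split.train, config.seed) if config.balance else split.train
    logger.info("train: %d (balanced=%s)  test: %d",
                len(train), config.balance, len(split.test))

    meta_cfg = MetaNetworkConfig(**{"seed": config.seed, **config.meta})
    spec = BinaryClassifierSpec(config.expert_algorithm, seed=config.seed)

    rep: dict = {
        "config": config.to_dict(),
        "versions": {"ystr_ancestry": __version__},
        "n_input": len(table),
        "n_complete": len(complete),
        "n_train": len(train),
        "n_test": len(split.test),
        "architectures": {},
    }
    artifacts: dict = {"train": train, "test": split.test, "true_models": models}

    if "ovr" in config.architectures:
        model = OvRAttentionModel(
            train,
            specs=None if config.tune else {p: spec for p in set(train.populations)},
            tune_budget=config.tune_budget,
            calibration_folds=config.calibration_folds,
            temperature=config.temperature,
            meta_config=meta_cfg,
            feature_mode=config.feature_mode,
            vocab=vocab,
            seed=config.seed,
        )
        res = model.fit()
        rep["architectures"]["ovr"] = _evaluate(res, split.test)
        rep["architectures"]["ovr"]["attention_weights"] = {
            e.population: float(w)
            for e, w in zip(res.experts, res.attention.weights)
        }
        artifacts["ovr"] = res

    if "ovo" in config.architectures:
        model = OvOStackingModel(
            train, spec=spec,
            calibration_folds=config.calibration_folds,
            meta_config=meta_cfg,
            feature_mode=config.feature_mode,
            vocab=vocab,
            seed=config.seed,
        )
        res = model.fit()
        rep["architectures"]["ovo"] = _evaluate(res, split.test)
        pam = res.pairwise_accuracy(split.test)
        rep["architectures"]["ovo"]["pairwise_accuracy"] = {
            "classes": list(pam.classes),
            "values": [[None if not np.isfinite(v) else float(v) for v in row]
                       for row in pam.values],
        }
        artifacts["ovo"] = res

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_haplotype_table(train, out / "train.csv")
        write_haplotype_table(split.test, out / "test.csv")
        (out / "report.json").write_text(json.dumps(rep, indent=1, sort_keys=True))
        (out / "manifest.json").write_text(json.dumps(
            {"config": config.to_dict(), "versions": rep["versions"]},
            indent=1, sort_keys=True))
        for arch in ("ovr", "ovo"):
            if arch in artifacts:
                save_results(artifacts[arch], out / f"model_{arch}")
    return rep, artifacts


def compare_architectures(config: RunConfig):
    """Train both architectures on the identical split and report
    side-by-side metrics, counts and the pairwise-accuracy matrix."""
    if set(config.architectures) != {"ovr", "ovo"}:
        raise ConfigError("comparison requires architectures = ('ovr', 'ovo')")
    rep, artifacts = run_experiment(config)
    k = artifacts["ovr"].k
    rep["comparison"] = {
        "k": k,
        "classifier_counts": {
            "ovr": count_classifiers(k, "ovr"),
            "ovo": count_classifiers(k, "ovo"),
        },
        "accuracy": {
            "ovr": rep["architectures"]["ovr"]["accuracy"],
            "ovo": rep["architectures"]["ovo"]["accuracy"],
        },
    }
    if config.output_dir:
        (Path(config.output_dir) / "report.json").write_text(
            json.dumps(rep, indent=1, sort_keys=True)
        )
    return rep, artifacts


# ---------------------------------------------------------------------------
# model persistence: JSON manifest for everything auditable + joblib for
# the fitted estimators

def save_results(results, path: str | Path) -> None:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": type(results).__name__,
        "classes": list(results.encoding.classes),
        "vocabulary": results.vocab.to_dict(),
        "versions": {"ystr_ancestry": __version__},
    }
    if hasattr(results, "attention"):
        manifest["attention_weights"] = results.attention.weights.tolist()
        manifest["experts"] = [
            {
                "population": e.population,
                "algorithm": e.spec.algorithm,
                "hyperparameters": e.spec.hyperparameters,
                "seed": e.spec.seed,
                "calibration": {"A": e.calibration.A, "B": e.calibration.B},
                "oof_balanced_accuracy": e.oof_balanced_accuracy,
                "mi_score": e.mi_score,
            }
            for e in results.experts
        ]
    else:
        manifest["experts"] = [
            {
                "pair": list(e.pair),
                "algorithm": e.spec.algorithm,
                "calibration": {"A": e.calibration.A, "B": e.calibration.B},
                "n_train": e.n_train,
            }
            for e in results.experts
        ]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    joblib.dump(results, out / "model.joblib")


def load_results(path: str | Path):
    return joblib.load(Path(path) / "model.joblib")
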