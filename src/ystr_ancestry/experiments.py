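"""Canned simulation experiments that probe the classifier architectures.

Each experiment is a self-contained study design with known ground truth:

* **separable ceiling** — populations with pairwise-disjoint allele
  supports; any competent classifier should reach ~100% accuracy, so the
  full pipeline is checked against that ceiling.
* **null floor** — identically distributed populations; no method can
  beat chance, so accuracy should sit at 1/k within binomial noise.
* **admixture echo** — three populations where exactly one is an
  admixture blend of another (the Han–Hui situation in miniature): the
  blended pair should surface as the minimum of the pairwise-accuracy
  matrix and as the dominant confusion-matrix error cell.
* **planted allele** — one population carries a private allele; the
  per-population importance ranking should recover it as the top
  feature.

All randomness is derived from the caller's seed; replicate seeds stay
below 2**31.
"""

from __future__ import annotations

import numpy as np

from .base import BinaryClassifierSpec
from .calibration import CalibrationParams
from .evaluate import confusion, importance_ranking, misclassification_summary
from .features import build_vocabulary, one_hot_encode
from .metanet import MetaNetworkConfig
from .ovo import OvOStackingModel
from .ovr import OvRAttentionModel, OvRExpert
from .panel import DEFAULT_PANEL, MarkerPanel
from .preprocess import downsample_to_min, encode_labels, stratified_split
from .simulate import (
    PopulationModel,
    SimulationConfig,
    generate_table,
    mix_populations,
    sample_population_model,
    separable_models,
)

#: Base-classifier family and meta-network sizing used by the canned
#: experiments; the designs are all low-dimensional enough that a
#: regularized linear expert and a small (32, 16) network are fully
#: adequate, keeping replicate loops cheap.
def _spec(seed: int) -> BinaryClassifierSpec:
    return BinaryClassifierSpec("logistic_regression", seed=seed % (2**31 - 1))


def _meta(seed: int) -> MetaNetworkConfig:
    return MetaNetworkConfig(hidden_sizes=(32, 16), epochs=200,
                             learning_rate=0.01, seed=seed % (2**31 - 1))


#: Reduced screening panel for the admixture-echo design: the first nine
#: loci of the default panel (10 locus-copies). With fewer loci the
#: admixture signal dominates sampling noise instead of being washed out
#: by a highly informative marker battery.
ECHO_PANEL = MarkerPanel(DEFAULT_PANEL.loci[:9], {"DYS385ab": 2})


def _fit_both(table, seed, architectures=("ovr", "ovo")):
    vocab = build_vocabulary(table)
    split = stratified_split(table, 0.8, seed)
    train = downsample_to_min(split.train, seed)
    spec = _spec(seed)
    out = {}
    if "ovr" in architectures:
        out["ovr"] = OvRAttentionModel(
            train, specs={p: spec for p in set(train.populations)},
            meta_config=_meta(seed), vocab=vocab, seed=seed % (2**31 - 1),
        ).fit()
    if "ovo" in architectures:
        out["ovo"] = OvOStackingModel(
            train, spec=spec, meta_config=_meta(seed), vocab=vocab,
            seed=seed % (2**31 - 1),
        ).fit()
    return out, split


def separable_ceiling(seed: int, k: int = 7, n_per_class: int = 220) -> dict:
    """Accuracy of both architectures on disjoint-support populations."""
    models = separable_models(DEFAULT_PANEL, k, alleles_per_locus=3, seed=seed)
    table = generate_table(SimulationConfig(
        DEFAULT_PANEL, models, {m.name: n_per_class for m in models}, seed=seed))
    fitted, split = _fit_both(table, seed)
    truth = np.array(split.test.populations)
    return {
        "accuracy_ovr": float(np.mean(np.array(fitted["ovr"].predict(split.test)) == truth)),
        "accuracy_ovo": float(np.mean(np.array(fitted["ovo"].predict(split.test)) == truth)),
        "n_classifiers_ovr": fitted["ovr"].n_classifiers,
        "n_classifiers_ovo": fitted["ovo"].n_classifiers,
        "n_test": len(split.test),
        "k": k,
    }


def null_floor(seed: int, k: int = 7, n_per_class: int = 220) -> dict:
    """Accuracy of the attention ensemble when all populations share one
    allele-frequency model (pure chance)."""
    base = sample_population_model(DEFAULT_PANEL, 6, 1.0, seed=seed, name="base")
    models = [PopulationModel(name=f"POP{i + 1}", freqs=base.freqs)
              for i in range(k)]
    table = generate_table(SimulationConfig(
        DEFAULT_PANEL, models, {m.name: n_per_class for m in models}, seed=seed))
    fitted, split = _fit_both(table, seed, architectures=("ovr",))
    truth = np.array(split.test.populations)
    acc = float(np.mean(np.array(fitted["ovr"].predict(split.test)) == truth))
    n = len(split.test)
    return {
        "accuracy": acc,
        "chance": 1.0 / k,
        "n_test": n,
        "band": 3.0 * float(np.sqrt((1 / k) * (1 - 1 / k) / n)),
    }


def admixture_echo_replicate(seed: int, n_per_class: int = 300) -> dict:
    """One replicate of the blended-pair design.

    POP2's model is 0.6·POP1 + 0.4·(its own base model); POP1 and POP3
    stay unblended. Returns whether the blended pair is the minimum
    off-diagonal of the pairwise-accuracy matrix and whether it hosts
    the largest misclassification cell of both architectures.
    """
    models = [
        sample_population_model(ECHO_PANEL, 6, 1.5, seed=seed * 10 + i,
                                name=f"POP{i + 1}")
        for i in range(3)
    ]
    models[1] = mix_populations(models[0], models[1], 0.6, "POP2")
    table = generate_table(SimulationConfig(
        ECHO_PANEL, models, {m.name: n_per_class for m in models}, seed=seed))
    fitted, split = _fit_both(table, seed)
    pam = fitted["ovo"].pairwise_accuracy(split.test)
    min_is_blended = set(pam.min_pair()) == {"POP1", "POP2"}
    top_is_blended = True
    for res in fitted.values():
        cm = confusion(split.test.populations, res.predict(split.test),
                       res.encoding)
        cells = misclassification_summary(cm, top_n=1)
        top_is_blended &= bool(cells) and set(cells[0][:2]) == {"POP1", "POP2"}
    return {
        "min_pair_is_blended": bool(min_is_blended),
        "top_cell_is_blended": bool(top_is_blended),
        "blended_pair_accuracy": float(pam.values[0, 1]),
    }


def admixture_echo(seed: int, n_replicates: int = 20) -> dict:
    """Replicate rates for the blended-pair structural echo."""
    reps = [admixture_echo_replicate(seed * 100 + r) for r in range(n_replicates)]
    return {
        "min_pair_rate": float(np.mean([r["min_pair_is_blended"] for r in reps])),
        "top_cell_rate": float(np.mean([r["top_cell_is_blended"] for r in reps])),
        "n_replicates": n_replicates,
    }


def planted_allele_replicate(
    seed: int, n_per_class: int = 220, private_freq: float = 0.8
) -> bool:
    """One replicate: does the importance ranking put the planted private
    allele first for its population?

    Three populations share a base model; POP2 carries allele "30" at
    one locus at frequency ``private_freq`` (absent elsewhere). The
    POP2-vs-rest expert is a random forest, whose impurity importances
    feed the ranking.
    """
    base = sample_population_model(DEFAULT_PANEL, 6, 1.0, seed=seed, name="base")
    locus = DEFAULT_PANEL.locus_copies[4]
    models = []
    for i in range(3):
        freqs = {lc: dict(d) for lc, d in base.freqs.items()}
        if i == 1:
            d = {a: f * (1 - private_freq) for a, f in freqs[locus].items()}
            d["30"] = private_freq
            total = sum(d.values())
            freqs[locus] = {a: f / total for a, f in d.items()}
        models.append(PopulationModel(name=f"POP{i + 1}", freqs=freqs))
    table = generate_table(SimulationConfig(
        DEFAULT_PANEL, models, {m.name: n_per_class for m in models}, seed=seed))
    vocab = build_vocabulary(table)
    enc = encode_labels(table)
    X = one_hot_encode(table, vocab).values.astype(float)
    y_bin = (enc.encode(table.populations) == enc.to_int("POP2")).astype(int)
    spec = BinaryClassifierSpec("random_forest", seed=seed % (2**31 - 1))
    est = spec.build().fit(X, y_bin)
    expert = OvRExpert("POP2", spec, est, CalibrationParams(-1.0, 0.0), 1.0, 1.0)
    ranking = importance_ranking([expert], vocab, X.std(axis=0))
    return ranking["POP2"][0][0] == f"{locus}_30"


def planted_allele_recovery(seed: int, n_replicates: int = 20) -> dict:
    """Fraction of replicates recovering the planted allele at rank 1."""
    hits = [planted_allele_replicate(seed * 100 + r) for r in range(n_replicates)]
    return {"top1_rate": float(np.mean(hits)), "n_replicates": n_replicates}
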