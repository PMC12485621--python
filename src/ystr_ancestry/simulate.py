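"""Synthetic Y-STR population simulator.

Generates haplotype tables with the statistical structure the classifiers
assume: each population is a set of per-locus-copy categorical allele
distributions (drawn from a symmetric Dirichlet), loci are independent
given the population, and admixture between a designated pair of
populations is emulated by mixing their frequency vectors. Microvariant
alleles ("13.2") and missing calls are generated on demand.

The simulator deliberately has no coalescent or mutation-model realism;
see the methods note for what that implies about test conclusions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import MISSING, HaplotypeTable, YSTRProfile, allele_sort_key, canonical_allele
from .panel import MarkerPanel


class SimulationError(ValueError):
    """Invalid simulation parameters or mismatched models."""


@dataclass
class PopulationModel:
    """Per-locus-copy categorical allele distributions for one population."""

    name: str
    freqs: dict[str, dict[str, float]]  # locus-copy -> allele -> frequency

    def __post_init__(self) -> None:
        for lc, dist in self.freqs.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(
                    f"{self.name}/{lc}: frequencies sum to {total}, not 1"
                )
            if any(f < 0 for f in dist.values()):
                raise SimulationError(f"{self.name}/{lc}: negative frequency")
            for allele in dist:
                if canonical_allele(allele) != allele:
                    raise SimulationError(
                        f"{self.name}/{lc}: allele {allele!r} not canonical"
                    )

    def to_dict(self) -> dict:
        return {"name": self.name, "freqs": self.freqs}

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(d["name"], {lc: dict(v) for lc, v in d["freqs"].items()})


@dataclass
class SimulationConfig:
    panel: MarkerPanel
    populations: list[PopulationModel]
    n_per_population: dict[str, int]
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise SimulationError("missing_rate must be in [0, 1]")
        for name, n in self.n_per_population.items():
            if n < 0:
                raise SimulationError(f"negative count for {name!r}")


def _allele_labels(
    rng: np.random.Generator,
    n_alleles: int,
    repeat_range: tuple[int, int],
    microvariant_prob: float,
) -> list[str]:
    """Draw distinct allele labels from a realistic repeat-count range,
    each independently promoted to a microvariant (.2) with the given
    probability."""
    lo, hi = repeat_range
    span = hi - lo + 1
    if n_alleles > 2 * span:
        raise SimulationError(
            f"cannot draw {n_alleles} distinct alleles from repeats {lo}..{hi}"
        )
    labels: set[str] = set()
    while len(labels) < n_alleles:
        base = int(rng.integers(lo, hi + 1))
        label = f"{base}.2" if rng.random() < microvariant_prob else str(base)
        labels.add(label)
    return sorted(labels, key=allele_sort_key)


def sample_population_model(
    panel: MarkerPanel,
    alleles_per_locus: int,
    concentration: float,
    seed: int,
    *,
    name: str = "pop",
    repeat_range: tuple[int, int] = (8, 20),
    microvariant_prob: float = 0.1,
) -> PopulationModel:
    """Draw a population model with symmetric-Dirichlet allele frequencies.

    Each locus-copy independently gets ``alleles_per_locus`` distinct
    allele labels from ``repeat_range`` (with a ``microvariant_prob``
    chance each of being a ".2" microvariant) and a frequency vector drawn
    from Dirichlet(concentration, ..., concentration). Deterministic given
    ``seed``.
    """
    if alleles_per_locus < 1:
        raise SimulationError("alleles_per_locus must be >= 1")
    if concentration <= 0:
        raise SimulationError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    freqs: dict[str, dict[str, float]] = {}
    for lc in panel.locus_copies:
        labels = _allele_labels(rng, alleles_per_locus, repeat_range, microvariant_prob)
        if alleles_per_locus == 1:
            probs = np.array([1.0])
        else:
            probs = rng.dirichlet(np.full(alleles_per_locus, concentration))
            probs = probs / probs.sum()
        freqs[lc] = {a: float(p) for a, p in zip(labels, probs)}
    return PopulationModel(name=name, freqs=freqs)


def mix_populations(
    a: PopulationModel, b: PopulationModel, alpha: float, name: str
) -> PopulationModel:
    """Admixture blend: alpha·a + (1−alpha)·b over the union of supports."""
    if set(a.freqs) != set(b.freqs):
        raise SimulationError(
            f"models {a.name!r} and {b.name!r} cover different locus-copies"
        )
    if not 0.0 <= alpha <= 1.0:
        raise SimulationError("alpha must be in [0, 1]")
    freqs: dict[str, dict[str, float]] = {}
    for lc in a.freqs:
        support = set(a.freqs[lc]) | set(b.freqs[lc])
        dist = {
            al: alpha * a.freqs[lc].get(al, 0.0) + (1 - alpha) * b.freqs[lc].get(al, 0.0)
            for al in sorted(support, key=allele_sort_key)
        }
        total = sum(dist.values())
        freqs[lc] = {al: f / total for al, f in dist.items()}
    return PopulationModel(name=name, freqs=freqs)


def generate_table(config: SimulationConfig) -> HaplotypeTable:
    """Draw profiles per population from its categorical distributions.

    Loci are independent given the population; multi-copy calls are
    stored in nondecreasing numeric order; each call is independently
    replaced by MISSING with probability ``missing_rate``. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    groups: dict[str, list[str]] = {}
    for lc, locus in panel.copy_group().items():
        groups.setdefault(locus, []).append(lc)

    profiles: list[YSTRProfile] = []
    for pop in config.populations:
        n = config.n_per_population.get(pop.name, 0)
        for i in range(n):
            calls: dict[str, str | None] = {}
            for locus, lcs in groups.items():
                drawn: list[str] = []
                for lc in lcs:
                    dist = pop.freqs[lc]
                    alleles = list(dist)
                    probs = np.array([dist[a] for a in alleles])
                    drawn.append(alleles[rng.choice(len(alleles), p=probs)])
                if len(drawn) > 1:
                    drawn.sort(key=allele_sort_key)
                for lc, v in zip(lcs, drawn):
                    calls[lc] = v
            if config.missing_rate > 0:
                for lc in panel.locus_copies:
                    if rng.random() < config.missing_rate:
                        calls[lc] = MISSING
            profiles.append(
                YSTRProfile(
                    sample_id=f"{pop.name}_{i:05d}",
                    calls=calls,
                    population=pop.name,
                )
            )
    return HaplotypeTable(panel, profiles)


def separable_models(
    panel: MarkerPanel,
    k: int,
    alleles_per_locus: int = 3,
    seed: int = 0,
    *,
    base_repeat: int = 6,
) -> list[PopulationModel]:
    """k population models with pairwise-disjoint allele supports at every
    locus-copy: population i draws only from its own block of repeat
    counts. Any two such populations are perfectly classifiable by a
    single-feature rule, which downstream tests use as a separability
    oracle."""
    rng = np.random.default_rng(seed)
    models = []
    for i in range(k):
        lo = base_repeat + i * alleles_per_locus
        labels = [str(lo + a) for a in range(alleles_per_locus)]
        freqs = {}
        for lc in panel.locus_copies:
            probs = rng.dirichlet(np.ones(alleles_per_locus))
            freqs[lc] = {a: float(p) for a, p in zip(labels, probs / probs.sum())}
        models.append(PopulationModel(name=f"POP{i + 1}", freqs=freqs))
    return models


def save_models(models: list[PopulationModel], path: str | Path) -> None:
    """Write the true population models as a JSON sidecar."""
    Path(path).write_text(
        json.dumps([m.to_dict() for m in models], indent=1, sort_keys=True)
    )


def load_models(path: str | Path) -> list[PopulationModel]:
    return [PopulationModel.from_dict(d) for d in json.loads(Path(path).read_text())]
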