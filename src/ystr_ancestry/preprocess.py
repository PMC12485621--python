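"""Quality control and partitioning.

The pipeline order is: drop profiles with any missing call, split
80:20 stratified by population, then downsample the *training* partition
so every class matches the smallest class — equal representation during
training while the test partition keeps its natural proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import HaplotypeTable


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class LabelEncoding:
    """Deterministic (lexicographic) population-name <-> integer bijection."""

    classes: tuple[str, ...]

    @classmethod
    def from_names(cls, names) -> "LabelEncoding":
        return cls(tuple(sorted(set(names))))

    @property
    def k(self) -> int:
        return len(self.classes)

    def to_int(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise PreprocessError(f"unknown population {name!r}") from None

    def to_name(self, idx: int) -> str:
        return self.classes[idx]

    def encode(self, names) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.array([index[n] for n in names], dtype=np.int64)
        except KeyError as exc:
            raise PreprocessError(f"unknown population {exc.args[0]!r}") from None


@dataclass
class SplitResult:
    train: HaplotypeTable
    test: HaplotypeTable
    seed: int


def filter_complete(table: HaplotypeTable) -> HaplotypeTable:
    """Keep only profiles with zero missing calls, order preserved."""
    return HaplotypeTable(
        table.panel, [p for p in table.profiles if p.is_complete()]
    )


def encode_labels(table: HaplotypeTable) -> LabelEncoding:
    """Build the integer label encoding from a fully labeled table."""
    for p in table.profiles:
        if p.population is None:
            raise PreprocessError(f"sample {p.sample_id!r} has no population label")
    return LabelEncoding.from_names(p.population for p in table.profiles)


def _per_class_train_counts(
    sizes: dict[str, int], train_fraction: float
) -> dict[str, int]:
    """Largest-remainder apportionment of the global train count across
    classes, ties broken by class name order; every class keeps at least
    one sample on each side of the split."""
    names = sorted(sizes)
    total = sum(sizes.values())
    target = int(np.floor(train_fraction * total + 0.5))  # round-half-up
    base = {c: int(np.floor(train_fraction * sizes[c])) for c in names}
    base = {c: min(max(b, 1), sizes[c] - 1) for c, b in base.items()}
    remainder = target - sum(base.values())
    frac = sorted(
        names,
        key=lambda c: (-(train_fraction * sizes[c] - np.floor(train_fraction * sizes[c])), c),
    )
    i = 0
    while remainder > 0 and i < 10 * len(names):
        c = frac[i % len(names)]
        if base[c] < sizes[c] - 1:
            base[c] += 1
            remainder -= 1
        i += 1
    i = 0
    while remainder < 0 and i < 10 * len(names):
        c = frac[-1 - (i % len(names))]  # smallest fractional parts first
        if base[c] > 1:
            base[c] -= 1
            remainder += 1
        i += 1
    return base


def stratified_split(
    table: HaplotypeTable, train_fraction: float, seed: int
) -> SplitResult:
    """Disjoint, exhaustive, per-class proportional train/test split."""
    if not 0.0 < train_fraction < 1.0:
        raise PreprocessError("train_fraction must be in (0, 1)")
    by_class: dict[str, list[int]] = {}
    for i, p in enumerate(table.profiles):
        if p.population is None:
            raise PreprocessError(f"sample {p.sample_id!r} has no population label")
        by_class.setdefault(p.population, []).append(i)
    for c, idxs in by_class.items():
        if len(idxs) < 2:
            raise PreprocessError(
                f"class {c!r} has {len(idxs)} sample(s); at least 2 required"
            )
    sizes = {c: len(idxs) for c, idxs in by_class.items()}
    train_counts = _per_class_train_counts(sizes, train_fraction)

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in sorted(by_class):
        idxs = np.array(by_class[c])
        perm = rng.permutation(len(idxs))
        n_train = train_counts[c]
        train_idx.extend(idxs[perm[:n_train]].tolist())
        test_idx.extend(idxs[perm[n_train:]].tolist())
    train_idx.sort()
    test_idx.sort()
    return SplitResult(
        train=table.subset(train_idx), test=table.subset(test_idx), seed=seed
    )


def downsample_to_min(table: HaplotypeTable, seed: int) -> HaplotypeTable:
    """Uniformly downsample every class (without replacement) to the size
    of the smallest class; original profile order is preserved."""
    by_class: dict[str, list[int]] = {}
    for i, p in enumerate(table.profiles):
        if p.population is None:
            raise PreprocessError(f"sample {p.sample_id!r} has no population label")
        by_class.setdefault(p.population, []).append(i)
    if not by_class:
        return HaplotypeTable(table.panel, [])
    m = min(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for c in sorted(by_class):
        idxs = np.array(by_class[c])
        chosen = rng.choice(len(idxs), size=m, replace=False)
        keep.extend(idxs[chosen].tolist())
    keep.sort()
    return table.subset(keep)
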