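"""One-hot allele encoding and mutual-information feature selection.

Every (locus-copy, allele) pair observed in the training data becomes one
binary feature named ``LOCUS_ALLELE`` (e.g. ``DYS439_10``, ``DYS385a_13.2``).
A complete profile activates exactly one feature per locus-copy, so row
sums always equal the panel's locus-copy count — a cheap structural
invariant the tests lean on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import HaplotypeTable, allele_sort_key
from .panel import MarkerPanel

logger = logging.getLogger(__name__)


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleVocabulary:
    """Ordered (locus-copy, allele) pairs defining the binary feature space.

    Ordering is deterministic: panel locus-copy order, then numeric
    allele order within each locus-copy.
    """

    panel: MarkerPanel
    entries: tuple[tuple[str, str], ...]

    @property
    def feature_names(self) -> list[str]:
        return [f"{lc}_{allele}" for lc, allele in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def index(self) -> dict[tuple[str, str], int]:
        return {e: i for i, e in enumerate(self.entries)}

    def to_dict(self) -> dict:
        return {"panel": self.panel.to_dict(), "entries": [list(e) for e in self.entries]}

    @classmethod
    def from_dict(cls, d: dict) -> "AlleleVocabulary":
        return cls(
            MarkerPanel.from_dict(d["panel"]),
            tuple((lc, a) for lc, a in d["entries"]),
        )

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "AlleleVocabulary":
        import json
        from pathlib import Path

        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FeatureMatrix:
    """Binary sample × feature matrix with row and column labels."""

    values: np.ndarray  # (n_samples, n_features) of {0, 1}
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise EncodingError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise EncodingError("feature_names length mismatch")
        if self.values.shape[0] != len(self.sample_ids):
            raise EncodingError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="SampleID")


def build_vocabulary(table: HaplotypeTable) -> AlleleVocabulary:
    """Union of observed (locus-copy, allele) pairs, deterministically
    ordered. The table must be complete (run filter_complete first)."""
    observed: dict[str, set[str]] = {lc: set() for lc in table.panel.locus_copies}
    for p in table.profiles:
        for lc, allele in p.calls.items():
            if allele is None:
                raise EncodingError(
                    f"sample {p.sample_id!r} has a missing call at {lc}; "
                    "vocabulary requires a complete table"
                )
            observed[lc].add(allele)
    entries = tuple(
        (lc, allele)
        for lc in table.panel.locus_copies
        for allele in sorted(observed[lc], key=allele_sort_key)
    )
    return AlleleVocabulary(panel=table.panel, entries=entries)


def one_hot_encode(
    table: HaplotypeTable,
    vocab: AlleleVocabulary,
    *,
    on_unseen: str = "error",
) -> FeatureMatrix:
    """Encode a complete table against a fitted vocabulary.

    ``on_unseen`` controls alleles absent from the vocabulary: ``"error"``
    (default — unseen alleles change row sums silently otherwise) or
    ``"zero"``, which leaves the locus-copy all-zero and logs a warning.
    """
    if on_unseen not in ("error", "zero"):
        raise ValueError("on_unseen must be 'error' or 'zero'")
    index = vocab.index()
    X = np.zeros((len(table.profiles), len(vocab)), dtype=np.int8)
    for i, p in enumerate(table.profiles):
        for lc in table.panel.locus_copies:
            allele = p.calls[lc]
            if allele is None:
                raise EncodingError(
                    f"sample {p.sample_id!r} has a missing call at {lc}"
                )
            j = index.get((lc, allele))
            if j is None:
                if on_unseen == "error":
                    raise EncodingError(
                        f"sample {p.sample_id!r}: allele {allele!r} at {lc} "
                        "not in the training vocabulary"
                    )
                logger.warning(
                    "sample %r: unseen allele %r at %s encoded as all-zeros",
                    p.sample_id, allele, lc,
                )
            else:
                X[i, j] = 1
    return FeatureMatrix(
        values=X, feature_names=vocab.feature_names, sample_ids=table.sample_ids
    )


def mutual_information(feature_column: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in mutual information (nats) between a binary feature and an
    integer label vector, with 0·log 0 := 0. No bias correction."""
    x = np.asarray(feature_column)
    y = np.asarray(labels)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature_column and labels must be equal-length 1-D")
    if x.size == 0:
        raise ValueError("need at least one sample")
    n = x.size
    xs = np.unique(x)
    ys = np.unique(y)
    mi = 0.0
    for xv in xs:
        px = np.count_nonzero(x == xv) / n
        for yv in ys:
            pxy = np.count_nonzero((x == xv) & (y == yv)) / n
            if pxy > 0:
                py = np.count_nonzero(y == yv) / n
                mi += pxy * np.log(pxy / (px * py))
    return max(mi, 0.0)


def binary_mi_per_column(X: np.ndarray, y_bin: np.ndarray) -> np.ndarray:
    """Vectorized plug-in MI (nats) of each binary column against a
    binary target; agrees with :func:`mutual_information` column-wise."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_bin, dtype=float)
    n = y.size
    n1 = X.sum(axis=0)
    n11 = y @ X
    ny1 = y.sum()
    cells = np.stack([
        n - n1 - (ny1 - n11),  # x=0, y=0
        ny1 - n11,             # x=0, y=1
        n1 - n11,              # x=1, y=0
        n11,                   # x=1, y=1
    ])
    px = np.stack([n - n1, n - n1, n1, n1]) / n
    py = np.array([n - ny1, ny1, n - ny1, ny1])[:, None] / n
    p = cells / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (px * py)), 0.0)
    return np.maximum(terms.sum(axis=0), 0.0)


def label_entropy(labels: np.ndarray) -> float:
    """Empirical Shannon entropy of the labels (nats)."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    p = counts / y.size
    return float(-(p * np.log(p)).sum())


def select_one_per_marker(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    vocab: AlleleVocabulary,
) -> tuple[FeatureMatrix, AlleleVocabulary]:
    """Retain, per locus-copy, the single allele feature with the highest
    mutual information against the labels (ties broken toward the lowest
    numeric allele). Output width equals the panel's locus-copy count.

    This is the dimensionality-reduction option used for sensitivity
    analysis; the default pipeline keeps the full one-hot matrix.
    """
    if len(vocab) != matrix.n_features:
        raise EncodingError("matrix and vocabulary disagree on feature count")
    y = np.asarray(labels)
    keep: list[int] = []
    by_locus: dict[str, list[int]] = {}
    for j, (lc, _) in enumerate(vocab.entries):
        by_locus.setdefault(lc, []).append(j)
    for lc in vocab.panel.locus_copies:
        cols = by_locus.get(lc, [])
        if not cols:
            continue
        # ties -> lowest numeric allele; columns are already in numeric
        # allele order inside a locus, so a strict '>' scan suffices
        best_j, best_mi = cols[0], -1.0
        for j in cols:
            mi = mutual_information(matrix.values[:, j], y)
            if mi > best_mi + 1e-15:
                best_j, best_mi = j, mi
        keep.append(best_j)
    sub_entries = tuple(vocab.entries[j] for j in keep)
    sub_vocab = AlleleVocabulary(panel=vocab.panel, entries=sub_entries)
    sub = FeatureMatrix(
        values=matrix.values[:, keep],
        feature_names=[matrix.feature_names[j] for j in keep],
        sample_ids=matrix.sample_ids,
    )
    return sub, sub_vocab
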