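"""Haplotype profiles, tables and CSV/TSV input-output.

Alleles are repeat counts reported as strings ("14", and microvariants
like "13.2" carrying a partial repeat unit). They are *categories*: the
pipeline never does arithmetic on them, only equality and a numeric sort
order. A missing call is ``None``, distinct from any allele including "0".
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .panel import MarkerPanel

#: Missing-call sentinel. Serialized as the empty string.
MISSING = None

#: Cell values interpreted as missing on read (case-insensitive).
DEFAULT_NA_TOKENS = frozenset({"", "na", "n/a", "nan", "null", "-", "."})

_ALLELE_RE = re.compile(r"^\d+(\.\d+)?$")


class FormatError(ValueError):
    """Malformed input file (bad header, unparseable cell)."""


class TableError(ValueError):
    """Inconsistent table-level state (panel mismatch, duplicate ids)."""


def canonical_allele(raw: str) -> str:
    """Normalize an allele string: strip whitespace and leading zeros,
    drop a zero fractional part ("013.0" -> "13", "13.20" -> "13.2").

    Raises
    ------
    FormatError
        If the string is not a nonnegative decimal number.
    """
    s = raw.strip()
    if not _ALLELE_RE.match(s):
        raise FormatError(f"unparseable allele string {raw!r}")
    if "." in s:
        whole, frac = s.split(".")
        frac = frac.rstrip("0")
        whole = whole.lstrip("0") or "0"
        return whole if not frac else f"{whole}.{frac}"
    return s.lstrip("0") or "0"


def allele_sort_key(allele: str) -> Fraction:
    """Exact numeric ordering key ("13" < "13.2" < "14")."""
    return Fraction(allele)


@dataclass
class YSTRProfile:
    """One male sample's haplotype: locus-copy -> allele string or MISSING."""

    sample_id: str
    calls: dict[str, str | None]
    population: str | None = None

    def is_complete(self) -> bool:
        return all(v is not None for v in self.calls.values())

    def missing_loci(self) -> list[str]:
        return [lc for lc, v in self.calls.items() if v is None]


@dataclass
class HaplotypeTable:
    """A panel-consistent, ordered collection of profiles."""

    panel: MarkerPanel
    profiles: list[YSTRProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        copies = set(self.panel.locus_copies)
        for p in self.profiles:
            if set(p.calls) != copies:
                raise TableError(
                    f"profile {p.sample_id!r} does not conform to the panel"
                )

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    @property
    def populations(self) -> list[str | None]:
        return [p.population for p in self.profiles]

    def subset(self, indices) -> "HaplotypeTable":
        return HaplotypeTable(self.panel, [self.profiles[i] for i in indices])


def _normalize_multicopy(table: HaplotypeTable) -> None:
    """Sort each multi-copy locus's calls into nondecreasing numeric order."""
    groups: dict[str, list[str]] = {}
    for lc, locus in table.panel.copy_group().items():
        groups.setdefault(locus, []).append(lc)
    multi = {locus: lcs for locus, lcs in groups.items() if len(lcs) > 1}
    for prof in table.profiles:
        for lcs in multi.values():
            vals = [prof.calls[lc] for lc in lcs]
            if any(v is None for v in vals):
                continue
            for lc, v in zip(lcs, sorted(vals, key=allele_sort_key)):
                prof.calls[lc] = v


def read_haplotype_table(
    path: str | Path,
    panel: MarkerPanel,
    *,
    delimiter: str | None = None,
    na_tokens: frozenset[str] = DEFAULT_NA_TOKENS,
) -> HaplotypeTable:
    """Read a YHRD-style haplotype table.

    Expected columns: ``SampleID``, optional ``Population``, then one
    column per locus-copy. A two-copy marker may appear either as split
    columns (``DYS385a``/``DYS385b``) or as a single comma-joined column
    under the parent locus name (``DYS385ab`` cell ``"11,14"``). Empty
    cells and ``na_tokens`` become missing calls. Multi-copy calls are
    normalized to nondecreasing numeric order.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if delimiter is None:
        header_line = text.splitlines()[0] if text.splitlines() else ""
        delimiter = "\t" if "\t" in header_line else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    if not rows:
        raise FormatError(f"{path}: empty file (no header)")
    header = [h.strip() for h in rows[0]]
    col = {name: i for i, name in enumerate(header)}

    if "SampleID" not in col:
        raise FormatError(f"{path}: missing required column 'SampleID'")
    pop_idx = col.get("Population")

    # Resolve each locus to either its split locus-copy columns or one
    # comma-joined column under the parent name.
    groups: dict[str, list[str]] = {}
    for lc, locus in panel.copy_group().items():
        groups.setdefault(locus, []).append(lc)
    plan: list[tuple[str, list[str], list[int] | int]] = []
    for locus, lcs in groups.items():
        if all(lc in col for lc in lcs):
            plan.append((locus, lcs, [col[lc] for lc in lcs]))
        elif locus in col:
            plan.append((locus, lcs, col[locus]))
        else:
            missing = lcs[0] if len(lcs) == 1 else f"{locus} (or {'/'.join(lcs)})"
            raise FormatError(f"{path}: missing required column for locus {missing}")

    na = {t.lower() for t in na_tokens}

    def parse_cell(cell: str, row_no: int) -> str | None:
        if cell.strip().lower() in na:
            return MISSING
        try:
            return canonical_allele(cell)
        except FormatError as exc:
            raise FormatError(f"{path}: row {row_no}: {exc}") from None

    profiles: list[YSTRProfile] = []
    for row_no, row in enumerate(rows[1:], start=2):
        if not any(c.strip() for c in row):
            continue
        calls: dict[str, str | None] = {}
        for locus, lcs, src in plan:
            if isinstance(src, int):
                cell = row[src] if src < len(row) else ""
                if cell.strip().lower() in na:
                    parts: list[str | None] = [MISSING] * len(lcs)
                else:
                    raw = [c for c in cell.split(",")]
                    if len(raw) != len(lcs):
                        raise FormatError(
                            f"{path}: row {row_no}: locus {locus} expects "
                            f"{len(lcs)} comma-joined calls, got {cell!r}"
                        )
                    parts = [parse_cell(c, row_no) for c in raw]
                for lc, v in zip(lcs, parts):
                    calls[lc] = v
            else:
                for lc, idx in zip(lcs, src):
                    cell = row[idx] if idx < len(row) else ""
                    calls[lc] = parse_cell(cell, row_no)
        sid = row[col["SampleID"]].strip()
        pop = None
        if pop_idx is not None and pop_idx < len(row):
            pop = row[pop_idx].strip() or None
        profiles.append(YSTRProfile(sample_id=sid, calls=calls, population=pop))

    table = HaplotypeTable(panel, profiles)
    _normalize_multicopy(table)
    return table


def write_haplotype_table(
    table: HaplotypeTable, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a table with split multi-copy columns; MISSING becomes ''."""
    path = Path(path)
    has_pop = any(p.population is not None for p in table.profiles)
    header = ["SampleID"] + (["Population"] if has_pop else []) + list(
        table.panel.locus_copies
    )
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(header)
        for p in table.profiles:
            row = [p.sample_id]
            if has_pop:
                row.append(p.population or "")
            row.extend(
                "" if p.calls[lc] is None else p.calls[lc]
                for lc in table.panel.locus_copies
            )
            w.writerow(row)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``kind`` is a stable machine-readable tag."""

    kind: str
    sample_id: str | None
    locus: str | None
    message: str


def validate_table(table: HaplotypeTable) -> list[Finding]:
    """Non-mutating sanity scan: missing calls, duplicate sample ids,
    unsorted multi-copy calls. Returns findings, never raises."""
    findings: list[Finding] = []

    seen: set[str] = set()
    for p in table.profiles:
        if p.sample_id in seen:
            findings.append(
                Finding("duplicate_id", p.sample_id, None,
                        f"duplicate sample id {p.sample_id!r}")
            )
        seen.add(p.sample_id)

    groups: dict[str, list[str]] = {}
    for lc, locus in table.panel.copy_group().items():
        groups.setdefault(locus, []).append(lc)
    multi = {locus: lcs for locus, lcs in groups.items() if len(lcs) > 1}

    for p in table.profiles:
        for lc in table.panel.locus_copies:
            if p.calls[lc] is None:
                findings.append(
                    Finding("missing_call", p.sample_id, lc,
                            f"sample {p.sample_id!r}: missing call at {lc}")
                )
        for locus, lcs in multi.items():
            vals = [p.calls[lc] for lc in lcs]
            if any(v is None for v in vals):
                continue
            keys = [allele_sort_key(v) for v in vals]
            if keys != sorted(keys):
                findings.append(
                    Finding("unsorted_multicopy", p.sample_id, locus,
                            f"sample {p.sample_id!r}: {locus} copies not in "
                            "nondecreasing order")
                )
    return findings
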