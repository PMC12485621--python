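"""Marker panel definition for Y-STR haplotype data.

A panel is an ordered list of loci with per-locus copy counts. Multi-copy
markers (DYS385ab is the common forensic case) are genotyped at two sites
and yield two allele calls per sample, conventionally reported in
nondecreasing order; the panel expands them into named locus-copies
(DYS385a, DYS385b) that the rest of the pipeline treats as independent
columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


class PanelError(ValueError):
    """Raised for malformed panel definitions."""


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered Y-STR locus panel with copy counts.

    Parameters
    ----------
    loci
        Ordered locus names, unique.
    multicopy
        Map locus name -> copy count for loci with more than one copy.
        Loci not listed have one copy.
    """

    loci: tuple[str, ...]
    multicopy: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise PanelError("locus names must be unique")
        object.__setattr__(self, "loci", tuple(self.loci))
        for locus, n in self.multicopy.items():
            if locus not in self.loci:
                raise PanelError(f"multicopy locus {locus!r} not in panel")
            if n < 1:
                raise PanelError(f"copy count for {locus!r} must be >= 1")

    def copies(self, locus: str) -> int:
        return self.multicopy.get(locus, 1)

    @property
    def locus_copies(self) -> tuple[str, ...]:
        """Expanded locus-copy names, in panel order.

        Single-copy loci keep their name. A locus named like "DYS385ab"
        with two copies expands to DYS385a / DYS385b (the conventional
        column names); other multi-copy loci get letter suffixes.
        """
        out: list[str] = []
        for locus in self.loci:
            n = self.copies(locus)
            if n == 1:
                out.append(locus)
            else:
                base = locus[:-2] if locus.endswith("ab") and n == 2 else locus
                out.extend(base + chr(ord("a") + i) for i in range(n))
        return tuple(out)

    def copy_group(self) -> dict[str, str]:
        """Map each locus-copy name back to its parent locus."""
        groups: dict[str, str] = {}
        idx = 0
        copies = self.locus_copies
        for locus in self.loci:
            for _ in range(self.copies(locus)):
                groups[copies[idx]] = locus
                idx += 1
        return groups

    @property
    def n_locus_copies(self) -> int:
        return sum(self.copies(locus) for locus in self.loci)

    def to_dict(self) -> dict:
        return {"loci": list(self.loci), "multicopy": dict(self.multicopy)}

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(tuple(d["loci"]), dict(d.get("multicopy", {})))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerPanel":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: The 20-locus forensic screening panel used as the built-in default:
#: DYS385ab is the single multi-copy marker, so the panel expands to 19
#: locus-copy columns.
DEFAULT_PANEL = MarkerPanel(
    loci=(
        "DYS19",
        "DYS385ab",
        "DYS389I",
        "DYS389II",
        "DYS390",
        "DYS391",
        "DYS392",
        "DYS393",
        "DYS437",
        "DYS438",
        "DYS439",
        "DYS448",
        "DYS487",
        "DYS533",
        "DYS570",
        "DYS576",
        "DYS635",
        "YGATAH4",
    ),
    multicopy={"DYS385ab": 2},
)
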