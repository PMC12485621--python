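import pytest

from ystr_ancestry.data import HaplotypeTable, YSTRProfile
from ystr_ancestry.panel import MarkerPanel


@pytest.fixture
def small_panel() -> MarkerPanel:
    """Three single-copy loci plus one two-copy marker (5 locus-copies)."""
    return MarkerPanel(
        loci=("DYS19", "DYS385ab", "DYS390", "DYS439"),
        multicopy={"DYS385ab": 2},
    )


@pytest.fixture
def single_copy_panel() -> MarkerPanel:
    return MarkerPanel(loci=("L1", "L2", "L3"))


def make_profile(panel: MarkerPanel, sample_id: str, alleles, population=None):
    """Build a profile from a list of calls in panel locus-copy order."""
    calls = dict(zip(panel.locus_copies, alleles))
    return YSTRProfile(sample_id=sample_id, calls=calls, population=population)


def make_table(panel: MarkerPanel, rows) -> HaplotypeTable:
    """rows: list of (sample_id, population, [alleles in locus-copy order])."""
    return HaplotypeTable(
        panel,
        [make_profile(panel, sid, alleles, pop) for sid, pop, alleles in rows],
    )
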