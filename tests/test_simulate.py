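"""Synthetic population models and table generation."""

import numpy as np
import pytest

from ystr_ancestry.data import allele_sort_key, validate_table, write_haplotype_table
from ystr_ancestry.simulate import (
    PopulationModel,
    SimulationConfig,
    SimulationError,
    generate_table,
    mix_populations,
    sample_population_model,
    separable_models,
)


class TestSamplePopulationModel:
    def test_single_allele_is_degenerate(self, small_panel):
        m = sample_population_model(small_panel, 1, 1.0, seed=0)
        for dist in m.freqs.values():
            assert list(dist.values()) == [1.0]

    def test_seed_determinism(self, small_panel):
        a = sample_population_model(small_panel, 4, 0.7, seed=11)
        b = sample_population_model(small_panel, 4, 0.7, seed=11)
        assert a.freqs == b.freqs

    def test_frequencies_sum_to_one(self, small_panel):
        m = sample_population_model(small_panel, 5, 0.3, seed=3)
        for dist in m.freqs.values():
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_high_concentration_is_near_uniform(self, small_panel):
        # Dirichlet(1000) with 5 categories concentrates near 0.2 each:
        # marginal sd = sqrt(0.2*0.8/5001) ~ 0.0057, so |f-0.2| < 0.05
        # holds with overwhelming probability across all locus-copies
        ms = [sample_population_model(small_panel, 5, 1000.0, seed=s)
              for s in range(20)]
        freqs = np.array([
            f for m in ms for dist in m.freqs.values() for f in dist.values()
        ])
        assert np.all(np.abs(freqs - 0.2) < 0.05)

    def test_invalid_parameters(self, small_panel):
        with pytest.raises(SimulationError):
            sample_population_model(small_panel, 0, 1.0, seed=0)
        with pytest.raises(SimulationError):
            sample_population_model(small_panel, 3, -1.0, seed=0)

    def test_microvariants_appear(self, small_panel):
        m = sample_population_model(small_panel, 8, 1.0, seed=5,
                                    microvariant_prob=0.5)
        alleles = {a for dist in m.freqs.values() for a in dist}
        assert any("." in a for a in alleles)


class TestMixPopulations:
    @pytest.mark.parametrize("alpha, expect_from", [(1.0, "a"), (0.0, "b")])
    def test_endpoints(self, small_panel, alpha, expect_from):
        a = sample_population_model(small_panel, 3, 1.0, seed=1, name="a")
        b = sample_population_model(small_panel, 3, 1.0, seed=2, name="b")
        mixed = mix_populations(a, b, alpha, "m")
        src = a if expect_from == "a" else b
        for lc in small_panel.locus_copies:
            for allele, f in src.freqs[lc].items():
                assert mixed.freqs[lc][allele] == pytest.approx(f, abs=1e-12)

    def test_half_mix_of_point_masses(self, single_copy_panel):
        freqs_a = {lc: {"14": 1.0} for lc in single_copy_panel.locus_copies}
        freqs_b = {lc: {"15": 1.0} for lc in single_copy_panel.locus_copies}
        a = PopulationModel("a", freqs_a)
        b = PopulationModel("b", freqs_b)
        m = mix_populations(a, b, 0.5, "m")
        assert m.freqs["L1"] == {"14": 0.5, "15": 0.5}

    def test_mismatched_panels_rejected(self, small_panel, single_copy_panel):
        a = sample_population_model(small_panel, 3, 1.0, seed=1)
        b = sample_population_model(single_copy_panel, 3, 1.0, seed=2)
        with pytest.raises(SimulationError):
            mix_populations(a, b, 0.5, "m")


class TestGenerateTable:
    def test_zero_counts_give_empty_table(self, small_panel):
        m = sample_population_model(small_panel, 3, 1.0, seed=0, name="P")
        cfg = SimulationConfig(small_panel, [m], {"P": 0}, seed=0)
        assert len(generate_table(cfg)) == 0

    def test_no_missing_when_rate_zero(self, small_panel):
        m = sample_population_model(small_panel, 3, 1.0, seed=0, name="P")
        cfg = SimulationConfig(small_panel, [m], {"P": 50}, missing_rate=0.0, seed=1)
        findings = validate_table(generate_table(cfg))
        assert [f for f in findings if f.kind == "missing_call"] == []

    def test_missing_rate_realized(self, small_panel):
        m = sample_population_model(small_panel, 3, 1.0, seed=0, name="P")
        cfg = SimulationConfig(small_panel, [m], {"P": 400}, missing_rate=0.2, seed=1)
        table = generate_table(cfg)
        n_missing = sum(len(p.missing_loci()) for p in table)
        total = 400 * small_panel.n_locus_copies
        # binomial(total, 0.2): 4 standard errors
        se = np.sqrt(0.2 * 0.8 / total)
        assert abs(n_missing / total - 0.2) < 4 * se

    def test_empirical_frequencies_match_model(self, single_copy_panel):
        m = sample_population_model(single_copy_panel, 4, 1.0, seed=9, name="P")
        cfg = SimulationConfig(single_copy_panel, [m], {"P": 5000}, seed=2)
        table = generate_table(cfg)
        for lc in single_copy_panel.locus_copies:
            counts = {}
            for p in table:
                counts[p.calls[lc]] = counts.get(p.calls[lc], 0) + 1
            for allele, f in m.freqs[lc].items():
                emp = counts.get(allele, 0) / 5000
                se = max(np.sqrt(f * (1 - f) / 5000), 1e-4)
                assert abs(emp - f) < 4 * se, (lc, allele)

    def test_multicopy_calls_nondecreasing(self, small_panel):
        m = sample_population_model(small_panel, 5, 0.5, seed=4, name="P")
        cfg = SimulationConfig(small_panel, [m], {"P": 200}, seed=3)
        for p in generate_table(cfg):
            a, b = p.calls["DYS385a"], p.calls["DYS385b"]
            assert allele_sort_key(a) <= allele_sort_key(b)

    def test_seed_determinism_byte_identical(self, tmp_path, small_panel):
        m = sample_population_model(small_panel, 4, 1.0, seed=0, name="P")
        files = []
        for name in ("a.csv", "b.csv"):
            cfg = SimulationConfig(small_panel, [m], {"P": 30},
                                   missing_rate=0.1, seed=17)
            path = tmp_path / name
            write_haplotype_table(generate_table(cfg), path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_labels_attached(self, small_panel):
        ms = separable_models(small_panel, 2, seed=0)
        cfg = SimulationConfig(small_panel, ms, {"POP1": 3, "POP2": 4}, seed=0)
        table = generate_table(cfg)
        assert table.populations.count("POP1") == 3
        assert table.populations.count("POP2") == 4


class TestSeparableModels:
    def test_supports_disjoint(self, small_panel):
        ms = separable_models(small_panel, 3, alleles_per_locus=3, seed=0)
        for lc in small_panel.locus_copies:
            supports = [set(m.freqs[lc]) for m in ms]
            for i in range(3):
                for j in range(i + 1, 3):
                    assert supports[i].isdisjoint(supports[j])

    def test_single_feature_rule_separates(self, small_panel):
        # any allele observed identifies its population: the downstream
        # separability oracle
        ms = separable_models(small_panel, 2, seed=1)
        cfg = SimulationConfig(small_panel, ms, {"POP1": 50, "POP2": 50}, seed=1)
        support1 = set(ms[0].freqs["DYS19"])
        for p in generate_table(cfg):
            predicted = "POP1" if p.calls["DYS19"] in support1 else "POP2"
            assert predicted == p.population
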