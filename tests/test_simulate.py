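"""Simulator contracts: structure, determinism, truth labels, noise, I/O."""

import filecmp

import numpy as np
import pytest

from snpcoseg.pedigree import read_ped, read_panel
from snpcoseg.phasing import CONSISTENT, mendelian_check
from snpcoseg.simulate import (
    FamilySpec,
    SimulationConfig,
    config_from_mapping,
    default_panels,
    informative_panel,
    simulate_cohort,
    write_fixture,
)

from helpers import make_panel


def small_config(**kw):
    panels = kw.pop("panels", default_panels()[:4])
    defaults = dict(
        n_families=6,
        panels=panels,
        causal_gene=panels[0].gene,
        family_structure=FamilySpec(2, 1),
        seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestStructureContract:
    def test_exact_typed_counts_and_ascertainment(self):
        cohort = simulate_cohort(small_config(n_families=10))
        for fam in cohort.families:
            typed_aff = [c for c in fam.children
                         if c.affection == "affected" and c.genotypes]
            typed_unaff = [c for c in fam.children
                           if c.affection == "unaffected" and c.genotypes]
            assert len(typed_aff) == 2 and len(typed_unaff) == 1
            assert fam.affected_children()

    def test_untyped_parent_has_missing_genotypes_but_latent_haplotypes(self):
        spec = FamilySpec(1, 1, father_typed=False)
        cohort = simulate_cohort(small_config(family_structure=spec))
        for fam, truth in zip(cohort.families, cohort.truth):
            assert fam.father.genotypes == {}
            assert "father" in truth.founder_haplotypes[cohort.panels[0].gene]

    def test_oversized_sibship_adds_untyped_sibs(self):
        spec = FamilySpec(1, 1, sibship_size=4)
        cohort = simulate_cohort(small_config(family_structure=spec))
        fam = cohort.families[0]
        assert len(fam.children) == 4
        assert sum(not c.genotypes for c in fam.children) == 2

    def test_rejection_cap_raises_with_guidance(self):
        config = small_config(
            family_structure=FamilySpec(2, 0, sibship_size=2),
            penetrance=0.0,
            max_attempts=40,
        )
        with pytest.raises(RuntimeError, match="attempts"):
            simulate_cohort(config)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_fixtures(self, tmp_path):
        for d in ("a", "b"):
            write_fixture(simulate_cohort(small_config(seed=5)), tmp_path / d)
        for name in ("cohort.ped", "panel.tsv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False)

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_cohort(small_config(seed=5))
        b = simulate_cohort(small_config(seed=6))
        ga = [c.genotypes for f in a.families for c in f.children]
        gb = [c.genotypes for f in b.families for c in f.children]
        assert ga != gb


class TestTruthLabels:
    def test_affected_children_carry_both_risk_copies(self):
        cohort = simulate_cohort(small_config())
        for fam, truth in zip(cohort.families, cohort.truth):
            risk = (truth.risk_copies["mother"], truth.risk_copies["father"])
            for child in fam.children:
                if not child.genotypes:
                    continue
                trans = truth.transmissions[child.individual_id][truth.causal_gene]
                assert (child.affection == "affected") == (tuple(trans) == risk)

    def test_transmissions_reproduce_observed_genotypes(self):
        cohort = simulate_cohort(small_config())
        for fam, truth in zip(cohort.families, cohort.truth):
            for child in fam.children:
                if not child.genotypes:
                    continue
                for panel in cohort.panels:
                    mc, pc = truth.transmissions[child.individual_id][panel.gene]
                    haps = truth.founder_haplotypes[panel.gene]
                    mhap = haps["mother"][mc - 1]
                    phap = haps["father"][pc - 1]
                    for j, m in enumerate(panel.markers):
                        g = child.genotype(m.marker_id)
                        assert tuple(sorted((mhap[j], phap[j]))) == g.alleles

    def test_mendelian_closure_without_noise(self):
        cohort = simulate_cohort(small_config(n_families=8))
        for fam in cohort.families:
            for panel in cohort.panels:
                for report in mendelian_check(fam, panel):
                    assert set(report.flags) == {CONSISTENT}

    def test_false_paternity_families_marked_in_truth(self):
        cohort = simulate_cohort(
            small_config(n_families=5, false_paternity_families=frozenset({1, 3}))
        )
        fp = [t.family_id for t in cohort.truth if not t.true_paternity]
        assert fp == ["F002", "F004"]


class TestNoiseModels:
    def test_missing_rate_produces_missing_calls(self):
        cohort = simulate_cohort(small_config(missing_rate=0.3, seed=9))
        n_calls = sum(
            len(p.genotypes) for f in cohort.families for p in f.members
        )
        full = simulate_cohort(small_config(missing_rate=0.0, seed=9))
        n_full = sum(len(p.genotypes) for f in full.families for p in f.members)
        assert n_calls < n_full

    def test_genotype_error_breaks_mendelian_closure_sometimes(self):
        cohort = simulate_cohort(small_config(genotype_error_rate=0.2, seed=9))
        bad = sum(
            f != CONSISTENT
            for fam in cohort.families
            for panel in cohort.panels
            for r in mendelian_check(fam, panel)
            for f in r.flags
        )
        assert bad > 0


class TestAlleleFrequencyRecovery:
    def test_founder_frequencies_match_config(self):
        """>=5,000 founders recover each allele frequency within 3 binomial SE."""
        panel = make_panel("G0", ("AG",), freqs=[(0.7, 0.3)])
        config = SimulationConfig(
            n_families=2500,
            panels=[panel],
            causal_gene="G0",
            family_structure=FamilySpec(1, 0, sibship_size=1),
            seed=77,
        )
        cohort = simulate_cohort(config)
        alleles = []
        for t in cohort.truth:
            for who in ("father", "mother"):
                for hap in t.founder_haplotypes["G0"][who]:
                    alleles.append(hap[0])
        n = len(alleles)
        assert n == 10_000
        freq_g = alleles.count("G") / n
        se = (0.3 * 0.7 / n) ** 0.5
        assert abs(freq_g - 0.3) <= 3 * se


class TestInformativePanel:
    def test_founders_carry_four_distinct_alleles(self):
        panel = informative_panel("TEST")
        config = SimulationConfig(
            n_families=1,
            panels=[panel],
            causal_gene="TEST",
            family_structure=FamilySpec(1, 0),
            informative_genes=frozenset({"TEST"}),
            seed=3,
        )
        cohort = simulate_cohort(config)
        t = cohort.truth[0]
        haps = t.founder_haplotypes["TEST"]
        seen = {haps[w][i][0] for w in ("father", "mother") for i in range(2)}
        assert seen == {"1", "2", "3", "4"}


class TestFixtureIO:
    def test_roundtrip_and_truth_contents(self, reference_cohort, fixture_dir):
        panels = read_panel(fixture_dir / "panel.tsv")
        families = read_ped(fixture_dir / "cohort.ped", panels)
        assert [f.family_id for f in families] == \
            [f.family_id for f in reference_cohort.families]
        for orig, rt in zip(reference_cohort.families, families):
            for a, b in zip(orig.members, rt.members):
                assert a.genotypes == b.genotypes and a.affection == b.affection
        import json

        truth = json.loads((fixture_dir / "truth.json").read_text())
        assert truth["causal_gene"] == reference_cohort.config.causal_gene
        assert truth["false_paternity_families"] == ["F001", "F002"]


class TestConfigSchema:
    def test_unknown_field_named_in_error(self):
        with pytest.raises(ValueError, match="n_fmailies"):
            config_from_mapping({"n_fmailies": 3})

    def test_zero_families_rejected(self):
        with pytest.raises(ValueError, match="n_families"):
            config_from_mapping({"n_families": 0}).validate()

    def test_family_structure_list(self):
        cfg = config_from_mapping(
            {
                "n_families": 2,
                "family_structure": [
                    {"n_affected": 1, "n_unaffected": 0},
                    {"n_affected": 2, "n_unaffected": 1},
                ],
                "seed": 1,
            }
        )
        cohort = simulate_cohort(cfg)
        assert len(cohort.families[1].children) == 3
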