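"""Cohort-level validation experiments.

These routines re-derive the analysis' calibration properties by
simulation: Monte-Carlo exclusion rates at fully informative loci (which
have a closed form), the causal-gene protection and monotonicity
guarantees, the exclusion gradient across affected-count strata, and a
reference cohort configuration (31 families, two with misattributed
paternity) mirroring the structure of the published study population.
"""

from __future__ import annotations

import numpy as np

from .cosegregation import EXCLUDED, call_gene
from .pedigree import Genotype, Individual
from .simulate import (
    FamilySpec,
    SimulationConfig,
    default_family_structure,
    default_panels,
    informative_panel,
    simulate_cohort,
)


def exclusion_probability_informative(k: int, u: int) -> float:
    """Closed-form exclusion probability of a non-causal gene.

    At a fully informative locus (father 1/2, mother 3/4) transmissions are
    observed exactly, so a family with k affected and u unaffected sibs
    retains the gene iff all affecteds share the first affected's pair
    (probability (1/4)^(k-1)) and no unaffected carries it ((3/4)^u)::

        P(excluded) = 1 - (1/4)**(k-1) * (3/4)**u
    """
    return 1.0 - 0.25 ** (k - 1) * 0.75 ** u


def monte_carlo_exclusion_rate(k: int, u: int, n_reps: int, seed: int) -> float:
    """Empirical exclusion rate of a non-causal fully informative gene.

    Simulates *n_reps* independent families with exactly *k* affected and
    *u* unaffected genotyped sibs, with both the causal locus and an
    unlinked test locus fully informative, and runs the cosegregation call
    on the test locus.
    """
    panels = [informative_panel("CAUSAL"), informative_panel("TEST")]
    config = SimulationConfig(
        n_families=n_reps,
        panels=panels,
        causal_gene="CAUSAL",
        family_structure=FamilySpec(n_affected=k, n_unaffected=u),
        informative_genes=frozenset({"CAUSAL", "TEST"}),
        seed=seed,
    )
    cohort = simulate_cohort(config)
    test_panel = cohort.panels[1]
    n_excl = sum(call_gene(f, test_panel).status == EXCLUDED for f in cohort.families)
    return n_excl / n_reps


def affected_gradient(n_families: int, seed: int) -> dict:
    """Mean proportion of genes excluded per affected-count stratum.

    Splits *n_families* evenly across strata with 1, 2 and 3 affected sibs
    (one unaffected sib each, both parents genotyped) at the default
    biallelic panels and returns {1: mean, 2: mean, 3: mean}.
    """
    panels = default_panels()
    out = {}
    per = n_families // 3
    sizes = {1: n_families - 2 * per, 2: per, 3: per}
    for k in (1, 2, 3):
        config = SimulationConfig(
            n_families=sizes[k],
            panels=panels,
            causal_gene="USH2A",
            family_structure=FamilySpec(n_affected=k, n_unaffected=1),
            seed=seed + k,
        )
        cohort = simulate_cohort(config)
        from .cosegregation import build_matrix

        matrix = build_matrix(cohort.families, cohort.panels)
        out[k] = float(
            np.mean([matrix.proportion_excluded(f.family_id) for f in cohort.families])
        )
    return out


def causal_exclusion_count(n_families: int, seed: int) -> int:
    """Families in which the causal gene is (wrongly) EXCLUDED.

    With no genotype error, full penetrance and no phenocopies this must be
    exactly zero: the true phase always rescues the causal gene.  Family
    structures are sampled from the reference cohort's marginals.
    """
    config = SimulationConfig(n_families=n_families, seed=seed)
    cohort = simulate_cohort(config)
    causal = next(p for p in cohort.panels if p.gene == config.causal_gene)
    return sum(call_gene(f, causal).status == EXCLUDED for f in cohort.families)


def _gene_drop_child(family, truth, panels, rng, affection: str):
    """A new genotyped child drawn from the family's latent founder copies."""
    genos = {}
    for panel in panels:
        haps = truth.founder_haplotypes[panel.gene]
        mc, pc = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        mhap = haps["mother"][mc - 1]
        phap = haps["father"][pc - 1]
        for j, m in enumerate(panel.markers):
            genos[m.marker_id] = Genotype(mhap[j], phap[j])
    return Individual(
        individual_id="C_extra",
        family_id=family.family_id,
        father_id=family.father.individual_id,
        mother_id=family.mother.individual_id,
        affection=affection,
        genotypes=genos,
    )


def monotonicity_violations(n_trials: int, seed: int, n_genes: int = 4) -> int:
    """EXCLUDED verdicts overturned by adding a genotyped child.

    For random simulated families, takes each gene's verdict, adds one
    extra gene-dropped child (random affection) and recounts; returns the
    number of (family, gene) augmentations in which an EXCLUDED gene became
    INCLUDED (or uninformative).  Must be zero: exclusion is a universal
    statement that extra data can only reinforce.
    """
    rng = np.random.default_rng(seed)
    panels = default_panels()[:n_genes]
    violations = 0
    trials = 0
    while trials < n_trials:
        k = int(rng.integers(1, 4))
        u = int(rng.integers(0, 2))
        config = SimulationConfig(
            n_families=1,
            panels=panels,
            causal_gene=panels[0].gene,
            family_structure=FamilySpec(n_affected=k, n_unaffected=u),
            seed=int(rng.integers(2**31)),
        )
        cohort = simulate_cohort(config)
        family = cohort.families[0]
        truth = cohort.truth[0]
        before = {p.gene: call_gene(family, p).status for p in panels}
        affection = "affected" if rng.random() < 0.5 else "unaffected"
        child = _gene_drop_child(family, truth, panels, rng, affection)
        bigger = type(family)(
            family.family_id, family.father, family.mother, family.children + [child]
        )
        for p in panels:
            if trials >= n_trials:
                break
            after = call_gene(bigger, p).status
            if before[p.gene] == EXCLUDED and after != EXCLUDED:
                violations += 1
            trials += 1
    return violations


def reference_cohort_config(seed: int) -> SimulationConfig:
    """A 31-family cohort shaped like the published study population.

    Family structures are sampled from the reference cohort's marginals;
    the first two families carry misattributed paternity and are given the
    cohort's modal detectable structure (two affected and one unaffected
    genotyped sibs, both parental DNA samples available) — a family whose
    false paternity was observed necessarily had paternal DNA.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    specs = default_family_structure(31, rng)
    detectable = FamilySpec(
        n_affected=2, n_unaffected=1, father_typed=True, mother_typed=True
    )
    specs[0] = detectable
    specs[1] = detectable
    return SimulationConfig(
        n_families=31,
        family_structure=specs,
        false_paternity_families=frozenset({0, 1}),
        seed=seed,
    )
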