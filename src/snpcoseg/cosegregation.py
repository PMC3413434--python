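"""Recessive cosegregation exclusion calls per family x gene.

Under a fully penetrant autosomal recessive model, a candidate gene is
compatible with a family's disease when some Mendelian-consistent phase
assignment admits a "disease pair" (one maternal copy, one paternal copy)
carried by every affected child and by no unaffected child.  A gene is
EXCLUDED only when *no* consistent assignment is compatible — exclusion is
a universal statement over phases, so uninformative data can never exclude
(the conservative inclusion rule).  A family with no consistent assignment
at a gene is INCONSISTENT: it is surfaced to the paternity screen rather
than counted as excluded.

The per-gene evaluation never materialises the full assignment set: for
each pair of parental phase configurations the per-child allowed
transmissions factorise, so consistency, compatibility, informativeness and
the exact canonical assignment count (raw count / 4: the copy-label swap
group acts freely whenever the family has a child) are all computed from
the per-child transmission sets directly.  ``enumerate_assignments`` in
:mod:`snpcoseg.phasing` remains the reference implementation and the two
are tested against each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

from .pedigree import MISSING, GenePanel, NuclearFamily
from .phasing import (
    PhaseAssignment,
    allowed_transmissions,
    parent_phase_configs,
)

EXCLUDED = "EXCLUDED"
INCLUDED = "INCLUDED"
UNINFORMATIVE_INCLUDED = "UNINFORMATIVE_INCLUDED"
INCONSISTENT = "INCONSISTENT"

STATUS_CODES = {
    EXCLUDED: "E",
    INCLUDED: "I",
    UNINFORMATIVE_INCLUDED: "U",
    INCONSISTENT: "X",
}

_ALL_PAIRS = ((1, 1), (1, 2), (2, 1), (2, 2))


@dataclass(frozen=True)
class ExclusionCall:
    """Verdict for one family at one gene."""

    family_id: str
    gene: str
    status: str
    reason: str
    n_assignments: int
    analyzed: bool = True


def recessive_compatible(assignment: PhaseAssignment, affections: Sequence[str]) -> bool:
    """Is one phase assignment compatible with recessive segregation?

    True iff some disease pair (maternal copy, paternal copy) is the
    transmission of every affected child and of no unaffected child.
    Children with unknown affection impose no constraint.  *affections*
    aligns with the assignment's transmission order.
    """
    for pair in _ALL_PAIRS:
        ok = True
        for aff, trans in zip(affections, assignment.transmissions):
            if aff == "affected" and trans != pair:
                ok = False
                break
            if aff == "unaffected" and trans == pair:
                ok = False
                break
        if ok:
            return True
    return False


def _compatible_exists(per_child, affections, unaffecteds_constrain=True) -> bool:
    """Existence of a compatible choice of transmissions, factorised.

    ``per_child[i]`` is the allowed transmission set of the i-th constrained
    child.  A compatible assignment exists iff some pair is allowed for all
    affected children and each unaffected child retains an alternative.
    """
    for pair in _ALL_PAIRS:
        ok = True
        for trans_set, aff in zip(per_child, affections):
            if aff == "affected" and pair not in trans_set:
                ok = False
                break
            if (
                unaffecteds_constrain
                and aff == "unaffected"
                and trans_set == (pair,)
            ):
                ok = False
                break
        if ok:
            return True
    return False


@dataclass
class _GeneEvaluation:
    raw_count: int  # raw consistent assignments over constrained children
    n_unconstrained: int  # children untyped at this panel (marginalised)
    any_compatible: bool
    uninformative: bool


def _evaluate_gene(
    family: NuclearFamily, panel: GenePanel, unaffecteds_constrain: bool = True
) -> _GeneEvaluation:
    constrained = [c for c in family.children if c.is_typed_at(panel)]
    n_unconstrained = len(family.children) - len(constrained)
    affections = [c.affection for c in constrained]

    raw_count = 0
    any_compatible = False
    product_sets = set()  # per-(father,mother) tuples of per-child transmission sets
    for father, mother in product(
        parent_phase_configs(family.father, panel),
        parent_phase_configs(family.mother, panel),
    ):
        per_child = [allowed_transmissions(c, father, mother, panel) for c in constrained]
        if any(not t for t in per_child):
            continue
        count = 1
        for t in per_child:
            count *= len(t)
        raw_count += count
        if not any_compatible and _compatible_exists(
            per_child, affections, unaffecteds_constrain
        ):
            any_compatible = True
        product_sets.add(tuple(frozenset(t) for t in per_child))

    # Uninformative: every transmission vector over the constrained children
    # is realised by some consistent assignment, i.e. the genotype data do
    # not restrict transmission at all and could never have excluded.
    uninformative = False
    if raw_count > 0:
        if not constrained:
            uninformative = True
        else:
            uninformative = all(
                any(all(t in s for t, s in zip(vec, prod)) for prod in product_sets)
                for vec in product(_ALL_PAIRS, repeat=len(constrained))
            )
    return _GeneEvaluation(raw_count, n_unconstrained, any_compatible, uninformative)


def call_gene(
    family: NuclearFamily, panel: GenePanel, unaffecteds_constrain: bool = True
) -> ExclusionCall:
    """Exclusion verdict for one family at one gene.

    With ``unaffecteds_constrain=False`` unaffected sibs are treated as
    non-constraining (sensitivity analysis for incomplete penetrance): only
    haplotype sharing among affecteds is required for compatibility.
    """
    ev = _evaluate_gene(family, panel, unaffecteds_constrain)
    analyzed = any(m.is_typed_at(panel) for m in family.members)
    # canonical count: swap group acts freely (>=1 child), so raw/4; the
    # marginalised untyped children contribute a free factor of 4 each.
    n_assignments = ev.raw_count * 4 ** ev.n_unconstrained // 4 if ev.raw_count else 0
    if ev.raw_count == 0:
        status, reason = INCONSISTENT, "no Mendelian-consistent phase assignment"
    elif ev.uninformative:
        status, reason = (
            UNINFORMATIVE_INCLUDED,
            "genotypes do not constrain transmission (lack of informativeness)",
        )
    elif ev.any_compatible:
        status, reason = INCLUDED, "some phase assignment cosegregates recessively"
    else:
        status, reason = EXCLUDED, "no phase assignment cosegregates recessively"
    return ExclusionCall(family.family_id, panel.gene, status, reason, n_assignments, analyzed)


@dataclass
class ExclusionMatrix:
    """Families x genes grid of exclusion calls."""

    family_ids: list
    genes: list
    calls: dict  # (family_id, gene) -> ExclusionCall

    def call(self, family_id: str, gene: str) -> ExclusionCall:
        return self.calls[(family_id, gene)]

    def family_calls(self, family_id: str) -> list:
        return [self.calls[(family_id, g)] for g in self.genes]

    def proportion_excluded(self, family_id: str) -> float:
        """EXCLUDED count / genes analyzed for this family.

        Genes untyped in every family member are dropped from the
        denominator; INCONSISTENT genes count as analyzed but not excluded.
        """
        calls = [c for c in self.family_calls(family_id) if c.analyzed]
        if not calls:
            return float("nan")
        return sum(c.status == EXCLUDED for c in calls) / len(calls)

    def per_gene_exclusion_counts(self) -> dict:
        return {
            g: sum(self.calls[(f, g)].status == EXCLUDED for f in self.family_ids)
            for g in self.genes
        }

    def mean_genes_excluded(self) -> float:
        total = sum(
            sum(c.status == EXCLUDED for c in self.family_calls(f))
            for f in self.family_ids
        )
        return total / len(self.family_ids) if self.family_ids else float("nan")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {g: [STATUS_CODES[self.calls[(f, g)].status] for f in self.family_ids] for g in self.genes},
            index=pd.Index(self.family_ids, name="family_id"),
        )

    def write_tsv(self, path) -> None:
        """TSV grid: families as rows, genes as columns, codes E/I/U/X."""
        self.to_dataframe().to_csv(path, sep="\t")

    def write_json(self, path) -> None:
        """Companion JSON with reasons and per-family proportions."""
        payload = {
            "families": {
                f: {
                    "proportion_excluded": self.proportion_excluded(f),
                    "calls": {
                        g: {
                            "status": self.calls[(f, g)].status,
                            "reason": self.calls[(f, g)].reason,
                            "n_assignments": self.calls[(f, g)].n_assignments,
                            "analyzed": self.calls[(f, g)].analyzed,
                        }
                        for g in self.genes
                    },
                }
                for f in self.family_ids
            },
            "per_gene_excluded_in_n_families": self.per_gene_exclusion_counts(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def build_matrix(
    cohort: Sequence[NuclearFamily],
    panels: Sequence[GenePanel],
    unaffecteds_constrain: bool = True,
) -> ExclusionMatrix:
    """One exclusion call per family x gene over the whole cohort."""
    calls = {}
    for fam in cohort:
        for panel in panels:
            calls[(fam.family_id, panel.gene)] = call_gene(fam, panel, unaffecteds_constrain)
    return ExclusionMatrix(
        [f.family_id for f in cohort], [p.gene for p in panels], calls
    )


def _hap_matches(hap: tuple, query: tuple) -> bool:
    return all(q == MISSING or h == MISSING or h == q for h, q in zip(hap, query))


def shared_haplotype_scan(
    cohort: Sequence[NuclearFamily], panel: GenePanel, query: tuple
) -> list:
    """Affected individuals who may carry *query* on a transmitted copy.

    Lists every affected child for whom at least one Mendelian-consistent
    phase assignment of their family places a haplotype matching *query*
    (MISSING positions on either side are wildcards) on one of the child's
    two transmitted copies.  Used to spot candidate founder haplotypes
    shared across families.
    """
    if len(query) != panel.n_markers:
        raise ValueError(
            f"query length {len(query)} does not match panel {panel.gene} "
            f"({panel.n_markers} markers)"
        )
    hits = []
    for fam in cohort:
        affected_idx = [
            i for i, c in enumerate(fam.children) if c.affection == "affected"
        ]
        if not affected_idx:
            continue
        found = set()
        for father, mother in product(
            parent_phase_configs(fam.father, panel),
            parent_phase_configs(fam.mother, panel),
        ):
            per_child = [
                allowed_transmissions(c, father, mother, panel) for c in fam.children
            ]
            if any(not t for t in per_child):
                continue
            for i in affected_idx:
                if i in found:
                    continue
                for mc, pc in per_child[i]:
                    if _hap_matches(mother.hap(mc), query) or _hap_matches(
                        father.hap(pc), query
                    ):
                        found.add(i)
                        break
            if len(found) == len(affected_idx):
                break
        hits.extend(
            (fam.family_id, fam.children[i].individual_id) for i in sorted(found)
        )
    return hits
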