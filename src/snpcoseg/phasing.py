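"""Exhaustive phase enumeration for one nuclear family at one gene panel.

A gene panel spans a single locus and its flanks, so no recombination is
modelled: each child inherits exactly one unrecombined haplotype per parent
per gene.  A *phase assignment* is a choice of the two ordered parental
haplotypes for each parent (copy labels 1/2 are arbitrary but fixed) plus,
per child, the pair (maternal copy, paternal copy) transmitted.  Copy
labels are identity-by-descent labels by construction: even when a parent's
two haplotypes are identical in content, the copies remain distinct labels.

Missing parental genotypes leave the corresponding haplotype entries
MISSING; missing entries act as wildcards when matching child genotypes and
are never imputed.  Enumeration is exact: only heterozygous markers
contribute phase choices (<= 2^6 per parent), and per-child transmissions
are filtered independently, so the full consistent set is recovered without
heuristics.  The empty set is the signal for Mendelian inconsistency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from typing import Sequence

from .pedigree import MISSING, GenePanel, Genotype, Individual, NuclearFamily

CONSISTENT = "consistent"
PATERNAL_INCONSISTENT = "paternal_inconsistent"
MATERNAL_INCONSISTENT = "maternal_inconsistent"
INDETERMINATE_INCONSISTENT = "indeterminate_inconsistent"


@dataclass(frozen=True)
class ParentalDiplotype:
    """Ordered pair of parental haplotypes (copy labels 1 and 2)."""

    hap1: tuple
    hap2: tuple

    def hap(self, copy: int) -> tuple:
        return self.hap1 if copy == 1 else self.hap2

    def swapped(self) -> "ParentalDiplotype":
        return ParentalDiplotype(self.hap2, self.hap1)


@dataclass(frozen=True)
class PhaseAssignment:
    """One consistent phase of a family at a panel.

    ``transmissions[i]`` is the (maternal copy, paternal copy) pair, each in
    {1, 2}, inherited by the i-th child (in family child order).
    """

    father: ParentalDiplotype
    mother: ParentalDiplotype
    transmissions: tuple

    def child_haplotypes(self, child_index: int) -> tuple:
        """(maternal haplotype, paternal haplotype) carried by a child."""
        mc, pc = self.transmissions[child_index]
        return self.mother.hap(mc), self.father.hap(pc)

    def canonical(self) -> "PhaseAssignment":
        """Representative under independent swaps of each parent's labels."""
        candidates = []
        for swap_f, swap_m in product((False, True), repeat=2):
            fa = self.father.swapped() if swap_f else self.father
            mo = self.mother.swapped() if swap_m else self.mother
            trans = tuple(
                (3 - mc if swap_m else mc, 3 - pc if swap_f else pc)
                for mc, pc in self.transmissions
            )
            candidates.append(PhaseAssignment(fa, mo, trans))
        return min(candidates, key=_assignment_key)


def _assignment_key(a: PhaseAssignment):
    return (a.father.hap1, a.father.hap2, a.mother.hap1, a.mother.hap2, a.transmissions)


@dataclass(frozen=True)
class InconsistencyReport:
    """Per-marker single-marker consistency flags for one child."""

    child_id: str
    flags: tuple  # one flag per panel marker

    def inconsistent_markers(self) -> tuple:
        return tuple(i for i, f in enumerate(self.flags) if f != CONSISTENT)


# ---------------------------------------------------------------------------
# Parental phase configurations


def parent_phase_configs(parent: Individual | None, panel: GenePanel) -> list:
    """All raw ordered diplotypes consistent with a parent's genotypes.

    Homozygous or missing markers contribute one entry choice; heterozygous
    markers contribute both orderings, so the list has 2^h elements for h
    heterozygous markers (both orientations included — canonicalisation
    happens downstream).  An absent parent yields the single all-MISSING
    diplotype, i.e. a fully unconstrained wildcard pair.
    """
    per_marker = []
    for m in panel.markers:
        g = parent.genotype(m.marker_id) if parent is not None else Genotype()
        if g.is_missing:
            per_marker.append([(MISSING, MISSING)])
        elif g.allele_a == g.allele_b:
            per_marker.append([(g.allele_a, g.allele_a)])
        else:
            per_marker.append([(g.allele_a, g.allele_b), (g.allele_b, g.allele_a)])
    configs = []
    for combo in product(*per_marker):
        hap1 = tuple(x for x, _ in combo)
        hap2 = tuple(y for _, y in combo)
        configs.append(ParentalDiplotype(hap1, hap2))
    return configs


def _pair_matches(x: str, y: str, genotype: Genotype) -> bool:
    """Does the unordered haplotype-entry pair (x, y) match a child genotype?

    MISSING haplotype entries are wildcards.
    """
    a, b = genotype.alleles

    def ok(h, allele):
        return h == MISSING or h == allele

    return (ok(x, a) and ok(y, b)) or (ok(x, b) and ok(y, a))


def allowed_transmissions(
    child: Individual, father: ParentalDiplotype, mother: ParentalDiplotype, panel: GenePanel
) -> tuple:
    """Transmission pairs (maternal copy, paternal copy) consistent with a child.

    Markers where the child is untyped are unconstrained.
    """
    out = []
    genos = [child.genotype(m.marker_id) for m in panel.markers]
    for mc, pc in ((1, 1), (1, 2), (2, 1), (2, 2)):
        mhap = mother.hap(mc)
        phap = father.hap(pc)
        if all(
            g.is_missing or _pair_matches(mhap[i], phap[i], g) for i, g in enumerate(genos)
        ):
            out.append((mc, pc))
    return tuple(out)


def enumerate_assignments(family: NuclearFamily, panel: GenePanel) -> set:
    """The exact set of Mendelian-consistent phase assignments, canonicalised.

    Canonicalisation quotients out the 4-element group of per-parent copy
    label swaps so equivalent relabelings appear once.  An empty set signals
    Mendelian inconsistency at this gene.
    """
    assignments = set()
    for father, mother in product(
        parent_phase_configs(family.father, panel),
        parent_phase_configs(family.mother, panel),
    ):
        per_child = [
            allowed_transmissions(c, father, mother, panel) for c in family.children
        ]
        if any(not t for t in per_child):
            continue
        for trans in product(*per_child):
            assignments.add(PhaseAssignment(father, mother, trans).canonical())
    return assignments


# ---------------------------------------------------------------------------
# Single-marker Mendelian checks


def single_marker_flag(child_g: Genotype, father_g: Genotype, mother_g: Genotype) -> str:
    """Classify one child genotype against both parents at one marker.

    A missing child genotype is consistent.  A missing parental genotype
    supplies any allele.  When inconsistent, the flag attributes the failure
    to the parent who cannot supply the required allele; if neither parent
    can supply a needed allele, or either parent could equally be blamed,
    the flag is indeterminate.
    """
    if child_g.is_missing:
        return CONSISTENT
    a, b = child_g.alleles

    def can_supply(parent_g: Genotype, allele: str) -> bool:
        return parent_g.is_missing or allele in parent_g.alleles

    for x, y in ((a, b), (b, a)):
        if can_supply(mother_g, x) and can_supply(father_g, y):
            return CONSISTENT
    m_ok = can_supply(mother_g, a) or can_supply(mother_g, b)
    p_ok = can_supply(father_g, a) or can_supply(father_g, b)
    if m_ok and not p_ok:
        return PATERNAL_INCONSISTENT
    if p_ok and not m_ok:
        return MATERNAL_INCONSISTENT
    return INDETERMINATE_INCONSISTENT


def mendelian_check(family: NuclearFamily, panel: GenePanel) -> list:
    """Per-child, per-marker single-marker consistency reports."""
    father = family.father
    mother = family.mother
    reports = []
    for child in family.children:
        flags = []
        for m in panel.markers:
            flags.append(
                single_marker_flag(
                    child.genotype(m.marker_id),
                    father.genotype(m.marker_id) if father is not None else Genotype(),
                    mother.genotype(m.marker_id) if mother is not None else Genotype(),
                )
            )
        reports.append(InconsistencyReport(child.individual_id, tuple(flags)))
    return reports


def assignments_report(family: NuclearFamily, panel: GenePanel, assignments: set) -> str:
    """JSON debug report: gene, family, count and one sample assignment."""
    sample = None
    if assignments:
        a = min(assignments, key=_assignment_key)
        sample = {
            "father": [list(a.father.hap1), list(a.father.hap2)],
            "mother": [list(a.mother.hap1), list(a.mother.hap2)],
            "transmissions": {
                c.individual_id: list(t)
                for c, t in zip(family.children, a.transmissions)
            },
        }
    return json.dumps(
        {
            "gene": panel.gene,
            "family": family.family_id,
            "n_assignments": len(assignments),
            "sample": sample,
        },
        indent=2,
    )
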