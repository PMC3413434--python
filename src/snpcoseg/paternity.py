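"""Misattributed-parentage screening from clustered Mendelian inconsistencies.

Non-paternity shows up as parent-specific Mendelian inconsistencies spread
across many unlinked gene panels: with a misattributed father, each panel
independently has some chance of revealing a child allele the recorded
father cannot have transmitted.  A family is flagged when the fraction of
analyzed genes with paternal-specific inconsistency reaches a threshold
(default 0.5 — deliberately permissive, and configurable; gross multi-gene
inconsistency is the evidence, not any single marker, since an isolated
inconsistency may be a genotyping error).  Maternal misattribution is
screened symmetrically and reported separately.

Both single-marker checks and whole-gene haplotype contradictions (an empty
phase-assignment set) are computed; their union defines an inconsistent
gene, but parent-of-origin is attributed only from single-marker evidence —
a multi-marker contradiction without single-marker attribution is reported
as indeterminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .cosegregation import _evaluate_gene
from .pedigree import GenePanel, NuclearFamily
from .phasing import (
    CONSISTENT,
    INDETERMINATE_INCONSISTENT,
    MATERNAL_INCONSISTENT,
    PATERNAL_INCONSISTENT,
    mendelian_check,
)

logger = logging.getLogger(__name__)

INDETERMINATE = "indeterminate"

DEFAULT_THRESHOLD = 0.5


@dataclass
class PaternityReport:
    """Per-family misattributed-parentage screen result."""

    family_id: str
    gene_flags: dict  # gene -> consistent/paternal_inconsistent/maternal_inconsistent/indeterminate
    n_genes_analyzed: int
    n_paternal_inconsistent: int
    n_maternal_inconsistent: int
    threshold_used: float
    flagged: bool = field(init=False)
    maternal_flagged: bool = field(init=False)

    def __post_init__(self):
        n = self.n_genes_analyzed
        self.flagged = n > 0 and self.n_paternal_inconsistent / n >= self.threshold_used
        self.maternal_flagged = (
            n > 0 and self.n_maternal_inconsistent / n >= self.threshold_used
        )


def _gene_flag(family: NuclearFamily, panel: GenePanel) -> str:
    reports = mendelian_check(family, panel)
    flags = {f for r in reports for f in r.flags}
    has_p = PATERNAL_INCONSISTENT in flags
    has_m = MATERNAL_INCONSISTENT in flags
    has_i = INDETERMINATE_INCONSISTENT in flags
    if has_p and not has_m:
        return PATERNAL_INCONSISTENT
    if has_m and not has_p:
        return MATERNAL_INCONSISTENT
    if has_p and has_m:
        return INDETERMINATE
    if has_i:
        return INDETERMINATE
    # no single-marker evidence: check for a multi-marker haplotype
    # contradiction (empty assignment set); no parent-of-origin attribution.
    if _evaluate_gene(family, panel).raw_count == 0:
        return INDETERMINATE
    return CONSISTENT


def screen_family(
    family: NuclearFamily,
    panels: Sequence[GenePanel],
    threshold: float = DEFAULT_THRESHOLD,
) -> PaternityReport:
    """Screen one family across all gene panels.

    Genes untyped in every family member are excluded from the denominator.
    With no paternal genotypes at all, no paternal attribution is possible
    and the report is trivially unflagged.
    """
    gene_flags = {}
    n_analyzed = 0
    for panel in panels:
        if not any(m.is_typed_at(panel) for m in family.members):
            continue
        n_analyzed += 1
        gene_flags[panel.gene] = _gene_flag(family, panel)
    n_p = sum(f == PATERNAL_INCONSISTENT for f in gene_flags.values())
    n_m = sum(f == MATERNAL_INCONSISTENT for f in gene_flags.values())
    return PaternityReport(
        family_id=family.family_id,
        gene_flags=gene_flags,
        n_genes_analyzed=n_analyzed,
        n_paternal_inconsistent=n_p,
        n_maternal_inconsistent=n_m,
        threshold_used=threshold,
    )


def screen_cohort(
    cohort: Sequence[NuclearFamily],
    panels: Sequence[GenePanel],
    threshold: float = DEFAULT_THRESHOLD,
):
    """Screen every family; return (reports, cohort with flagged families removed).

    Families flagged for paternal or maternal misattribution are dropped
    from the returned cohort; every removal is logged, never silent.
    """
    reports = [screen_family(f, panels, threshold) for f in cohort]
    by_id = {r.family_id: r for r in reports}
    kept = []
    for fam in cohort:
        r = by_id[fam.family_id]
        if r.flagged or r.maternal_flagged:
            kind = "paternal" if r.flagged else "maternal"
            logger.warning(
                "family %s removed: %s misattribution flagged (%d/%d genes inconsistent, threshold %.2f)",
                fam.family_id,
                kind,
                r.n_paternal_inconsistent if r.flagged else r.n_maternal_inconsistent,
                r.n_genes_analyzed,
                threshold,
            )
        else:
            kept.append(fam)
    return reports, kept


def write_report(reports: Sequence[PaternityReport], path) -> None:
    """TSV report, one row per family."""
    lines = [
        "family_id\tn_genes_analyzed\tn_paternal_inconsistent\tn_maternal_inconsistent\tflagged"
    ]
    for r in reports:
        lines.append(
            f"{r.family_id}\t{r.n_genes_analyzed}\t{r.n_paternal_inconsistent}"
            f"\t{r.n_maternal_inconsistent}\t{r.flagged or r.maternal_flagged}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
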