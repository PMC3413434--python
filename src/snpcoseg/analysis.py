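"""Model/Results front end tying the pipeline stages together.

:class:`CosegregationAnalysis` is constructed from a cohort of nuclear
families plus the gene panels (or from PED/panel files) and configured with
the screening threshold and regression alpha.  Its :meth:`fit` runs the
stages in order — validate, misattributed-parentage screen (optionally
dropping flagged families), per-family x gene exclusion calls, and the
family-structure regressions — and returns a :class:`CosegregationResults`
carrying the exclusion matrix, the reports, the fitted regressions and the
cost estimates, with a ``summary()`` table and plotting helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import stats as _stats
from .cosegregation import EXCLUDED, ExclusionMatrix, build_matrix
from .paternity import DEFAULT_THRESHOLD, screen_cohort
from .pedigree import GenePanel, NuclearFamily, read_panel, read_ped, validate_cohort

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when the cohort fails structural validation."""

    def __init__(self, findings):
        self.findings = findings
        super().__init__(
            "cohort validation failed:\n" + "\n".join(str(f) for f in findings)
        )


@dataclass
class CosegregationResults:
    """Fitted cohort-level results of the cosegregation analysis."""

    matrix: ExclusionMatrix
    paternity_reports: list
    dropped_families: list  # family ids removed by the screen
    structure: pd.DataFrame
    univariate: dict  # variable -> RegressionResult (where fittable)
    backwards: object | None  # BackwardsEliminationResult or None
    costs: pd.DataFrame
    panels: list

    @property
    def proportions(self) -> pd.Series:
        return self.structure.set_index("family_id")["proportion_excluded"]

    def summary(self) -> str:
        m = self.matrix
        lines = []
        lines.append("SNP-panel cosegregation analysis")
        lines.append("=" * 48)
        lines.append(f"families analyzed:        {len(m.family_ids)}")
        if self.dropped_families:
            lines.append(
                f"families dropped (screen): {len(self.dropped_families)} "
                f"({', '.join(self.dropped_families)})"
            )
        lines.append(f"candidate genes:          {len(m.genes)}")
        lines.append(f"mean genes excluded/family: {m.mean_genes_excluded():.1f}")
        counts = m.per_gene_exclusion_counts()
        if counts:
            lines.append(
                "per-gene exclusion counts:  "
                f"min {min(counts.values())}, max {max(counts.values())}"
            )
        by_aff = self.structure.groupby("affected_bin")["proportion_excluded"].mean()
        for lv in ("1", "2", _stats.GE3):
            if lv in by_aff.index:
                lines.append(
                    f"mean proportion excluded, {lv} affected analyzed: {by_aff[lv]:.3f}"
                )
        if self.backwards is not None:
            if self.backwards.retained:
                kept = ", ".join(
                    f"{v} (p={self.backwards.variable_p[v]:.4g})"
                    for v in self.backwards.retained
                )
                lines.append(f"retained after backwards elimination: {kept}")
            else:
                lines.append("retained after backwards elimination: none (intercept only)")
        finite = self.costs["fold_savings"].replace([float("inf")], pd.NA).dropna()
        if len(finite):
            lines.append(f"median fold cost savings:  {finite.median():.2f}")
        return "\n".join(lines)

    def plot_exclusion_by_affected(self, ax=None):
        """Boxplot of proportion excluded by affected-count stratum."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = [lv for lv in ("1", "2", _stats.GE3) if (self.structure["affected_bin"] == lv).any()]
        data = [
            self.structure.loc[self.structure["affected_bin"] == lv, "proportion_excluded"]
            for lv in order
        ]
        ax.boxplot(data, tick_labels=order)
        ax.set_xlabel("affected individuals analyzed")
        ax.set_ylabel("proportion of genes excluded")
        return ax


class CosegregationAnalysis:
    """Cosegregation exclusion model for a cohort of nuclear families.

    Parameters
    ----------
    families, panels
        The cohort and per-gene SNP panels.
    paternity_threshold : float
        Fraction of analyzed genes with parent-specific inconsistency at
        which a family is flagged (default 0.5).
    drop_flagged : bool
        Remove flagged families before the exclusion stage (default True).
    unaffecteds_constrain : bool
        When False, unaffected sibs do not constrain compatibility
        (sensitivity analysis for incomplete penetrance).
    alpha : float
        Significance level for backwards elimination.
    """

    def __init__(
        self,
        families: Sequence[NuclearFamily],
        panels: Sequence[GenePanel],
        *,
        paternity_threshold: float = DEFAULT_THRESHOLD,
        drop_flagged: bool = True,
        unaffecteds_constrain: bool = True,
        alpha: float = 0.05,
        validate: bool = True,
    ):
        self.families = list(families)
        self.panels = list(panels)
        self.paternity_threshold = paternity_threshold
        self.drop_flagged = drop_flagged
        self.unaffecteds_constrain = unaffecteds_constrain
        self.alpha = alpha
        self.validate = validate

    @classmethod
    def from_files(cls, ped_path, panel_path, **kwargs) -> "CosegregationAnalysis":
        panels = read_panel(panel_path)
        families = read_ped(ped_path, panels)
        return cls(families, panels, **kwargs)

    def fit(self) -> CosegregationResults:
        if self.validate:
            findings = validate_cohort(self.families, self.panels)
            if findings:
                raise ValidationError(findings)
        reports, kept = screen_cohort(
            self.families, self.panels, self.paternity_threshold
        )
        cohort = kept if self.drop_flagged else self.families
        dropped = (
            [f.family_id for f in self.families if f not in kept]
            if self.drop_flagged
            else []
        )
        matrix = build_matrix(cohort, self.panels, self.unaffecteds_constrain)
        for call in matrix.calls.values():
            if call.status == "INCONSISTENT":
                logger.warning(
                    "family %s gene %s: Mendelian inconsistency (not counted as excluded)",
                    call.family_id,
                    call.gene,
                )
        table = _stats.structure_table(cohort, matrix)
        univariate = {}
        for var in _stats.VARIABLES:
            col = _stats.VARIABLES[var][0]
            if table.empty or table[col].nunique() < 2:
                continue
            univariate[var] = _stats.fit_univariate(table, var)
        backwards = None
        if len(univariate) >= 1 and len(table) > 2:
            backwards = _stats.fit_backwards(table, list(univariate), alpha=self.alpha)
        costs = _stats.cost_report(matrix, self.panels)
        return CosegregationResults(
            matrix=matrix,
            paternity_reports=reports,
            dropped_families=dropped,
            structure=table,
            univariate=univariate,
            backwards=backwards,
            costs=costs,
            panels=self.panels,
        )
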