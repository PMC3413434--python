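"""Family-structure covariates, exclusion-proportion regressions, cost model.

The response analysed throughout is the per-family proportion of candidate
genes excluded by cosegregation.  Family-structure covariates (numbers of
genotyped affected and unaffected sibs, availability of parental DNA,
sibship size) enter ordinary least squares as treatment-coded categorical
dummies, each variable's reference level being the category with the
highest expected exclusion success (affected ">=3", unaffected "0",
parental DNA "No", sibship ">=5"), so each coefficient is exactly the level
mean minus the reference mean.  Backwards elimination removes, at each
step, the variable with the largest multi-degree-of-freedom F-test p-value
above alpha (a per-dummy criterion is available as an option).  Proportions
are modelled by plain linear regression — no logistic or beta refinement is
attempted.

The sequencing cost model assumes cost directly proportional to transcript
size: fold savings for a family is total panel transcript size over the
transcript size of the genes it must still sequence (everything not
EXCLUDED, including INCONSISTENT and uninformative genes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cosegregation import EXCLUDED, ExclusionCall, ExclusionMatrix
from .pedigree import GenePanel, NuclearFamily

logger = logging.getLogger(__name__)

GE3 = "≥3"
GE5 = "≥5"

#: variable name -> (table column, reference level, ordered levels)
VARIABLES = {
    "affected": ("affected_bin", GE3, ("1", "2", GE3)),
    "unaffected": ("unaffected_bin", "0", ("0", "1", "2")),
    "maternal": ("maternal_dna", "No", ("No", "Yes")),
    "paternal": ("paternal_dna", "No", ("No", "Yes")),
    "sibship": ("sibship_bin", GE5, ("2", "3", "4", GE5)),
}


@dataclass(frozen=True)
class FamilyStructure:
    """Genotyped-member counts and DNA availability for one family."""

    family_id: str
    n_affected_analyzed: int
    n_unaffected_analyzed: int
    maternal_dna: bool
    paternal_dna: bool
    sibship_size: int


def _bin_affected(n: int) -> str:
    return GE3 if n >= 3 else str(n)


def _bin_unaffected(n: int) -> str:
    # the reference table's top category is "2"; larger counts are binned
    # with it ("2(+)")
    return "2" if n >= 2 else str(n)


def _bin_sibship(n: int) -> str:
    if n >= 5:
        return GE5
    return str(max(n, 2))


def family_structure(family: NuclearFamily) -> FamilyStructure:
    """Covariates for one family; counts are of genotyped individuals."""

    def typed(person):
        return person is not None and bool(person.genotypes)

    return FamilyStructure(
        family_id=family.family_id,
        n_affected_analyzed=sum(typed(c) for c in family.affected_children()),
        n_unaffected_analyzed=sum(typed(c) for c in family.unaffected_children()),
        maternal_dna=typed(family.mother),
        paternal_dna=typed(family.father),
        sibship_size=len(family.children),
    )


def structure_table(
    cohort: Sequence[NuclearFamily], matrix: ExclusionMatrix
) -> pd.DataFrame:
    """One row per family: covariates, categorical bins, proportion excluded."""
    rows = []
    for fam in cohort:
        s = family_structure(fam)
        rows.append(
            {
                "family_id": s.family_id,
                "n_affected": s.n_affected_analyzed,
                "n_unaffected": s.n_unaffected_analyzed,
                "maternal_dna": "Yes" if s.maternal_dna else "No",
                "paternal_dna": "Yes" if s.paternal_dna else "No",
                "sibship_size": s.sibship_size,
                "affected_bin": _bin_affected(s.n_affected_analyzed),
                "unaffected_bin": _bin_unaffected(s.n_unaffected_analyzed),
                "sibship_bin": _bin_sibship(s.sibship_size),
                "proportion_excluded": matrix.proportion_excluded(fam.family_id),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TermEstimate:
    level: str
    n_families: int
    group_mean: float
    group_se: float
    estimate: float  # 0 for the reference level
    std_error: float | None
    p_value: float | None


@dataclass
class RegressionResult:
    """Univariate OLS of exclusion proportion on one categorical variable."""

    variable: str
    reference_level: str
    terms: list
    intercept: float
    residual_df: int
    sm_results: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": self.variable,
                    "category": t.level,
                    "n": t.n_families,
                    "mean": t.group_mean,
                    "mean_se": t.group_se,
                    "estimate": t.estimate,
                    "estimate_se": t.std_error,
                    "p_value": t.p_value,
                }
                for t in self.terms
            ]
        )


def _design(table: pd.DataFrame, variables: Sequence[str]):
    """Treatment-coded dummy design with the documented reference levels."""
    cols = {}
    groups = {}
    for var in variables:
        col, ref, levels = VARIABLES[var]
        present = [lv for lv in levels if (table[col] == lv).any()]
        for lv in levels:
            if lv not in present and lv != ref:
                logger.warning("variable %s: level %r has no families; dropped", var, lv)
        names = []
        for lv in present:
            if lv == ref:
                continue
            name = f"{var}[{lv}]"
            cols[name] = (table[col] == lv).astype(float).to_numpy()
            names.append(name)
        groups[var] = names
    X = pd.DataFrame(cols, index=table.index)
    X.insert(0, "Intercept", 1.0)
    return X, groups


def fit_univariate(table: pd.DataFrame, variable: str) -> RegressionResult:
    """OLS of proportion excluded on one treatment-coded categorical variable.

    Coefficients equal level mean minus reference mean exactly; standard
    errors come from the pooled residual variance, p-values from the t
    distribution on the residual degrees of freedom.  Levels with no
    families are dropped with a warning.
    """
    col, ref, levels = VARIABLES[variable]
    present = [lv for lv in levels if (table[col] == lv).any()]
    if len(present) < 2:
        raise ValueError(f"variable {variable}: needs >=2 non-empty levels")
    y = table["proportion_excluded"].to_numpy(dtype=float)
    X, groups = _design(table, [variable])
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(y, X).fit()
    terms = []
    for lv in present:
        sel = (table[col] == lv).to_numpy()
        n = int(sel.sum())
        mean = float(y[sel].mean())
        se = float(y[sel].std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        if lv == ref:
            terms.append(TermEstimate(lv, n, mean, se, 0.0, None, None))
        else:
            name = f"{variable}[{lv}]"
            terms.append(
                TermEstimate(
                    lv,
                    n,
                    mean,
                    se,
                    float(res.params[name]),
                    float(res.bse[name]),
                    float(res.pvalues[name]),
                )
            )
    ref_sel = (table[col] == ref).to_numpy()
    intercept = float(y[ref_sel].mean()) if ref_sel.any() else float(res.params["Intercept"])
    return RegressionResult(
        variable=variable,
        reference_level=ref,
        terms=terms,
        intercept=intercept,
        residual_df=int(res.df_resid),
        sm_results=res,
    )


def _rss(y, X) -> tuple:
    res = sm.OLS(y, X).fit()
    return float(res.ssr), int(res.df_resid), res


def _variable_p(y, X_full, groups, var, rss_full, df_full, per_dummy, full_res):
    if per_dummy:
        ps = [float(full_res.pvalues[n]) for n in groups[var]]
        ps = [p for p in ps if not math.isnan(p)]
        return min(ps) if ps else 1.0
    X_red = X_full.drop(columns=groups[var])
    rss_red, _, _ = _rss(y, X_red)
    q = len(groups[var])
    if df_full <= 0:
        return 0.0 if rss_red > rss_full + 1e-12 else 1.0
    if rss_full <= 1e-12:
        return 0.0 if rss_red > 1e-12 else 1.0
    F = ((rss_red - rss_full) / q) / (rss_full / df_full)
    return float(sps.f.sf(F, q, df_full))


@dataclass
class BackwardsEliminationResult:
    """Final multivariate model after backwards elimination."""

    retained: list
    eliminated: list  # (variable, p at removal) in removal order
    variable_p: dict  # retained variable -> final F-test p
    sm_results: object
    design_columns: list

    @property
    def intercept_only(self) -> bool:
        return not self.retained


def fit_backwards(
    table: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.05,
    per_dummy: bool = False,
) -> BackwardsEliminationResult:
    """Backwards elimination from the full multivariate OLS model.

    At each step the variable with the largest p-value above *alpha* is
    removed; by default the p-value is the multi-df F test of the
    variable's whole dummy block (``per_dummy=True`` uses the smallest
    per-dummy t-test p instead).  Ties are broken by removing the variable
    later in the input order.  May return an intercept-only model.
    """
    retained = [v for v in variables if len({*table[VARIABLES[v][0]]}) >= 2]
    for v in variables:
        if v not in retained:
            logger.warning("variable %s has <2 levels in this table; not entered", v)
    eliminated = []
    while retained:
        y = table["proportion_excluded"].to_numpy(dtype=float)
        X, groups = _design(table, retained)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss_full, df_full, full_res = _rss(y, X)
            pvals = {
                v: _variable_p(y, X, groups, v, rss_full, df_full, per_dummy, full_res)
                for v in retained
            }
        removable = [v for v in retained if pvals[v] > alpha]
        if not removable:
            break
        worst_p = max(pvals[v] for v in removable)
        # tie-break: remove the variable later in the caller's input order
        ties = [v for v in removable if pvals[v] == worst_p]
        victim = max(ties, key=lambda v: list(variables).index(v))
        retained.remove(victim)
        eliminated.append((victim, worst_p))

    y = table["proportion_excluded"].to_numpy(dtype=float)
    X, groups = _design(table, retained)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_full, df_full, full_res = _rss(y, X)
        final_p = {
            v: _variable_p(y, X, groups, v, rss_full, df_full, per_dummy, full_res)
            for v in retained
        }
    return BackwardsEliminationResult(
        retained=retained,
        eliminated=eliminated,
        variable_p=final_p,
        sm_results=full_res,
        design_columns=list(X.columns),
    )


@dataclass(frozen=True)
class CostEstimate:
    """Sequencing cost savings from exclusion, in transcript-size units."""

    family_id: str
    total_size: int
    retained_size: int
    fold_savings: float
    all_excluded: bool

    @property
    def is_infinite(self) -> bool:
        return self.all_excluded


def cost_savings(calls: Sequence[ExclusionCall], panels: Sequence[GenePanel]) -> CostEstimate:
    """Fold cost savings for one family's row of exclusion calls.

    fold = sum of transcript sizes over analyzed genes / sum over genes
    still to sequence (everything not EXCLUDED; INCONSISTENT and
    uninformative genes count as retained).  Infinite (flagged) when every
    gene is excluded.  Scale-invariant in the transcript sizes.
    """
    sizes = {p.gene: p.transcript_size for p in panels}
    analyzed = [c for c in calls if c.analyzed]
    missing = [c.gene for c in analyzed if c.gene not in sizes]
    if missing:
        raise ValueError(f"no transcript size for genes: {missing}")
    total = sum(sizes[c.gene] for c in analyzed)
    retained = sum(sizes[c.gene] for c in analyzed if c.status != EXCLUDED)
    family_id = analyzed[0].family_id if analyzed else "?"
    if retained == 0:
        return CostEstimate(family_id, total, 0, math.inf, True)
    return CostEstimate(family_id, total, retained, total / retained, False)


def regression_report(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Long-format report mirroring the standard cohort table layout."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)


def cost_report(matrix: ExclusionMatrix, panels: Sequence[GenePanel]) -> pd.DataFrame:
    rows = []
    for fid in matrix.family_ids:
        est = cost_savings(matrix.family_calls(fid), panels)
        rows.append(
            {
                "family_id": fid,
                "total_transcript_bp": est.total_size,
                "retained_transcript_bp": est.retained_size,
                "fold_savings": est.fold_savings,
            }
        )
    return pd.DataFrame(rows)
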