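"""Published reference values used as inputs by examples and checks.

``COHORT_SUMMARY`` holds the family-structure summary reported for a
29-family non-consanguineous arRP cohort analysed with SNP-panel
cosegregation: for each structure variable, the category levels with the
number of families and the mean proportion of candidate loci excluded in
that category.  Expanding each category to its family count at the group
mean reconstructs a family-level table on which the univariate regressions
can be re-fitted; because treatment-coded OLS coefficients equal level mean
minus reference mean, the reconstruction reproduces the published parameter
estimates exactly.
"""

from __future__ import annotations

import pandas as pd

from .stats import GE3, GE5, VARIABLES, RegressionResult, fit_univariate

#: variable -> list of (level, n_families, mean proportion excluded)
COHORT_SUMMARY = {
    "affected": [("1", 9, 0.290), ("2", 13, 0.714), (GE3, 7, 0.898)],
    "unaffected": [("0", 12, 0.768), ("1", 11, 0.516), ("2", 6, 0.548)],
    "maternal": [("No", 5, 0.743), ("Yes", 24, 0.603)],
    "paternal": [("No", 8, 0.772), ("Yes", 21, 0.571)],
    "sibship": [("2", 4, 0.384), ("3", 12, 0.717), ("4", 8, 0.509), (GE5, 5, 0.793)],
}


def reference_table(variable: str) -> pd.DataFrame:
    """Family-level table for one variable, each family at its group mean."""
    col = VARIABLES[variable][0]
    rows = []
    i = 0
    for level, n, mean in COHORT_SUMMARY[variable]:
        for _ in range(n):
            i += 1
            rows.append({"family_id": f"R{i:02d}", col: level, "proportion_excluded": mean})
    return pd.DataFrame(rows)


def reference_univariate_fits() -> dict:
    """Univariate OLS fits on the reconstructed reference tables."""
    out: dict[str, RegressionResult] = {}
    for var in COHORT_SUMMARY:
        out[var] = fit_univariate(reference_table(var), var)
    return out
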