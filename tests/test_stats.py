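"""Structure covariates, OLS reconstruction, backwards elimination, cost model."""

import math

import numpy as np
import pandas as pd
import pytest

from snpcoseg.cosegregation import ExclusionCall, build_matrix
from snpcoseg.datasets import COHORT_SUMMARY, reference_table, reference_univariate_fits
from snpcoseg.stats import (
    GE3,
    GE5,
    VARIABLES,
    cost_savings,
    fit_backwards,
    fit_univariate,
    structure_table,
)
from snpcoseg.simulate import FamilySpec, SimulationConfig, default_panels, simulate_cohort

from helpers import make_panel


def _call(gene, status, fid="F1"):
    return ExclusionCall(fid, gene, status, "", 1, True)


class TestStructureTable:
    def test_binning_and_proportions(self):
        panels = default_panels()[:4]
        cohort = simulate_cohort(
            SimulationConfig(
                n_families=1,
                panels=panels,
                causal_gene=panels[0].gene,
                family_structure=FamilySpec(3, 0, mother_typed=False,
                                            sibship_size=5),
                seed=2,
            )
        )
        matrix = build_matrix(cohort.families, panels)
        table = structure_table(cohort.families, matrix)
        row = table.iloc[0]
        assert row["affected_bin"] == GE3
        assert row["maternal_dna"] == "No" and row["paternal_dna"] == "Yes"
        assert row["sibship_bin"] == GE5
        fid = cohort.families[0].family_id
        assert row["proportion_excluded"] == matrix.proportion_excluded(fid)


class TestFitUnivariate:
    def test_coefficients_equal_group_mean_differences(self):
        """Treatment-coded OLS: estimate == level mean - reference mean."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            bins = rng.choice(["1", "2", GE3], size=24)
            table = pd.DataFrame(
                {"affected_bin": bins, "proportion_excluded": rng.random(24)}
            )
            result = fit_univariate(table, "affected")
            ref_mean = table.loc[table["affected_bin"] == GE3,
                                 "proportion_excluded"].mean()
            for t in result.terms:
                level_mean = table.loc[table["affected_bin"] == t.level,
                                       "proportion_excluded"].mean()
                assert t.estimate == pytest.approx(level_mean - ref_mean, abs=1e-12)
            assert result.intercept == pytest.approx(ref_mean, abs=1e-12)

    def test_reference_cohort_reconstruction_matches_published_estimates(self):
        expected = {
            "affected": {"1": -0.608, "2": -0.184},
            "unaffected": {"1": -0.252, "2": -0.220},
            "maternal": {"Yes": -0.140},
            "paternal": {"Yes": -0.201},
            "sibship": {"2": -0.409, "3": -0.076, "4": -0.284},
        }
        fits = reference_univariate_fits()
        for var, coefs in expected.items():
            by_level = {t.level: t.estimate for t in fits[var].terms}
            for level, value in coefs.items():
                assert round(by_level[level], 3) == value

    def test_group_sizes_match_the_published_table(self):
        for var, rows in COHORT_SUMMARY.items():
            assert sum(n for _, n, _ in rows) == 29

    def test_constant_response_within_levels_gives_zero_se(self):
        table = reference_table("affected")
        result = fit_univariate(table, "affected")
        for t in result.terms:
            if t.level != GE3:
                assert t.std_error == pytest.approx(0.0, abs=1e-12)

    def test_equal_proportions_give_zero_coefficients(self):
        table = pd.DataFrame(
            {"affected_bin": ["1", "2", GE3] * 4, "proportion_excluded": 0.5}
        )
        result = fit_univariate(table, "affected")
        assert all(t.estimate == pytest.approx(0.0, abs=1e-12) for t in result.terms)

    def test_single_level_rejected(self):
        table = pd.DataFrame({"affected_bin": ["2"] * 5, "proportion_excluded": 0.5})
        with pytest.raises(ValueError, match="levels"):
            fit_univariate(table, "affected")


def _noise_table(rng, n=40):
    return pd.DataFrame(
        {
            "affected_bin": rng.choice(["1", "2", GE3], size=n),
            "unaffected_bin": rng.choice(["0", "1", "2"], size=n),
            "maternal_dna": rng.choice(["No", "Yes"], size=n),
            "paternal_dna": rng.choice(["No", "Yes"], size=n),
            "sibship_bin": rng.choice(["2", "3", "4", GE5], size=n),
            "proportion_excluded": rng.random(n),
        }
    )


class TestFitBackwards:
    def test_alpha_one_keeps_the_full_model(self):
        table = _noise_table(np.random.default_rng(1))
        result = fit_backwards(table, list(VARIABLES), alpha=1.0)
        assert set(result.retained) == set(VARIABLES)

    def test_single_variable_reduces_to_an_f_test(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        table = _noise_table(rng)
        result = fit_backwards(table, ["affected"], alpha=0.05)
        groups = [
            table.loc[table["affected_bin"] == lv, "proportion_excluded"]
            for lv in ("1", "2", GE3)
        ]
        f_p = sps.f_oneway(*groups).pvalue
        if result.retained:
            assert result.variable_p["affected"] == pytest.approx(f_p, rel=1e-9)
        else:
            assert result.eliminated[0][1] == pytest.approx(f_p, rel=1e-9)

    def test_tie_break_removes_the_later_variable(self):
        rng = np.random.default_rng(3)
        table = _noise_table(rng)
        table["paternal_dna"] = table["maternal_dna"]  # perfectly collinear
        result = fit_backwards(table, ["maternal", "paternal"], alpha=0.05)
        assert result.eliminated[0][0] == "paternal"

    def test_strong_signal_variable_is_retained(self):
        rng = np.random.default_rng(4)
        table = _noise_table(rng, n=60)
        effect = table["affected_bin"].map({"1": 0.2, "2": 0.6, GE3: 0.9})
        table["proportion_excluded"] = effect + 0.03 * rng.standard_normal(60)
        result = fit_backwards(table, list(VARIABLES), alpha=0.05)
        assert "affected" in result.retained
        assert result.variable_p["affected"] < 1e-6

    def test_affected_count_drives_selection_on_generative_truth(self):
        """On simulated cohorts where exclusion success depends only on how
        many affected sibs are genotyped, the affected count dominates
        selection across seeds while noise variables obey the nominal level."""
        retained_sets = []
        seeds = [0, 1, 2, 3, 4]
        for seed in seeds:
            rng = np.random.default_rng(seed)
            panels = default_panels()[:10]
            # only the affected count varies causally; sibship size varies
            # through extra untyped sibs, which carry no genotype information
            specs = []
            for _ in range(36):
                k = int(rng.integers(1, 4))
                specs.append(
                    FamilySpec(
                        n_affected=k,
                        n_unaffected=1,
                        sibship_size=k + 1 + int(rng.integers(0, 3)),
                    )
                )
            cohort = simulate_cohort(
                SimulationConfig(
                    n_families=36,
                    panels=panels,
                    causal_gene=panels[0].gene,
                    family_structure=specs,
                    seed=seed + 100,
                )
            )
            matrix = build_matrix(cohort.families, panels)
            table = structure_table(cohort.families, matrix)
            result = fit_backwards(table, list(VARIABLES), alpha=0.05)
            retained_sets.append(set(result.retained))
        assert all("affected" in s for s in retained_sets)
        assert sum("sibship" in s for s in retained_sets) <= 2

    def test_pure_noise_is_mostly_reduced_to_intercept_only(self):
        """Type-I behaviour: with an independent response, full elimination
        should happen at roughly the nominal rate across seeds."""
        intercept_only = 0
        for seed in range(10):
            table = _noise_table(np.random.default_rng(seed), n=50)
            result = fit_backwards(table, list(VARIABLES), alpha=0.05)
            intercept_only += result.intercept_only
        assert intercept_only >= 6


class TestCostSavings:
    def _panels(self, sizes):
        return [
            make_panel(f"G{i}", ("AG",), transcript_size=s)
            for i, s in enumerate(sizes)
        ]

    def test_fold_savings_examples(self):
        panels = self._panels([10, 10, 80])
        calls = [_call("G0", "INCLUDED"), _call("G1", "INCLUDED"),
                 _call("G2", "EXCLUDED")]
        est = cost_savings(calls, panels)
        assert est.fold_savings == pytest.approx(5.0)
        # equal sizes, 3 of 4 excluded -> 4-fold
        panels4 = self._panels([7, 7, 7, 7])
        calls4 = [_call(f"G{i}", "EXCLUDED") for i in range(3)] + [
            _call("G3", "UNINFORMATIVE_INCLUDED")
        ]
        assert cost_savings(calls4, panels4).fold_savings == pytest.approx(4.0)

    def test_nothing_excluded_is_unity(self):
        panels = self._panels([5, 5])
        calls = [_call("G0", "INCLUDED"), _call("G1", "INCONSISTENT")]
        est = cost_savings(calls, panels)
        assert est.fold_savings == 1.0 and not est.is_infinite

    def test_everything_excluded_is_marked_infinite(self):
        panels = self._panels([5, 5])
        calls = [_call("G0", "EXCLUDED"), _call("G1", "EXCLUDED")]
        est = cost_savings(calls, panels)
        assert math.isinf(est.fold_savings) and est.is_infinite

    def test_scale_invariance(self):
        calls = [_call("G0", "EXCLUDED"), _call("G1", "INCLUDED"),
                 _call("G2", "EXCLUDED")]
        a = cost_savings(calls, self._panels([3, 11, 19]))
        b = cost_savings(calls, self._panels([30, 110, 190]))
        assert a.fold_savings == pytest.approx(b.fold_savings)
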