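import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

import polyrisk as pr
from polyrisk.association import fit_joint_model, fit_marginal_models
from polyrisk.association import test_interaction as interaction_test
from polyrisk.io_cohort import REFERENCE_CATEGORY


def two_group_cohort(build, a, b, c, d, other="high_noncarrier"):
    """reference cells (c cases, d controls), contrast cells (a, b)."""
    return build({REFERENCE_CATEGORY: (c, d), other: (a, b)})


class TestJointModel:
    def test_unadjusted_or_equals_cross_product_ratio(self, small_cohort):
        cohort = two_group_cohort(small_cohort, 30, 10, 20, 40)
        table = fit_joint_model(cohort, "overall", adjust=False)
        # (30*40)/(20*10) = 6.0
        np.testing.assert_allclose(table.or_["high_noncarrier"], 6.0, rtol=1e-7)

    def test_identical_distributions_give_null_ors(self, small_cohort):
        cohort = small_cohort({
            REFERENCE_CATEGORY: (40, 40),
            "high_noncarrier": (25, 25),
            "low_noncarrier": (15, 15),
        })
        table = fit_joint_model(cohort, "overall", adjust=False)
        np.testing.assert_allclose(table.or_.to_numpy(), 1.0, atol=1e-8)

    def test_zero_control_category_flagged_undefined(self, small_cohort):
        cohort = small_cohort({
            REFERENCE_CATEGORY: (30, 30),
            "high_carrier": (8, 0),
            "high_noncarrier": (20, 15),
        })
        table = fit_joint_model(cohort, "overall", adjust=False)
        assert "high_carrier" in table.flags
        assert "high_carrier" not in table.beta.index
        frame = table.to_frame()
        assert np.isnan(frame.loc[frame["category"] == "high_carrier", "OR"]).all()
        # the remaining category still gets a sensible estimate
        assert np.isfinite(table.or_["high_noncarrier"])

    def test_or_equals_exp_beta_and_cov_is_psd(self, small_cohort):
        cohort = small_cohort({
            REFERENCE_CATEGORY: (30, 40),
            "high_noncarrier": (25, 10),
            "low_noncarrier": (9, 21),
        })
        table = fit_joint_model(cohort, "overall", adjust=False)
        np.testing.assert_allclose(table.or_.to_numpy(), np.exp(table.beta.to_numpy()))
        eig = np.linalg.eigvalsh(table.cov.to_numpy())
        assert eig.min() > -1e-10
        assert (table.ci_lo < table.or_).all() and (table.or_ < table.ci_hi).all()

    def test_reference_relabeling_consistency(self, small_cohort):
        # ORs against a different reference are recovered as ratios of ORs,
        # matching the cross-product from the corresponding 2x2 subtable
        cells = {REFERENCE_CATEGORY: (30, 40), "high_noncarrier": (25, 10), "low_noncarrier": (9, 21)}
        table = fit_joint_model(small_cohort(cells), "overall", adjust=False)
        or_high_vs_low = table.or_["high_noncarrier"] / table.or_["low_noncarrier"]
        a, b = cells["high_noncarrier"]
        c, d = cells["low_noncarrier"]
        np.testing.assert_allclose(or_high_vs_low, (a * d) / (c * b), rtol=1e-6)

    def test_controls_only_error(self, small_cohort):
        cohort = small_cohort({REFERENCE_CATEGORY: (0, 50)})
        with pytest.raises(ValueError, match="case"):
            fit_joint_model(cohort, "overall", adjust=False)


@given(
    a=st.integers(5, 60), b=st.integers(5, 60),
    c=st.integers(5, 60), d=st.integers(5, 60),
)
@settings(max_examples=60, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
def test_cross_product_oracle_property(small_cohort, a, b, c, d):
    """Unadjusted logistic OR equals ad/bc on any all-cells>=5 2x2 table."""
    cohort = small_cohort({REFERENCE_CATEGORY: (c, d), "high_noncarrier": (a, b)})
    table = fit_joint_model(cohort, "overall", adjust=False)
    expected = (a * d) / (b * c)
    np.testing.assert_allclose(table.or_["high_noncarrier"], expected, rtol=1e-6)


class TestMarginalModels:
    def _cohort(self, build, carrier_cells, prs_cells=None):
        cells = {}
        for (cat, carrier), (nca, nco) in carrier_cells.items():
            cells[f"{cat}_{'carrier' if carrier else 'noncarrier'}"] = (nca, nco)
        df = build(cells)
        df["prs_category"] = df["joint_category"].str.rsplit("_", n=1).str[0]
        df["carrier"] = df["joint_category"].str.endswith("_carrier")
        return df

    def test_carrier_2x2_oracle(self, small_cohort):
        df = self._cohort(small_cohort, {
            ("intermediate", True): (40, 10),
            ("intermediate", False): (160, 490),
        })
        carrier_tab, _ = fit_marginal_models(df, "overall", adjust=False)
        np.testing.assert_allclose(carrier_tab.or_["carrier"], 12.25, rtol=1e-6)

    def test_equal_carrier_frequency_gives_null_or(self, small_cohort):
        df = self._cohort(small_cohort, {
            ("intermediate", True): (10, 10),
            ("intermediate", False): (200, 200),
        })
        carrier_tab, _ = fit_marginal_models(df, "overall", adjust=False)
        assert carrier_tab.or_["carrier"] == pytest.approx(1.0, abs=1e-6)

    def test_prs_marginal_reference_is_intermediate(self, small_cohort):
        df = self._cohort(small_cohort, {
            ("low", False): (10, 30),
            ("intermediate", False): (30, 30),
            ("high", False): (30, 10),
        })
        _, prs_tab = fit_marginal_models(df, "overall", adjust=False)
        assert prs_tab.reference == "intermediate"
        assert prs_tab.or_["high"] > 1 > prs_tab.or_["low"]


class TestInteraction:
    def _sim_cohort(self, interaction, n=6000, seed=11, carrier_freq=0.05):
        # enough carriers per tertile to keep every product cell populated
        sim = pr.generate_cohort(pr.SimConfig(
            n_individuals=n, n_prs_variants=40, seed=seed,
            carrier_freq_controls=carrier_freq,
            interaction_log_or=interaction,
        ))
        prs_res, _ = pr.score_and_categorize(
            sim.scoring, sim.dosages,
            [p.individual_id for p in sim.phenotypes if p.status == "control"])
        cohort, _ = pr.assemble_cohort(sim.phenotypes, sim.dosages, sim.carrier_truth, prs_res)
        return cohort

    def test_result_contract(self):
        cohort = self._sim_cohort(0.0)
        res = interaction_test(cohort, "overall")
        assert res.lrt_stat >= 0 and res.wald_stat >= 0
        assert res.lrt_df == 2 and res.wald_df == 2
        assert 0 <= res.lrt_p <= 1 and 0 <= res.wald_p <= 1

    def test_strong_product_term_detected(self):
        cohort = self._sim_cohort(1.5, n=20000, seed=4)
        res = interaction_test(cohort, "overall")
        assert res.lrt_p < 1e-3 and res.wald_p < 1e-3

    def test_continuous_prs_variant_has_df_1(self):
        cohort = self._sim_cohort(0.0)
        res = interaction_test(cohort, "overall", continuous_prs=True)
        assert res.lrt_df == 1 and res.wald_df == 1

    def test_empty_product_cell_reduces_df(self, small_cohort):
        df = small_cohort({
            REFERENCE_CATEGORY: (30, 30),
            "high_noncarrier": (25, 15),
            "low_noncarrier": (10, 20),
            "intermediate_carrier": (6, 6),
            "high_carrier": (8, 5),  # no low-tertile carriers at all
        })
        df["prs_category"] = df["joint_category"].str.rsplit("_", n=1).str[0]
        df["carrier"] = df["joint_category"].str.endswith("_carrier")
        res = interaction_test(df, "overall", adjust=False)
        assert res.lrt_df == 1


class TestOutcomeContrasts:
    @staticmethod
    def _mark(df, category, label, k):
        ids = df[(df["joint_category"] == category) & (df["status"] == "case")].index
        df.loc[ids[:k], "outcome"] = label
        return df

    def test_aggressive_contrast_excludes_nonaggressive_cases(self, small_cohort):
        df = small_cohort({REFERENCE_CATEGORY: (20, 30), "high_noncarrier": (20, 10)})
        self._mark(df, "high_noncarrier", "aggressive", 10)
        self._mark(df, REFERENCE_CATEGORY, "aggressive", 8)
        table = fit_joint_model(df, "aggressive", adjust=False)
        assert table.counts.loc["high_noncarrier", "n_cases"] == 10
        assert table.counts.loc[REFERENCE_CATEGORY, "n_cases"] == 8
        # the overall contrast keeps every case
        table_all = fit_joint_model(df, "overall", adjust=False)
        assert table_all.counts.loc["high_noncarrier", "n_cases"] == 20

    def test_metastatic_contrast_uses_metastatic_cases_only(self, small_cohort):
        df = small_cohort({REFERENCE_CATEGORY: (20, 30), "high_noncarrier": (20, 10)})
        self._mark(df, "high_noncarrier", "metastatic-aggressive", 4)
        self._mark(df, REFERENCE_CATEGORY, "metastatic-aggressive", 5)
        table = fit_joint_model(df, "metastatic", adjust=False)
        assert table.counts.loc["high_noncarrier", "n_cases"] == 4
        agg = fit_joint_model(df, "aggressive", adjust=False)
        assert agg.counts.loc["high_noncarrier", "n_cases"] == 4  # metastatic within aggressive
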