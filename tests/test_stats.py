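import numpy as np
import pytest
from scipy import stats as sps

from funconn import fdr_adjust, partial_correlation, posthoc_pairwise, two_way_anova
from funconn.stats import anova_table_many


def balanced_cells(means, n, sd, seed):
    """Balanced 2x2 sample: returns values, sex, disease arrays."""
    rng = np.random.default_rng(seed)
    values, sex, disease = [], [], []
    for (s, d), m in zip([("female", "patient"), ("female", "control"),
                          ("male", "patient"), ("male", "control")], means):
        values.extend(rng.normal(m, sd, size=n))
        sex.extend([s] * n)
        disease.extend([d] * n)
    return np.array(values), np.array(sex), np.array(disease)


class TestTwoWayAnova:
    def test_pure_disease_effect_loads_only_on_disease(self):
        sex = np.array(["female"] * 10 + ["male"] * 10)
        disease = np.tile(["patient"] * 5 + ["control"] * 5, 2)
        values = (disease == "patient").astype(float)
        res = two_way_anova(values, sex, disease)
        assert res.f_sex == pytest.approx(0.0, abs=1e-20)
        assert res.f_interaction == pytest.approx(0.0, abs=1e-20)
        assert res.p_disease < 1e-12

    def test_zero_variance_yields_null_result(self):
        values, sex, disease = balanced_cells([1, 1, 1, 1], 5, 0.0, 0)
        res = two_way_anova(values, sex, disease)
        assert res.f_interaction == 0.0
        assert res.p_interaction == 1.0

    def test_interaction_f_matches_balanced_closed_form(self):
        """For a balanced design the interaction F has the textbook closed
        form n * (m11 - m12 - m21 + m22)^2 / (4 * MSE)."""
        n, sd = 5, 0.1
        values, sex, disease = balanced_cells([0, 0, 0, 1], n, sd, 42)
        res = two_way_anova(values, sex, disease)
        cells = {}
        sse = 0.0
        for s in ("female", "male"):
            for d in ("patient", "control"):
                v = values[(sex == s) & (disease == d)]
                cells[(s, d)] = v.mean()
                sse += ((v - v.mean()) ** 2).sum()
        contrast = (cells[("female", "patient")] - cells[("female", "control")]
                    - cells[("male", "patient")] + cells[("male", "control")])
        mse = sse / (4 * n - 4)
        f_expected = n * contrast ** 2 / (4 * mse)
        assert res.f_interaction == pytest.approx(f_expected, rel=1e-10)

    def test_matches_statsmodels_type2_on_unbalanced_data(self):
        """Cross-check against the statsmodels OLS/anova_lm route on an
        unbalanced (18 vs 20) layout."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(7)
        sex = np.array(["female"] * 20 + ["male"] * 18 + ["female"] * 20
                       + ["male"] * 18)
        disease = np.array(["patient"] * 38 + ["control"] * 38)
        values = rng.normal(size=76) + 0.5 * (sex == "female") \
            + 0.3 * (disease == "patient") * (sex == "female")
        res = two_way_anova(values, sex, disease, ss_type=2)
        df = pd.DataFrame({"y": values, "sex": sex, "disease": disease})
        fit = ols("y ~ C(sex) * C(disease)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res.f_sex == pytest.approx(table.loc["C(sex)", "F"], rel=1e-8)
        assert res.f_disease == pytest.approx(
            table.loc["C(disease)", "F"], rel=1e-8)
        assert res.f_interaction == pytest.approx(
            table.loc["C(sex):C(disease)", "F"], rel=1e-8)
        assert res.p_interaction == pytest.approx(
            table.loc["C(sex):C(disease)", "PR(>F)"], rel=1e-8)

    def test_factor_label_swap_invariance_on_balanced_data(self):
        values, sex, disease = balanced_cells([0.3, 0.1, 0.2, 0.4], 6, 0.2, 3)
        res = two_way_anova(values, sex, disease)
        swapped = two_way_anova(values, disease, sex)
        assert res.f_interaction == pytest.approx(swapped.f_interaction)
        assert res.f_sex == pytest.approx(swapped.f_disease)

    def test_empty_cell_rejected(self):
        values = np.arange(10.0)
        sex = np.array(["female"] * 10)
        disease = np.array(["patient"] * 5 + ["control"] * 5)
        with pytest.raises(ValueError):
            two_way_anova(values, sex, disease)

    def test_vectorized_table_matches_scalar_route(self):
        rng = np.random.default_rng(9)
        values, sex, disease = balanced_cells([0, 0.5, 0.2, 0.1], 8, 0.3, 5)
        extra = rng.normal(size=values.size)
        table = anova_table_many(np.column_stack([values, extra]),
                                 sex, disease)
        single = two_way_anova(values, sex, disease)
        assert table.loc[0, "F_interaction"] == pytest.approx(
            single.f_interaction)
        assert table.shape[0] == 2


class TestFdrAdjust:
    def test_step_up_accepts_dense_small_pvalues(self):
        p_adj, reject = fdr_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_single_pvalue_reduces_to_raw_threshold(self):
        _, reject = fdr_adjust([0.04], q=0.05)
        assert reject[0]

    def test_all_ones_rejected_nowhere(self):
        p_adj, reject = fdr_adjust([1.0, 1.0, 1.0])
        assert not reject.any()
        np.testing.assert_allclose(p_adj, 1.0)

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_adjusted_values_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        p_adj, _ = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()

    def test_fdr_controlled_in_mixture_simulation(self):
        """Over replicates of a null/alternative p-value mixture, the
        realized false-discovery proportion stays near or below q."""
        rng = np.random.default_rng(1)
        q = 0.1
        fdp = []
        for _ in range(200):
            null_p = rng.uniform(size=40)
            alt_p = rng.beta(0.1, 8.0, size=10)
            p = np.concatenate([null_p, alt_p])
            _, reject = fdr_adjust(p, q=q)
            if reject.any():
                fdp.append(reject[:40].sum() / reject.sum())
            else:
                fdp.append(0.0)
        assert np.mean(fdp) <= q + 0.03

    def test_by_variant_is_more_conservative(self):
        p = [0.01, 0.02, 0.04, 0.2]
        bh, _ = fdr_adjust(p, method="bh")
        by, _ = fdr_adjust(p, method="by")
        assert (by >= bh - 1e-12).all()


class TestPosthocPairwise:
    def test_identical_cells_show_nothing(self):
        values, sex, disease = balanced_cells([0.5] * 4, 6, 0.0, 0)
        table = posthoc_pairwise(values, sex, disease)
        assert not table["reject"].any()

    def test_shifted_cell_flags_its_three_contrasts(self):
        values, sex, disease = balanced_cells([5.0, 0, 0, 0], 18, 1.0, 1)
        table = posthoc_pairwise(values, sex, disease)
        involving = table[(table["cell_a"] == "female:patient")
                          | (table["cell_b"] == "female:patient")]
        others = table[(table["cell_a"] != "female:patient")
                       & (table["cell_b"] != "female:patient")]
        assert involving["reject"].all()
        assert not others["reject"].any()

    def test_within_sex_disease_contrasts_labelled(self):
        values, sex, disease = balanced_cells([1, 2, 3, 4], 5, 0.5, 2)
        table = posthoc_pairwise(values, sex, disease)
        assert table["within_sex_disease_contrast"].sum() == 2

    def test_two_cell_degenerate_input_rejected(self):
        values = np.arange(12.0)
        sex = np.array(["female"] * 12)
        disease = np.array(["patient"] * 6 + ["control"] * 6)
        with pytest.raises(ValueError):
            posthoc_pairwise(values, sex, disease)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r_partial == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_identity_relationship_is_perfect(self):
        x = np.arange(20.0)
        res = partial_correlation(x, x, np.random.default_rng(1).normal(size=20))
        assert res.r_partial == pytest.approx(1.0)
        assert res.p == 0.0

    def test_orthogonal_covariate_changes_nothing(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=60), rng.normal(size=60)
        z = rng.normal(size=60)
        z -= np.polyval(np.polyfit(x, z, 0), 0)    # demean only
        plain = partial_correlation(x, y)
        # residualizing on pure noise moves r only marginally
        res = partial_correlation(x, y, z)
        assert res.r_partial == pytest.approx(plain.r_partial, abs=0.05)

    def test_confound_removed(self):
        """x and y share a common driver; controlling it collapses the
        correlation while the plain correlation stays large."""
        rng = np.random.default_rng(3)
        confound = rng.normal(size=300)
        x = confound + 0.3 * rng.normal(size=300)
        y = confound + 0.3 * rng.normal(size=300)
        plain = partial_correlation(x, y)
        controlled = partial_correlation(x, y, confound)
        assert plain.r_partial > 0.8
        assert abs(controlled.r_partial) < 0.15

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=50),
                           "y": rng.normal(size=50),
                           "z": rng.normal(size=50)})
        df["y"] += 0.5 * df["x"] + 0.3 * df["z"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        res = partial_correlation(df["x"], df["y"], df["z"])
        assert res.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        z = rng.normal(size=30)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))

    def test_degrees_of_freedom_accounting(self):
        rng = np.random.default_rng(6)
        res = partial_correlation(rng.normal(size=25), rng.normal(size=25),
                                  rng.normal(size=(25, 3)))
        assert res.dof == 25 - 2 - 3
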