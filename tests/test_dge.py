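"""Weighted linear models, variance moderation and FDR against direct oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastevo import (
    Contrast,
    CountMatrix,
    SampleDesign,
    SimConfig,
    ValidationError,
    bh_fdr,
    ebayes_moderate,
    fit_contrast,
    run_standard_contrasts,
    simulate_experiment,
    squeeze_var,
    standard_contrasts,
    tmm_factors,
    trigamma_inverse,
    voom_weights,
    weighted_lm,
)
from plastevo.dge import LinearFit


def two_group_design(n_per_group):
    table = pd.DataFrame(
        {
            "line_type": ["control"] * (2 * n_per_group),
            "treatment": ["unsprayed"] * n_per_group + ["sprayed"] * n_per_group,
            "timepoint": [8] * (2 * n_per_group),
        },
        index=pd.Index([f"s{j}" for j in range(2 * n_per_group)], name="sample"),
    )
    return SampleDesign(table)


TWO_GROUP = Contrast(
    "spray", {"control.sprayed.8": 1.0, "control.unsprayed.8": -1.0}
)


def bh_stepup_oracle(p):
    """Hand evaluation of the step-up rule, independent of statsmodels."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.37], [0.37]),
            (
                [0.005, 0.009, 0.05, 0.5, 1.0],
                [0.0225, 0.0225, 0.05 * 5 / 3, 0.625, 1.0],
            ),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_stepup_oracle_and_is_monotone(self, p):
        adj = bh_fdr(p)
        np.testing.assert_allclose(adj, bh_stepup_oracle(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestTrigammaInverse:
    def test_known_identity(self):
        assert trigamma_inverse(np.pi**2 / 6) == pytest.approx(1.0, abs=1e-8)

    def test_round_trip(self):
        from scipy.special import polygamma

        for x in (0.1, 0.5, 2.0, 25.0):
            assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(
                x, rel=1e-6
            )


class TestWeightedLm:
    def test_unit_weights_match_normal_equations(self):
        """With all weights one the fit must agree with a direct normal-equations
        solution and, for a two-group design, with group-mean differences."""
        rng = np.random.default_rng(8)
        design = two_group_design(3)
        X = design.design_matrix().to_numpy()
        y = pd.DataFrame(
            rng.normal(size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=design.sample_ids,
        )
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        fit = weighted_lm(y, w, design)
        cf = fit_contrast(fit, TWO_GROUP)

        theta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy().T).T
        resid = y.to_numpy() - theta @ X.T
        s2 = (resid**2).sum(axis=1) / (6 - 2)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), theta, atol=1e-10)
        np.testing.assert_allclose(cf["sigma2"], s2, atol=1e-10)
        diff = y.iloc[:, 3:].mean(axis=1) - y.iloc[:, :3].mean(axis=1)
        np.testing.assert_allclose(cf["beta"], diff, atol=1e-10)
        np.testing.assert_allclose(cf["v_unscaled"], 2.0 / 3.0, atol=1e-12)

    def test_weighted_fit_matches_per_gene_wls(self):
        rng = np.random.default_rng(9)
        design = two_group_design(4)
        X = design.design_matrix().to_numpy()
        y = pd.DataFrame(
            rng.normal(size=(6, 8)), index=[f"g{i}" for i in range(6)],
            columns=design.sample_ids,
        )
        w = pd.DataFrame(
            rng.uniform(0.2, 5.0, size=(6, 8)), index=y.index, columns=y.columns
        )
        fit = weighted_lm(y, w, design)
        for g in range(6):
            Wg = np.diag(w.iloc[g])
            theta = np.linalg.solve(X.T @ Wg @ X, X.T @ Wg @ y.iloc[g])
            np.testing.assert_allclose(fit.coefficients.iloc[g], theta, atol=1e-10)

    def test_all_zero_contrast_rejected(self):
        with pytest.raises(ValidationError):
            Contrast("null", {"a": 0.0, "b": 0.0})

    def test_singular_weight_pattern_names_gene(self):
        design = two_group_design(2)
        y = pd.DataFrame(
            np.ones((2, 4)), index=["gOK", "gBAD"], columns=design.sample_ids
        )
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        w.loc["gBAD", ["s2", "s3"]] = 0.0  # kills one cell entirely
        with pytest.raises(ValidationError, match="gBAD"):
            weighted_lm(y, w, design)

    def test_recovers_planted_effect_at_low_dispersion(self):
        config = SimConfig(
            n_genes=300,
            samples_per_cell=3,
            dispersion_a0=0.0,
            dispersion_a1=1e-6,
            baseline_log2cpm_mean=8.0,
            baseline_log2cpm_sd=0.5,
            frac_plastic=0.2,  # mostly-null transcriptome: TMM's assumption
            frac_evolved=0.0,
            frac_both=0.0,
            effect_lfc_mean=2.0,
            effect_lfc_sd=0.0,
            seed=6,
        )
        counts, design, truth = simulate_experiment(config)
        res = run_standard_contrasts(counts, design)["plastic_control_pooled"]
        plastic = truth.table["true_plastic_lfc"] != 0
        err = res["logFC"][plastic] - truth.table.loc[plastic, "true_plastic_lfc"]
        assert np.abs(err).mean() < 0.05


class TestSqueezeVar:
    def test_recovers_prior_parameters(self):
        rng = np.random.default_rng(10)
        d0, s02, dg, n = 4.0, 2.0, 10, 20000
        true_var = s02 * d0 / rng.chisquare(d0, n)
        s2 = true_var * rng.chisquare(dg, n) / dg
        d0_hat, s02_hat, squeezed = squeeze_var(s2, dg)
        assert d0_hat == pytest.approx(d0, abs=1.0)
        assert s02_hat == pytest.approx(s02, abs=0.2)
        # shrinkage: squeezed variances track the true variances better
        # (log scale: the inverse-chi-square prior is heavy tailed)
        mse_raw = np.mean((np.log(s2) - np.log(true_var)) ** 2)
        mse_squeezed = np.mean((np.log(squeezed) - np.log(true_var)) ** 2)
        assert mse_squeezed < mse_raw

    def test_homogeneous_variances_give_infinite_prior_df(self):
        rng = np.random.default_rng(11)
        s2 = np.full(200, 3.0) * np.exp(rng.normal(0, 1e-8, 200))
        d0, s02, squeezed = squeeze_var(s2, 50)
        assert np.isinf(d0)
        assert s02 == pytest.approx(3.0, rel=0.05)
        np.testing.assert_allclose(squeezed, s02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            squeeze_var(np.zeros(100), 5)
        with pytest.raises(ValidationError):
            squeeze_var(np.ones(5), 5)


class TestEbayesModerate:
    @staticmethod
    def contrast_fit(rng, n=50, df=6):
        return pd.DataFrame(
            {
                "beta": rng.normal(size=n),
                "v_unscaled": np.full(n, 0.5),
                "sigma2": rng.chisquare(df, n) / df,
                "df": df,
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_forced_zero_prior_df_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(12)
        cf = self.contrast_fit(rng)
        res = ebayes_moderate(cf, d0=0.0, s02=1.0)
        t_ord = cf["beta"] / np.sqrt(cf["sigma2"] * cf["v_unscaled"])
        np.testing.assert_allclose(res["t"], t_ord, atol=1e-12)

    def test_sign_of_t_matches_sign_of_lfc(self):
        rng = np.random.default_rng(13)
        res = ebayes_moderate(self.contrast_fit(rng))
        assert (np.sign(res["t"]) == np.sign(res["logFC"])).all()
        assert ((res["P.Value"] >= 0) & (res["P.Value"] <= 1)).all()
        assert (res["adj.P.Val"] >= res["P.Value"] - 1e-15).all()

    def test_infinite_prior_df_uses_normal_tail(self):
        rng = np.random.default_rng(14)
        cf = self.contrast_fit(rng)
        res = ebayes_moderate(cf, d0=np.inf, s02=1.0)
        from scipy import stats

        np.testing.assert_allclose(
            res["P.Value"], 2 * stats.norm.sf(np.abs(res["t"])), atol=1e-12
        )


class TestVoom:
    def test_flat_mean_variance_gives_near_constant_weights(self):
        """Counts with (log-scale) constant variance must produce a flat trend,
        hence weights within a modest band of each other."""
        config = SimConfig(
            n_genes=2000,
            samples_per_cell=4,
            baseline_log2cpm_mean=9.0,
            baseline_log2cpm_sd=0.3,
            dispersion_a0=0.0,
            dispersion_a1=0.05,
            frac_plastic=0.0,
            frac_evolved=0.0,
            frac_both=0.0,
            seed=15,
        )
        counts, design, _ = simulate_experiment(config)
        v = voom_weights(counts, tmm_factors(counts), design)
        w = v.weights.to_numpy()
        assert w.max() / w.min() < 1.2

    def test_library_scale_invariance(self, small_experiment):
        counts, design, _ = small_experiment
        factors = tmm_factors(counts)
        v1 = voom_weights(counts, factors, design)
        scaled = CountMatrix(counts.counts.copy(), counts.lib_sizes * 4.0)
        v2 = voom_weights(scaled, tmm_factors(scaled), design)
        np.testing.assert_allclose(
            v2.weights.to_numpy(), v1.weights.to_numpy(), rtol=1e-3
        )

    def test_zero_residual_variance_gene_gets_finite_weight(self):
        design = two_group_design(3)
        base = np.array([[50, 50, 50, 50, 50, 50], [10, 60, 35, 20, 80, 45]])
        filler = 1_000_000 - base.sum(axis=0)
        counts = CountMatrix(
            pd.DataFrame(
                np.vstack([base, filler]),
                index=["gFLAT", "gVAR", "gFILL"],
                columns=design.sample_ids,
            )
        )
        v = voom_weights(counts, tmm_factors(counts), design)
        assert np.isfinite(v.weights.loc["gFLAT"]).all()
        assert (v.weights.to_numpy() > 0).all()

    def test_saturated_design_rejected(self):
        design = two_group_design(1)
        counts = CountMatrix(
            pd.DataFrame(
                [[10, 20], [30, 40]], index=["g0", "g1"], columns=design.sample_ids
            )
        )
        with pytest.raises(ValidationError):
            voom_weights(counts, tmm_factors(counts), design)


class TestStandardContrasts:
    def test_all_six_present_with_fdr_per_contrast(self, small_results):
        results, _ = small_results
        assert set(results) == {
            "plastic_control_pooled",
            "plastic_control_8h",
            "plastic_control_32h",
            "plastic_resistant_pooled",
            "evolved_unsprayed",
            "evolved_sprayed",
        }
        for table in results.values():
            np.testing.assert_allclose(
                table["adj.P.Val"], bh_fdr(table["P.Value"]), atol=1e-12
            )

    def test_planted_plastic_genes_found_only_in_plastic_contrasts(
        self, small_results
    ):
        results, truth = small_results
        plastic_only = truth.table.index[truth.table["class_label"] == "plastic_only"]
        shared = plastic_only.intersection(results["plastic_control_pooled"].index)
        hit = (results["plastic_control_pooled"].loc[shared, "adj.P.Val"] < 0.1).mean()
        leak = (results["evolved_unsprayed"].loc[shared, "adj.P.Val"] < 0.1).mean()
        assert hit > 0.8
        assert leak < 0.05

    def test_swapping_treatment_labels_flips_plastic_sign_exactly(
        self, small_experiment
    ):
        counts, design, _ = small_experiment
        res = run_standard_contrasts(counts, design)
        swapped_table = design.table.copy()
        swapped_table["treatment"] = swapped_table["treatment"].map(
            {"sprayed": "unsprayed", "unsprayed": "sprayed"}
        )
        res_swapped = run_standard_contrasts(counts, SampleDesign(swapped_table))
        np.testing.assert_allclose(
            res_swapped["plastic_control_pooled"]["logFC"].to_numpy(),
            -res["plastic_control_pooled"]["logFC"].to_numpy(),
            atol=1e-10,
        )

    def test_gene_order_invariance(self, small_experiment):
        # factors held fixed: the TMM trim tie-break is positional by design
        counts, design, _ = small_experiment
        factors = tmm_factors(counts)
        res = run_standard_contrasts(counts, design, factors)["plastic_control_pooled"]
        rng = np.random.default_rng(16)
        perm = rng.permutation(counts.n_genes)
        shuffled = CountMatrix(counts.counts.iloc[perm], counts.lib_sizes)
        res_shuffled = run_standard_contrasts(shuffled, design, factors)[
            "plastic_control_pooled"
        ]
        pd.testing.assert_frame_equal(
            res_shuffled.sort_index(), res.sort_index(), atol=1e-10
        )

    def test_missing_cell_named_in_error(self, small_experiment):
        counts, design, _ = small_experiment
        keep = design.table["timepoint"] == 8
        sub_design = SampleDesign(design.table[keep])
        sub_counts = CountMatrix(
            counts.counts.loc[:, keep.to_numpy()], counts.lib_sizes[keep.to_numpy()]
        )
        with pytest.raises(ValidationError, match="32"):
            run_standard_contrasts(sub_counts, sub_design)

    def test_single_line_design_rejected(self):
        design = two_group_design(2)
        counts = CountMatrix(
            pd.DataFrame(
                np.arange(8).reshape(2, 4) + 1,
                index=["g0", "g1"],
                columns=design.sample_ids,
            )
        )
        with pytest.raises(ValidationError):
            run_standard_contrasts(counts, design)


def test_contrast_weights_sum_to_zero():
    for contrast in standard_contrasts().values():
        assert abs(sum(contrast.weights.values())) < 1e-12
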